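"""Linear SPECT data-acquisition model and Poisson data simulation.

The system operator maps a 2D activity image to a sinogram of noise-free
projection means, ``g_mean = A f``, where the implied matrix entry ``a_ij``
is the probability that a photon emitted in pixel ``j`` is detected in
sinogram bin ``i``.  The operator is matrix-free and built from three exact
linear stages per view:

1. rotation of the image into the view frame, implemented as a sparse
   *push* (splat) bilinear interpolation — mass-preserving for pixels that
   stay inside the grid, and with an exact sparse-transpose adjoint;
2. depth-dependent attenuation, a fixed diagonal factor
   ``exp(-integral of mu along the ray to the detector)`` computed from the
   rotated attenuation map;
3. collimator-detector response, a Gaussian blur along the detector axis
   whose width grows linearly with distance from the detector,
   ``sigma(d) = sigma0 + sigma_slope * d`` (pixels);

followed by summation along the ray direction.  Every stage is a sparse or
diagonal linear map, so the adjoint (``backward``) is the exact transpose
and the inner-product identity <A f, g> = <f, A' g> holds to machine
precision — several reconstruction tests depend on that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import map_coordinates


@dataclass(frozen=True)
class Geometry:
    """Acquisition geometry: parallel-beam views around the object.

    ``n_bins`` must equal the image side for the rotation-based operator
    (detector bins align with image columns in the view frame).
    """

    n_views: int = 64
    angular_range_deg: float = 180.0
    n_bins: int = 128
    bin_width_cm: float = 0.4

    def __post_init__(self) -> None:
        if self.n_views < 1 or self.n_bins < 1:
            raise ValueError("n_views and n_bins must be >= 1")
        if not (0.0 < self.angular_range_deg <= 360.0):
            raise ValueError("angular_range_deg must lie in (0, 360]")

    @property
    def angles_deg(self) -> np.ndarray:
        step = self.angular_range_deg / self.n_views
        return np.arange(self.n_views) * step


@dataclass(frozen=True)
class DetectorResponse:
    """Depth-dependent Gaussian collimator-detector response (pixels)."""

    sigma0_px: float = 0.6
    sigma_slope: float = 0.01

    def sigma(self, depth_px: np.ndarray | float) -> np.ndarray | float:
        return self.sigma0_px + self.sigma_slope * np.asarray(depth_px, dtype=float)


@dataclass
class Sinogram:
    """views x bins array of projection means (floats) or counts (ints)."""

    values: np.ndarray
    is_counts: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("sinogram must be 2D (views x bins)")
        if np.any(self.values < 0):
            raise ValueError("sinogram values must be >= 0")
        if self.is_counts and not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.round(self.values)):
                raise ValueError("count sinogram must be integer-valued")


def as_values(sino) -> np.ndarray:
    """Accept a Sinogram or a bare array and return the value array."""
    return np.asarray(getattr(sino, "values", sino), dtype=float)


def _push_rotation(n: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse (n*n, n*n) matrix rotating an image about its center.

    Each source pixel's value is splatted at its rotated center with
    bilinear weights; weights for a source pixel sum to one whenever the
    rotated center lands strictly inside the grid (mass preservation).
    """
    c = (n - 1) / 2.0
    t = np.deg2rad(angle_deg)
    ct, st = np.cos(t), np.sin(t)
    rows, cols = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    dr = (rows - c).ravel()
    dc = (cols - c).ravel()
    r2 = c + dr * ct - dc * st
    c2 = c + dr * st + dc * ct
    r0 = np.floor(r2).astype(np.int64)
    c0 = np.floor(c2).astype(np.int64)
    fr = r2 - r0
    fc = c2 - c0
    src = np.arange(n * n, dtype=np.int64)
    data, out_idx, src_idx = [], [], []
    for dro, dco, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        ro = r0 + dro
        co = c0 + dco
        ok = (ro >= 0) & (ro < n) & (co >= 0) & (co < n) & (w > 0)
        data.append(w[ok])
        out_idx.append(ro[ok] * n + co[ok])
        src_idx.append(src[ok])
    mat = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(out_idx), np.concatenate(src_idx))),
        shape=(n * n, n * n),
    )
    return mat.tocsr()


def _pull_rotate_image(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a fixed map (e.g. attenuation) into the view frame by sampling."""
    n = img.shape[0]
    c = (n - 1) / 2.0
    t = np.deg2rad(angle_deg)
    ct, st = np.cos(t), np.sin(t)
    rows, cols = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    dr = rows - c
    dc = cols - c
    # inverse map: view-frame pixel -> patient-frame coordinates
    rs = c + dr * ct + dc * st
    cs = c - dr * st + dc * ct
    return map_coordinates(img, [rs, cs], order=1, mode="constant", cval=0.0)


def _blur_matrix(n: int, response: DetectorResponse) -> sparse.csr_matrix:
    """Sparse (n*n, n*n) depth-dependent blur along the detector axis.

    Row r of the view-frame image sits at depth r from the detector (the
    detector is on the row-0 side); each row is convolved with a normalized
    Gaussian of width sigma(r).  Zero-padded convolution with a symmetric
    kernel gives a symmetric, hence self-adjoint, matrix.
    """
    blocks = []
    for r in range(n):
        sig = float(response.sigma(r))
        if sig <= 0:
            blocks.append(sparse.identity(n, format="csr"))
            continue
        half = max(1, int(np.ceil(4.0 * sig)))
        x = np.arange(-half, half + 1, dtype=float)
        k = np.exp(-0.5 * (x / sig) ** 2)
        k /= k.sum()
        offsets = np.arange(-half, half + 1)
        block = sparse.diags([np.full(n - abs(o), k[half + o]) for o in offsets], offsets, format="csr")
        blocks.append(block)
    return sparse.block_diag(blocks, format="csr")


class SystemModel:
    """Matrix-free SPECT projector with optional attenuation and response.

    Parameters
    ----------
    geometry:
        View/bin layout; ``geometry.n_bins`` must equal ``grid_side``.
    grid_side:
        Image side in pixels.
    pixel_size_cm:
        Pixel (and ray-step) size in cm, used for attenuation integrals.
    attenuation:
        Optional 2D attenuation map in cm^-1, or None to disable.
    response:
        Optional :class:`DetectorResponse`, or None to disable blurring.
    """

    def __init__(
        self,
        geometry: Geometry,
        grid_side: int,
        pixel_size_cm: float = 0.4,
        attenuation: np.ndarray | None = None,
        response: DetectorResponse | None = None,
    ):
        if geometry.n_bins != grid_side:
            raise ValueError(
                f"rotation-based projector requires n_bins == grid_side "
                f"({geometry.n_bins} != {grid_side})"
            )
        self.geometry = geometry
        self.grid_side = int(grid_side)
        self.pixel_size_cm = float(pixel_size_cm)
        self.response = response
        n = self.grid_side
        self._rot = [_push_rotation(n, a) for a in geometry.angles_deg]
        if attenuation is not None:
            attenuation = np.asarray(attenuation, dtype=float)
            if attenuation.shape != (n, n):
                raise ValueError("attenuation map shape must match the grid")
            if np.any(attenuation < 0):
                raise ValueError("attenuation must be >= 0")
            self._att = []
            for a in geometry.angles_deg:
                mu = _pull_rotate_image(attenuation, a)
                # path integral from pixel center to the detector (row 0 side),
                # counting half of the emitting pixel's own attenuation
                path = np.cumsum(mu, axis=0) - 0.5 * mu
                self._att.append(np.exp(-self.pixel_size_cm * path).ravel())
        else:
            self._att = None
        self._blur = _blur_matrix(n, response) if response is not None else None
        self._sens: np.ndarray | None = None

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.grid_side, self.grid_side)

    @property
    def sino_shape(self) -> tuple[int, int]:
        return (self.geometry.n_views, self.geometry.n_bins)

    def _check_image(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.shape != self.image_shape:
            raise ValueError(f"expected image of shape {self.image_shape}, got {image.shape}")
        return image

    def forward(self, image: np.ndarray, views: np.ndarray | None = None) -> np.ndarray:
        """Project an image to (selected views of) the mean sinogram."""
        image = self._check_image(image)
        n = self.grid_side
        idx = range(self.geometry.n_views) if views is None else np.atleast_1d(views)
        out = np.empty((len(idx), n))
        flat = image.ravel()
        for k, v in enumerate(idx):
            x = self._rot[v] @ flat
            if self._att is not None:
                x = x * self._att[v]
            if self._blur is not None:
                x = self._blur @ x
            out[k] = x.reshape(n, n).sum(axis=0)
        return out

    def backward(self, sino_values: np.ndarray, views: np.ndarray | None = None) -> np.ndarray:
        """Exact adjoint of :meth:`forward` (backprojection)."""
        g = np.atleast_2d(as_values(sino_values))
        n = self.grid_side
        idx = range(self.geometry.n_views) if views is None else np.atleast_1d(views)
        if g.shape != (len(idx), n):
            raise ValueError(f"expected sinogram of shape {(len(idx), n)}, got {g.shape}")
        acc = np.zeros(n * n)
        for k, v in enumerate(idx):
            x = np.broadcast_to(g[k], (n, n)).ravel().copy()
            if self._blur is not None:
                x = self._blur.T @ x
            if self._att is not None:
                x = x * self._att[v]
            acc += self._rot[v].T @ x
        return acc.reshape(n, n)

    def sensitivity_image(self, views: np.ndarray | None = None) -> np.ndarray:
        """Per-pixel sum_i a_ij — the backprojection of an all-ones sinogram."""
        if views is None:
            if self._sens is None:
                self._sens = self.backward(np.ones(self.sino_shape))
            return self._sens
        ones = np.ones((len(np.atleast_1d(views)), self.geometry.n_bins))
        return self.backward(ones, views=views)

    def dense_matrix(self) -> np.ndarray:
        """Explicit (I, J) system matrix for small grids (test oracles)."""
        if self.grid_side > 32:
            raise ValueError("dense_matrix is limited to grids <= 32x32")
        n = self.grid_side
        cols = []
        for j in range(n * n):
            e = np.zeros(n * n)
            e[j] = 1.0
            cols.append(self.forward(e.reshape(n, n)).ravel())
        return np.stack(cols, axis=1)


class MatrixModel:
    """System model defined by an explicit matrix — for small oracle problems.

    Implements the same forward/backward/sensitivity interface as
    :class:`SystemModel` so reconstruction code is agnostic to which it gets.
    """

    def __init__(self, matrix: np.ndarray, image_shape: tuple[int, int], sino_shape: tuple[int, int]):
        matrix = np.asarray(matrix, dtype=float)
        if np.any(matrix < 0):
            raise ValueError("system matrix entries must be >= 0")
        if matrix.shape != (sino_shape[0] * sino_shape[1], image_shape[0] * image_shape[1]):
            raise ValueError("matrix shape inconsistent with image/sinogram shapes")
        self.matrix = matrix
        self.image_shape = tuple(image_shape)
        self.sino_shape = tuple(sino_shape)

    def _rows(self, views):
        n_bins = self.sino_shape[1]
        idx = np.atleast_1d(views)
        return np.concatenate([np.arange(v * n_bins, (v + 1) * n_bins) for v in idx])

    def forward(self, image: np.ndarray, views=None) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.shape != self.image_shape:
            raise ValueError(f"expected image of shape {self.image_shape}, got {image.shape}")
        if views is None:
            return (self.matrix @ image.ravel()).reshape(self.sino_shape)
        rows = self._rows(views)
        return (self.matrix[rows] @ image.ravel()).reshape(len(np.atleast_1d(views)), self.sino_shape[1])

    def backward(self, sino_values, views=None) -> np.ndarray:
        g = as_values(sino_values).ravel()
        if views is None:
            return (self.matrix.T @ g).reshape(self.image_shape)
        rows = self._rows(views)
        return (self.matrix[rows].T @ g).reshape(self.image_shape)

    def sensitivity_image(self, views=None) -> np.ndarray:
        if views is None:
            return self.matrix.sum(axis=0).reshape(self.image_shape)
        rows = self._rows(views)
        return self.matrix[rows].sum(axis=0).reshape(self.image_shape)


def forward_project(model, image: np.ndarray) -> Sinogram:
    """Noise-free mean sinogram of an activity image (linear in the image)."""
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("activity image must be >= 0")
    return Sinogram(model.forward(image), is_counts=False)


def back_project(model, sino) -> np.ndarray:
    """Adjoint of :func:`forward_project` applied to a sinogram."""
    return model.backward(as_values(sino))


def sensitivity(model) -> np.ndarray:
    """Sensitivity image sum_i a_ij; equals back_project of all-ones."""
    return model.sensitivity_image()


def simulate_counts(mean, seed: int, scale: float | None = None) -> Sinogram:
    """Draw an independent Poisson count per bin around the mean sinogram.

    If ``scale`` is given the mean is first rescaled so its total equals
    ``scale`` (total-count target).  Reproducible for a fixed seed.
    """
    m = as_values(mean)
    if np.any(m < 0):
        raise ValueError("mean sinogram must be >= 0")
    if scale is not None:
        total = m.sum()
        if total <= 0:
            raise ValueError("cannot rescale an all-zero mean sinogram")
        m = m * (float(scale) / total)
    rng = np.random.default_rng(seed)
    return Sinogram(rng.poisson(m), is_counts=True)
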