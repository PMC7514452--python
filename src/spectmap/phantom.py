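"""Digital phantoms for 2D SPECT simulation studies.

The default phantom emulates an oncologic liver study in a torso axial
cross-section: an elliptical body containing a liver and a stomach, with a
small hot tumor embedded in the upper-left part of the liver whose activity
is 1.6 times that of the surrounding healthy liver tissue.  Arbitrary
phantoms can be built from geometric primitives (rotated ellipses and discs).

Rasterization is deliberately simple — a pixel belongs to a primitive iff
its *center* lies inside the primitive, with no anti-aliasing — so region
masks and activity ratios are exact, which the reconstruction tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical region labels; later primitives overwrite earlier ones, so the
#: tumor (drawn last in the default phantom) always wins where it overlaps.
LABELS = {"background": 0, "body": 1, "liver": 2, "stomach": 3, "tumor": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass(frozen=True)
class Primitive:
    """A rotated ellipse or disc with a constant activity level.

    Parameters
    ----------
    shape:
        ``"ellipse"`` or ``"disc"``.  A disc is an ellipse with equal
        semi-axes; ``semi_axes`` must then be equal.
    center:
        (row, col) of the center in pixel coordinates.
    semi_axes:
        (row semi-axis, col semi-axis) in pixels, before rotation.
    angle_deg:
        Counter-clockwise rotation of the ellipse axes, degrees.
    activity:
        Activity level in arbitrary units, >= 0.
    label:
        Region label; one of :data:`LABELS`.
    """

    shape: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float = 0.0
    activity: float = 0.0
    label: str = "body"

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "disc"):
            raise ValueError(f"unknown primitive shape {self.shape!r}")
        if self.shape == "disc" and self.semi_axes[0] != self.semi_axes[1]:
            raise ValueError("disc primitives require equal semi-axes")
        if self.activity < 0:
            raise ValueError(f"negative activity on primitive {self.label!r}")
        if min(self.semi_axes) <= 0:
            raise ValueError(f"non-positive semi-axis on primitive {self.label!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown region label {self.label!r}")

    def extent(self) -> tuple[float, float]:
        """Half-extent of the rotated ellipse along (row, col)."""
        a, b = self.semi_axes
        t = np.deg2rad(self.angle_deg)
        er = float(np.hypot(a * np.cos(t), b * np.sin(t)))
        ec = float(np.hypot(a * np.sin(t), b * np.cos(t)))
        return er, ec

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Boolean membership of pixel centers (rows, cols)."""
        a, b = self.semi_axes
        t = np.deg2rad(self.angle_deg)
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        # rotate offsets into the ellipse frame
        u = dr * np.cos(t) + dc * np.sin(t)
        v = -dr * np.sin(t) + dc * np.cos(t)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of a phantom.

    Invariants enforced at construction: all activities are non-negative,
    every primitive fits inside the grid, and (when both regions are present)
    tumor activity equals ``tumor_to_liver_ratio`` times liver activity
    exactly.
    """

    grid_side: int = 128
    pixel_size_cm: float = 0.4
    primitives: tuple[Primitive, ...] = ()
    tumor_to_liver_ratio: float = 1.6
    attenuation_inside_body: float = 0.15  # cm^-1, soft tissue

    def __post_init__(self) -> None:
        if self.grid_side < 1:
            raise ValueError("grid_side must be >= 1")
        if self.pixel_size_cm <= 0:
            raise ValueError("pixel_size_cm must be > 0")
        if self.attenuation_inside_body < 0:
            raise ValueError("attenuation must be >= 0")
        object.__setattr__(self, "primitives", tuple(self.primitives))
        for p in self.primitives:
            er, ec = p.extent()
            lo = min(p.center[0] - er, p.center[1] - ec)
            hi = max(p.center[0] + er, p.center[1] + ec)
            if lo < 0 or hi > self.grid_side - 1:
                raise ValueError(
                    f"primitive {p.label!r} (center {p.center}, semi-axes "
                    f"{p.semi_axes}) does not lie fully inside the "
                    f"{self.grid_side}x{self.grid_side} grid"
                )
        liver = [p for p in self.primitives if p.label == "liver"]
        tumor = [p for p in self.primitives if p.label == "tumor"]
        if liver and tumor:
            want = self.tumor_to_liver_ratio * liver[-1].activity
            for p in tumor:
                if p.activity != want:
                    raise ValueError(
                        "tumor activity must equal tumor_to_liver_ratio x "
                        f"liver activity ({want}), got {p.activity}"
                    )


@dataclass
class PhantomBundle:
    """Rasterized phantom: activity, attenuation map, region masks.

    ``masks`` is an integer label image using the :data:`LABELS` coding; the
    labels partition the grid.  ``profile_row`` is the image row through the
    tumor center, used for the profile comparisons.
    """

    activity: np.ndarray
    attenuation: np.ndarray
    masks: np.ndarray
    profile_row: int
    pixel_size_cm: float

    def mask_of(self, label: str) -> np.ndarray:
        return self.masks == LABELS[label]


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Rasterize a :class:`PhantomSpec` on its grid.

    Primitives are painted in order, later ones overwriting earlier ones.
    The attenuation map equals ``spec.attenuation_inside_body`` wherever the
    label is not background and zero elsewhere.
    """
    n = spec.grid_side
    rows, cols = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    activity = np.zeros((n, n))
    masks = np.full((n, n), LABELS["background"], dtype=np.int32)
    tumor_center_row = None
    for p in spec.primitives:
        inside = p.contains(rows, cols)
        activity[inside] = p.activity
        masks[inside] = LABELS[p.label]
        if p.label == "tumor":
            tumor_center_row = int(round(p.center[0]))
    attenuation = np.where(masks != LABELS["background"], spec.attenuation_inside_body, 0.0)
    profile_row = tumor_center_row if tumor_center_row is not None else n // 2
    return PhantomBundle(
        activity=activity,
        attenuation=attenuation,
        masks=masks,
        profile_row=profile_row,
        pixel_size_cm=spec.pixel_size_cm,
    )


def default_liver_phantom(grid_side: int = 128) -> PhantomSpec:
    """Default torso phantom: body, liver, stomach and a hot liver tumor.

    Deterministic.  Activities are in arbitrary units with healthy liver at
    1.0; the tumor is at 1.6 (ratio 1.6), the stomach at 1.3 and the body
    background at 0.2.  The geometry scales linearly with ``grid_side`` so a
    half-size (64 px) phantom has the same anatomy.
    """
    s = grid_side / 128.0
    prims = (
        Primitive("ellipse", (64 * s, 64 * s), (42 * s, 55 * s), 0.0, 0.2, "body"),
        Primitive("ellipse", (60 * s, 44 * s), (26 * s, 20 * s), 20.0, 1.0, "liver"),
        Primitive("ellipse", (62 * s, 88 * s), (18 * s, 13 * s), -15.0, 1.3, "stomach"),
        Primitive("disc", (44 * s, 36 * s), (5 * s, 5 * s), 0.0, 1.6, "tumor"),
    )
    return PhantomSpec(
        grid_side=grid_side,
        pixel_size_cm=0.4 * 128.0 / grid_side,
        primitives=prims,
        tumor_to_liver_ratio=1.6,
        attenuation_inside_body=0.15,
    )
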