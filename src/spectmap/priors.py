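"""Image priors: Gibbs (Markov random field) energies and entropy functionals.

Two prior families are provided.

* A Gibbs prior ``exp(-beta * U)`` whose energy ``U(f) = sum_j sum_{k in c_j}
  w_jk V(f_j - f_k)`` sums an edge-preserving potential ``V`` over
  neighboring-pixel differences.  The double sum counts each unordered pair
  twice, exactly as the energy is conventionally written, so the gradient is
  ``dU/df_j = 2 sum_{k in c_j} w_jk V'(f_j - f_k)`` for even ``V``; the
  factor of two is absorbed into ``beta`` in practice.

* Entropy priors ``-beta * sum_j f_j ln f_j`` favoring smooth, spread-out
  activity, in a global form (one ``beta``) and a local form where the image
  is partitioned into regions ``C_k`` with region-specific weights
  ``beta_k`` — the ingredient of locally regularized MAP reconstruction.

Boundary handling for the Gibbs energy: neighbors falling outside the grid
are omitted, so the energy is a sum over valid pixel pairs only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Neighborhood system c_j: integer offsets and their weights w_jk.

    Must be symmetric (the negation of every offset is present with the same
    weight) and must not contain the zero offset.
    """

    offsets: tuple[tuple[int, int], ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", tuple(tuple(o) for o in self.offsets))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(self.offsets) != len(self.weights):
            raise ValueError("offsets and weights must have equal length")
        table = dict(zip(self.offsets, self.weights))
        if len(table) != len(self.offsets):
            raise ValueError("duplicate neighborhood offsets")
        for (dr, dc), w in table.items():
            if (dr, dc) == (0, 0):
                raise ValueError("zero offset is not a neighbor")
            if w <= 0:
                raise ValueError("neighborhood weights must be > 0")
            if table.get((-dr, -dc)) != w:
                raise ValueError("neighborhood must be symmetric with equal weights")


def four_neighborhood() -> NeighborhoodSpec:
    """Axial 4-neighborhood with unit weights."""
    offs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    return NeighborhoodSpec(offs, (1.0,) * 4)


def eight_neighborhood() -> NeighborhoodSpec:
    """8-neighborhood: weight 1 for axial, 1/sqrt(2) for diagonal neighbors."""
    offs = ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1))
    w = (1.0, 1.0, 1.0, 1.0, 1 / _SQRT2, 1 / _SQRT2, 1 / _SQRT2, 1 / _SQRT2)
    return NeighborhoodSpec(offs, w)


@dataclass(frozen=True)
class PotentialSpec:
    """Edge-preserving clique potential V(d) on neighbor differences d.

    families:
      - ``rational_quadratic``: V(d) = d^2 / (2 delta^2 + d^2), bounded in
        [0, 1); saturates for |d| >> delta so sharp edges are tolerated.
      - ``huber``: V(d) = d^2 / (2 delta^2) for |d| <= delta, else
        (|d| - delta/2) / delta; quadratic near zero, linear in the tails,
        continuous and C^1 at |d| = delta.

    ``delta`` (activity units) sets the difference scale that separates
    "noise" from "edge".
    """

    family: str = "rational_quadratic"
    delta: float = 0.1

    def __post_init__(self) -> None:
        if self.family not in ("rational_quadratic", "huber"):
            raise ValueError(f"unknown potential family {self.family!r}")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


def potential_value(spec: PotentialSpec, d) -> np.ndarray:
    """V(d); even in d, non-negative, V(0) = 0."""
    d = np.asarray(d, dtype=float)
    dl = spec.delta
    if spec.family == "rational_quadratic":
        return d * d / (2.0 * dl * dl + d * d)
    quad = d * d / (2.0 * dl * dl)
    lin = (np.abs(d) - dl / 2.0) / dl
    return np.where(np.abs(d) <= dl, quad, lin)


def potential_derivative(spec: PotentialSpec, d) -> np.ndarray:
    """V'(d); odd in d, analytic counterpart of :func:`potential_value`."""
    d = np.asarray(d, dtype=float)
    dl = spec.delta
    if spec.family == "rational_quadratic":
        return 4.0 * dl * dl * d / (2.0 * dl * dl + d * d) ** 2
    return np.where(np.abs(d) <= dl, d / (dl * dl), np.sign(d) / dl)


@dataclass
class PriorEvaluation:
    """Value and per-pixel gradient of a prior functional."""

    value: float
    gradient: np.ndarray


def _pair_views(img: np.ndarray, dr: int, dc: int):
    """Views (center, neighbor) of all in-grid pixel pairs at offset (dr, dc)."""
    nr, nc = img.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    center = np.s_[r0:r1, c0:c1]
    neighbor = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return center, neighbor


def gibbs_energy(image: np.ndarray, nb: NeighborhoodSpec, pot: PotentialSpec) -> PriorEvaluation:
    """Gibbs energy U(f) and its analytic gradient.

    Each unordered neighbor pair contributes twice to the value (once per
    orientation of the offset), matching the literal double sum.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    value = 0.0
    grad = np.zeros_like(image)
    for (dr, dc), w in zip(nb.offsets, nb.weights):
        center, neighbor = _pair_views(image, dr, dc)
        d = image[center] - image[neighbor]
        value += w * float(potential_value(pot, d).sum())
        # dU/df_j: j as the center of this offset plus j as the neighbor of
        # the mirrored offset (also in nb by symmetry) -> factor 2 overall
        grad[center] += 2.0 * w * potential_derivative(pot, d)
    return PriorEvaluation(value=value, gradient=grad)


def entropy_value(image: np.ndarray) -> PriorEvaluation:
    """Unweighted entropy -sum_j f_j ln f_j with the convention 0 ln 0 = 0.

    The gradient is -(1 + ln f_j) where f_j > 0 and 0 at f_j = 0 (the
    multiplicative entropy updates never evaluate it there).
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("entropy requires a non-negative image")
    pos = image > 0
    logs = np.zeros_like(image)
    logs[pos] = np.log(image[pos])
    value = -float((image * logs).sum())
    grad = np.where(pos, -(1.0 + logs), 0.0)
    return PriorEvaluation(value=value, gradient=grad)


@dataclass
class RegularizationMap:
    """Partition of the image into regions C_k with per-region weights.

    ``region_labels`` is an integer label image; ``gamma_per_region`` maps
    each label to its regularization parameter gamma_k = 1 / beta_k.  Every
    pixel must carry a label present in the map.
    """

    region_labels: np.ndarray
    gamma_per_region: dict[int, float]

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels)
        if not np.issubdtype(self.region_labels.dtype, np.integer):
            raise ValueError("region labels must be integers")
        present = set(np.unique(self.region_labels).tolist())
        missing = present - set(self.gamma_per_region)
        if missing:
            raise ValueError(f"unlabeled regions without a gamma: {sorted(missing)}")
        for k, g in self.gamma_per_region.items():
            if g <= 0:
                raise ValueError(f"gamma for region {k} must be > 0")

    def gamma_image(self) -> np.ndarray:
        out = np.empty(self.region_labels.shape, dtype=float)
        for k, g in self.gamma_per_region.items():
            out[self.region_labels == k] = g
        return out

    def beta_image(self) -> np.ndarray:
        return 1.0 / self.gamma_image()


@dataclass(frozen=True)
class EntropySpec:
    """Global entropy prior weight beta; gamma = 1/beta is the step form."""

    beta: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    @property
    def gamma(self) -> float:
        return 1.0 / self.beta


def local_entropy_value(image: np.ndarray, reg: RegularizationMap) -> PriorEvaluation:
    """Region-weighted entropy -sum_k beta_k sum_{j in C_k} f_j ln f_j.

    With all beta_k equal to a common beta this reduces to beta times
    :func:`entropy_value`.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != reg.region_labels.shape:
        raise ValueError("regularization map must cover the image")
    base = entropy_value(image)
    beta = reg.beta_image()
    pos = image > 0
    logs = np.zeros_like(image)
    logs[pos] = np.log(image[pos])
    value = -float((beta * image * logs).sum())
    grad = beta * base.gradient
    return PriorEvaluation(value=value, gradient=grad)
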