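"""Iterative reconstruction algorithms for Poisson emission data.

All algorithms maximize (or locally improve) an objective of the form

    Phi(f) = log P(g | f) + ln P(f),
    log P(g | f) = sum_i [ g_i ln (A f)_i - (A f)_i ]   (constants dropped)

using multiplicative updates that preserve non-negativity:

* ``mlem`` — classical expectation-maximization for the pure likelihood,
  ``f <- f * A'(g / A f) / A' 1``; monotone in the log-likelihood.
* ``osem`` — ordered-subsets acceleration of MLEM: one pass cycles through
  disjoint view subsets, using each subset's own sensitivity.
* ``map-gibbs`` — one-step-late (OSL) MAP with a Gibbs smoothing prior: the
  prior gradient, evaluated at the current iterate, joins the sensitivity in
  the denominator.  The denominator is clamped below at ``eps * sensitivity``
  because OSL can drive it non-positive at large beta.
* ``map-ent`` — MAP with a global entropy prior, in the multiplicative
  exponential form ``f <- f * exp(gamma * (A'(g/Af) - A'1))`` initialized at
  ``f = 1/e``; gamma = 1/beta damps the step, and regularization acts
  through damping plus early stopping.
* ``map-ent-add`` — the additive exponential form
  ``f <- exp(-1 + gamma * (A'(g/Af) - A'1))`` whose fixed point satisfies
  the exact entropy-MAP stationarity condition.
* ``map-ent-loc`` — the locally regularized entropy MAP: gamma varies per
  region of a :class:`~spectmap.priors.RegularizationMap`, with an adaptive
  rule that, from a switch iteration on, relabels organ pixels whose
  estimate exceeds the healthy-tissue activity level as "hot" and gives
  them their own gamma.

Exponents in the entropy-family updates are clamped to +-50 purely as an
overflow guard; it is inactive in ordinary use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import (
    NeighborhoodSpec,
    PotentialSpec,
    RegularizationMap,
    eight_neighborhood,
    entropy_value,
    gibbs_energy,
    local_entropy_value,
)
from .projector import as_values

EXP_CLAMP = 50.0
ALGORITHMS = ("mlem", "osem", "map-gibbs", "map-ent", "map-ent-add", "map-ent-loc")

# region codes used by the adaptive local-regularization rule
REGION_GLOBAL, REGION_HEALTHY, REGION_HOT = 0, 1, 2


def poisson_log_likelihood(counts, mean) -> float:
    """Poisson log-likelihood sum_i [g_i ln m_i - m_i], constants dropped.

    Bins with m_i = 0 contribute 0 when g_i = 0 and -inf when g_i > 0 (an
    impossible observation under the model).
    """
    g = as_values(counts)
    m = as_values(mean)
    if g.shape != m.shape:
        raise ValueError(f"count/mean shape mismatch: {g.shape} vs {m.shape}")
    if np.any(m < 0):
        raise ValueError("mean sinogram must be >= 0")
    zero = m == 0
    if np.any(zero & (g > 0)):
        return -np.inf
    ll = np.zeros_like(m)
    ok = ~zero
    ll[ok] = g[ok] * np.log(m[ok]) - m[ok]
    return float(ll.sum())


@dataclass
class LocalRegSpec:
    """Adaptive per-region regularization for the entropy-local algorithm.

    ``organ_mask`` marks the organ that receives local treatment (e.g. the
    liver, tumor included); pixels outside it keep the global gamma.  From
    ``switch_iteration`` on, organ pixels whose estimate exceeds
    ``healthy_level * (1 + threshold_margin)`` are labeled hot and use
    ``gamma_hot``; the rest of the organ uses ``gamma_healthy``.  When
    ``healthy_level`` is None it is estimated from the current iterate as
    the organ mean excluding the top decile.  ``refresh_labels`` re-derives
    the labels every iteration; otherwise they freeze at first assignment.
    """

    organ_mask: np.ndarray
    gamma_healthy: float
    gamma_hot: float
    switch_iteration: int = 5
    healthy_level: float | None = None
    threshold_margin: float = 0.1
    refresh_labels: bool = True

    def __post_init__(self) -> None:
        self.organ_mask = np.asarray(self.organ_mask, dtype=bool)
        if not self.organ_mask.any():
            raise ValueError("organ mask is empty")
        if self.gamma_healthy <= 0 or self.gamma_hot <= 0:
            raise ValueError("gammas must be > 0")
        if self.healthy_level is not None and self.healthy_level <= 0:
            raise ValueError("healthy_level must be > 0")


@dataclass
class ReconConfig:
    """Configuration of one reconstruction run."""

    algorithm: str = "mlem"
    n_iterations: int = 20
    n_subsets: int = 8
    beta: float = 1.0
    gamma: float = 0.05
    potential: PotentialSpec = field(default_factory=PotentialSpec)
    neighborhood: NeighborhoodSpec = field(default_factory=eight_neighborhood)
    local: LocalRegSpec | None = None
    epsilon: float = 1e-6
    checkpoints: tuple[int, ...] = ()
    track_objective: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.beta < 0 or self.gamma <= 0:
            raise ValueError("beta must be >= 0 and gamma > 0")
        if not (0 < self.epsilon < 1):
            raise ValueError("epsilon must lie in (0, 1)")
        if self.algorithm == "map-ent-loc" and self.local is None:
            raise ValueError("map-ent-loc requires a LocalRegSpec")


@dataclass
class ReconState:
    """Current estimate plus bookkeeping accumulated across iterations."""

    estimate: np.ndarray
    iteration: int = 0
    objective_history: list[dict] = field(default_factory=list)
    region_map: RegularizationMap | None = None
    checkpoints: dict[int, np.ndarray] = field(default_factory=dict)

    def advanced(self, new_estimate: np.ndarray) -> "ReconState":
        return ReconState(
            estimate=new_estimate,
            iteration=self.iteration + 1,
            objective_history=self.objective_history,
            region_map=self.region_map,
            checkpoints=self.checkpoints,
        )


def _em_factors(model, f: np.ndarray, counts: np.ndarray, views=None):
    """Backprojected likelihood ratio A'(g / A f) and sensitivity A'1."""
    mean = model.forward(f, views=views) if views is not None else model.forward(f)
    g = counts if views is None else counts[np.atleast_1d(views)]
    ratio = np.where(mean > 0, np.divide(g, mean, out=np.zeros_like(mean), where=mean > 0), 0.0)
    bp = model.backward(ratio, views=views) if views is not None else model.backward(ratio)
    sens = model.sensitivity_image(views=views) if views is not None else model.sensitivity_image()
    return bp, sens


def _check_sensitivity(f: np.ndarray, sens: np.ndarray) -> None:
    if np.any((f > 0) & (sens <= 0)):
        raise ValueError("zero sensitivity at pixels with positive estimate")


def mlem_update(state: ReconState, model, counts) -> ReconState:
    """One MLEM iteration: f <- f * A'(g / A f) / A'1."""
    f = state.estimate
    g = as_values(counts)
    bp, sens = _em_factors(model, f, g)
    _check_sensitivity(f, sens)
    new = np.where(sens > 0, f * np.divide(bp, sens, out=np.zeros_like(bp), where=sens > 0), 0.0)
    return state.advanced(new)


def osem_subsets(n_views: int, n_subsets: int) -> list[np.ndarray]:
    """Disjoint, exhaustive view subsets in bit-reversed processing order.

    Subset s holds the views congruent to s (mod n_subsets), giving uniform
    angular coverage within each subset; subsets are visited in bit-reversed
    order of s for maximal angular separation between consecutive updates.
    """
    if n_subsets < 1 or n_views % n_subsets != 0:
        raise ValueError(f"n_subsets ({n_subsets}) must divide n_views ({n_views})")
    n_bits = max(1, (n_subsets - 1).bit_length())
    order = sorted(range(n_subsets), key=lambda s: int(format(s, f"0{n_bits}b")[::-1], 2))
    return [np.arange(s, n_views, n_subsets) for s in order]


def osem_pass(state: ReconState, model, counts, n_subsets: int) -> ReconState:
    """One full OSEM pass: an MLEM-style sub-iteration per view subset."""
    f = state.estimate
    g = as_values(counts)
    for views in osem_subsets(model.sino_shape[0], n_subsets):
        bp, sens = _em_factors(model, f, g, views=views)
        # pixels a subset cannot see (zero subset sensitivity, e.g. grid
        # corners at oblique views) are left unchanged in that sub-iteration
        f = np.where(sens > 0, f * np.divide(bp, sens, out=np.zeros_like(bp), where=sens > 0), f)
    return state.advanced(f)


def map_gibbs_update(
    state: ReconState,
    model,
    counts,
    beta: float,
    nb: NeighborhoodSpec,
    pot: PotentialSpec,
    eps: float = 1e-6,
) -> ReconState:
    """One-step-late MAP iteration with a Gibbs prior.

    The prior gradient is evaluated at the current iterate (OSL), keeping
    the update multiplicative; beta = 0 reduces exactly to MLEM.
    """
    f = state.estimate
    g = as_values(counts)
    bp, sens = _em_factors(model, f, g)
    _check_sensitivity(f, sens)
    denom = sens + beta * gibbs_energy(f, nb, pot).gradient
    denom = np.maximum(denom, eps * sens)
    new = np.where(denom > 0, f * np.divide(bp, denom, out=np.zeros_like(bp), where=denom > 0), 0.0)
    return state.advanced(new)


def _ent_exponent(model, f, g, gamma) -> np.ndarray:
    bp, sens = _em_factors(model, f, g)
    return np.clip(gamma * (bp - sens), -EXP_CLAMP, EXP_CLAMP)


def map_ent_update(state: ReconState, model, counts, gamma: float) -> ReconState:
    """Multiplicative entropy-MAP step: f <- f * exp(gamma (A'(g/Af) - A'1))."""
    f = state.estimate
    if np.any(f <= 0):
        raise ValueError("entropy updates require a strictly positive estimate")
    new = f * np.exp(_ent_exponent(model, f, as_values(counts), gamma))
    return state.advanced(new)


def map_ent_update_additive(state: ReconState, model, counts, gamma: float) -> ReconState:
    """Additive entropy-MAP step: f <- exp(-1 + gamma (A'(g/Af) - A'1)).

    From the entropy initialization f = 1/e its first iterate coincides with
    the multiplicative form's; its fixed point satisfies the exact
    stationarity condition ln f = -1 + gamma (A'(g/Af) - A'1).
    """
    f = state.estimate
    if np.any(f <= 0):
        raise ValueError("entropy updates require a strictly positive estimate")
    new = np.exp(-1.0 + _ent_exponent(model, f, as_values(counts), gamma))
    return state.advanced(new)


def map_ent_loc_update(state: ReconState, model, counts, reg: RegularizationMap) -> ReconState:
    """Entropy-MAP step with per-region gamma from a RegularizationMap."""
    f = state.estimate
    if np.any(f <= 0):
        raise ValueError("entropy updates require a strictly positive estimate")
    if reg.region_labels.shape != f.shape:
        raise ValueError("regularization map must cover the image")
    new = f * np.exp(_ent_exponent(model, f, as_values(counts), reg.gamma_image()))
    out = state.advanced(new)
    out.region_map = reg
    return out


def estimate_healthy_level(estimate: np.ndarray, organ_mask: np.ndarray) -> float:
    """Organ mean excluding the top decile — a robust healthy-tissue level."""
    vals = np.sort(estimate[organ_mask])
    keep = max(1, int(np.ceil(0.9 * vals.size)))
    return float(vals[:keep].mean())


def update_region_map(
    state: ReconState,
    local: LocalRegSpec,
    gamma_global: float,
    iteration: int | None = None,
) -> RegularizationMap:
    """Adaptive region assignment for locally regularized entropy MAP.

    Before the switch iteration the whole organ is labeled healthy.  From
    the switch iteration on, organ pixels whose estimate exceeds the healthy
    activity level (times 1 + margin) are labeled hot.  Pixels outside the
    organ always carry the global label.  With ``refresh_labels`` False the
    labels computed at the switch iteration are kept for all later ones.
    """
    it = state.iteration if iteration is None else iteration
    labels = np.full(state.estimate.shape, REGION_GLOBAL, dtype=np.int32)
    labels[local.organ_mask] = REGION_HEALTHY
    if it >= local.switch_iteration:
        if (
            not local.refresh_labels
            and state.region_map is not None
            and np.any(state.region_map.region_labels == REGION_HOT)
        ):
            labels = state.region_map.region_labels
        else:
            level = local.healthy_level
            if level is None:
                level = estimate_healthy_level(state.estimate, local.organ_mask)
            hot = local.organ_mask & (state.estimate > level * (1.0 + local.threshold_margin))
            labels[hot] = REGION_HOT
    return RegularizationMap(
        region_labels=labels,
        gamma_per_region={
            REGION_GLOBAL: gamma_global,
            REGION_HEALTHY: local.gamma_healthy,
            REGION_HOT: local.gamma_hot,
        },
    )


def initial_estimate(config: ReconConfig, model, counts) -> np.ndarray:
    """Initialization: 1/e for the entropy family (the convention tied to the
    additive update's fixed-point form), else a uniform image scaled so its
    forward projection carries the observed total counts."""
    shape = model.image_shape
    if config.algorithm in ("map-ent", "map-ent-add", "map-ent-loc"):
        return np.full(shape, 1.0 / np.e)
    total = float(as_values(counts).sum())
    sens_total = float(model.sensitivity_image().sum())
    level = total / sens_total if sens_total > 0 and total > 0 else 1.0
    return np.full(shape, level)


def _objective_terms(config: ReconConfig, model, state: ReconState, counts) -> dict:
    mean = model.forward(state.estimate)
    ll = poisson_log_likelihood(counts, mean)
    if config.algorithm == "map-gibbs":
        prior = -config.beta * gibbs_energy(state.estimate, config.neighborhood, config.potential).value
    elif config.algorithm in ("map-ent", "map-ent-add"):
        prior = entropy_value(state.estimate).value / config.gamma
    elif config.algorithm == "map-ent-loc" and state.region_map is not None:
        prior = local_entropy_value(state.estimate, state.region_map).value
    else:
        prior = 0.0
    return {"iteration": state.iteration, "loglik": ll, "prior": prior, "objective": ll + prior}


def run_reconstruction(config: ReconConfig, model, counts, init: np.ndarray | None = None) -> ReconState:
    """Run the configured algorithm for ``config.n_iterations`` full passes.

    Records the per-iteration log-likelihood and prior value (when
    ``track_objective``), stores deep copies of the estimate at the
    requested checkpoint iterations, and, for the locally regularized
    entropy algorithm, refreshes the region map before each update.
    """
    g = as_values(counts)
    f0 = initial_estimate(config, model, counts) if init is None else np.asarray(init, dtype=float)
    state = ReconState(estimate=f0)
    if config.track_objective:
        state.objective_history.append(_objective_terms(config, model, state, g))
    if 0 in config.checkpoints:
        state.checkpoints[0] = f0.copy()
    for it in range(1, config.n_iterations + 1):
        if config.algorithm == "mlem":
            state = mlem_update(state, model, g)
        elif config.algorithm == "osem":
            state = osem_pass(state, model, g, config.n_subsets)
        elif config.algorithm == "map-gibbs":
            state = map_gibbs_update(
                state, model, g, config.beta, config.neighborhood, config.potential, config.epsilon
            )
        elif config.algorithm == "map-ent":
            state = map_ent_update(state, model, g, config.gamma)
        elif config.algorithm == "map-ent-add":
            state = map_ent_update_additive(state, model, g, config.gamma)
        elif config.algorithm == "map-ent-loc":
            reg = update_region_map(state, config.local, config.gamma, iteration=it)
            state.region_map = reg
            state = map_ent_loc_update(state, model, g, reg)
        if config.track_objective:
            state.objective_history.append(_objective_terms(config, model, state, g))
        if it in config.checkpoints:
            state.checkpoints[it] = state.estimate.copy()
    return state
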