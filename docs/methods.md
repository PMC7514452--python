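# Methods

## Data model

Activity is a non-negative 2D image `f` (arbitrary units) on an `n × n`
grid with pixel size `p` cm. Detected counts `g` in each of
`n_views × n_bins` sinogram bins are independent Poisson variables with
mean `ḡ = A f`. The system operator `A` is matrix-free and composed, per
view, of four exact linear stages:

1. **Rotation** of the image into the view frame by push (splat) bilinear
   interpolation about the grid center. Push interpolation preserves total
   counts for every pixel whose rotated center stays on the grid, and its
   adjoint is the literal sparse transpose, so `⟨Af, g⟩ = ⟨f, A'g⟩` holds to
   machine precision (the tests assert 1e-8 relative on random inputs; in
   practice the error is at rounding level).
2. **Attenuation**: a fixed diagonal factor `exp(−p·∫μ)` along each ray to
   the detector, computed from the attenuation map pull-rotated
   (`scipy.ndimage.map_coordinates`, bilinear) into the view frame, with
   the emitting pixel contributing half its own `μ`.
3. **Collimator-detector response**: each depth row `r` (distance `r`
   pixels from the detector) is convolved with a normalized Gaussian of
   width `σ(r) = σ0 + σ_slope · r`. Zero-padded convolution with a
   symmetric kernel is a symmetric matrix, hence self-adjoint.
4. **Summation** along the ray direction.

The detector has `n_bins = n` bins aligned with the rotated image columns;
64 views span 180° by default (configurable to 360°). Defaults
`σ0 = 0.6 px`, `σ_slope = 0.01` correspond to ~5.6 mm intrinsic FWHM at
4 mm pixels with mild depth dependence, typical of a parallel-hole
collimator. Attenuation defaults to water-equivalent soft tissue,
`μ = 0.15 cm⁻¹`, inside the body outline and zero outside.

## Phantom

The default phantom models an abdominal axial slice from an oncologic
liver study: a body ellipse (background activity 0.2), a liver ellipse
(activity 1.0), a stomach ellipse (1.3), and a 5-px-radius tumor disc in
the upper-left liver at exactly 1.6× the healthy-liver activity. The
1.6 ratio and the 128×128 grid are protocol constants; the remaining
geometry and the absolute activity levels are conventions chosen to echo a
typical clinical slice, and everything is configurable through
`PhantomSpec`. Rasterization is center-in-primitive with no anti-aliasing,
so region masks partition the grid exactly and the rasterized tumor:liver
mean-activity ratio equals the spec ratio to machine precision. The
profile line used for visual comparison is the image row through the tumor
center.

Total counts default to 1×10⁴ per slice — a deliberately count-poor
acquisition of the kind seen in In-111 octreotide imaging. This level was
calibrated once, against the intended qualitative behavior of the
comparison (unregularized OSEM visibly degrading by pass 5), and then
frozen; see "Empirical regularization defaults" below.

## Algorithms

All updates are multiplicative and preserve non-negativity; `A'` denotes
the exact adjoint and `A'1` the sensitivity image.

* **MLEM**: `f ← f · A'(g/Af) / A'1`. Monotone in the Poisson
  log-likelihood `Σ_i [g_i ln ḡ_i − ḡ_i]` (constants dropped). Initialized
  uniform, scaled so the forward projection carries the observed total
  counts.
* **OSEM**: one pass applies the MLEM update restricted to each of `S`
  disjoint view subsets in turn (subset sensitivity in the denominator).
  Subset `s` holds views congruent to `s` mod `S`; subsets are visited in
  bit-reversed order for maximal angular separation. Pixels a subset cannot
  see (zero subset sensitivity; grid corners at oblique views) are left
  unchanged in that sub-iteration. Default: 8 subsets.
* **MAP-Gibbs (one-step-late)**: the Gibbs prior `exp(−βU)` with
  `U(f) = Σ_j Σ_{k∈c_j} w_jk V(f_j − f_k)` joins the denominator:
  `f ← f · A'(g/Af) / (A'1 + β ∂U/∂f)`, the prior gradient evaluated at
  the current iterate. The double sum counts each unordered pair twice
  (`∂U/∂f_j = 2 Σ_k w_jk V'(f_j − f_k)`); the factor is absorbed into β.
  Potentials: rational-quadratic `d²/(2δ² + d²)` (bounded, strongly
  edge-preserving) and a Huber-type `d²/2δ²` / `(|d| − δ/2)/δ` (C¹ at
  `|d| = δ`). Neighborhood: 8 neighbors, weights 1 (axial) and 1/√2
  (diagonal); off-grid neighbors are omitted. The OSL denominator can turn
  non-positive when `β ∂U/∂f < −A'1`; it is clamped below at
  `ε · A'1` (ε = 1e-6). The clamp bounds the denominator, not the update,
  so OSL remains genuinely unstable for β beyond the clamp's reach — this
  is a property of the one-step-late scheme, and the practical stability
  boundary on the default protocol is noted below.
* **MAP-entropy (global)**: prior `−β Σ_j f_j ln f_j` with `γ = 1/β`.
  Multiplicative form `f ← f · exp(γ(A'(g/Af) − A'1))`, initialized at
  `f⁰ = 1/e`. Its fixed points coincide with the ML stationarity
  (`A'(g/Af) = A'1`); γ acts as a per-iteration damping factor, and
  regularization is exercised through damping plus a fixed iteration
  budget. The additive form `f ← exp(−1 + γ(A'(g/Af) − A'1))` is also
  provided; from `f⁰ = 1/e` its first iterate equals the multiplicative
  form's, and its fixed point satisfies the exact entropy-MAP stationarity
  `ln f = −1 + γ(A'(g/Af) − A'1)`, which the oracle tests verify by
  root-finding. Exponents are clamped to ±50 purely as an overflow guard.
* **MAP-entropy (local)**: the prior becomes `−Σ_k β_k Σ_{j∈C_k} f_j ln f_j`
  over a partition `C_k`, i.e. the multiplicative exponent is scaled by a
  per-pixel `γ_k`. The update rule is the per-region generalization of the
  global exponent; with all `γ_k` equal it is bitwise identical to the
  global algorithm. The partition is driven by an adaptive rule: outside a
  designated organ the global γ applies; inside it, all pixels start as
  "healthy", and from a switch iteration on, pixels whose estimate exceeds
  the healthy-tissue activity level times `(1 + margin)` are labeled "hot"
  and receive their own γ. The healthy level can be supplied (the study
  assumes it is known or estimable) or estimated as the organ mean
  excluding the top decile; labels are refreshed every iteration by
  default, or frozen at first assignment.

Stopping is by fixed iteration count only; statistical stopping rules and
data-driven choice of β/γ are out of scope.

## Empirical regularization defaults

The comparison protocol (OSEM checkpoints at passes 1/2/5; MAP checkpoints
at iterations 10/15/20) uses defaults chosen empirically on the default
phantom, mirroring how such parameters are set in practice:

* `map-gibbs`: rational-quadratic potential, `δ = 0.3` (activity units),
  `β = 0.03`. On this protocol the OSL scheme destabilizes for
  `β ≳ 0.05–0.1` at these δ (the clamp prevents sign flips but not
  blow-up), so β sits safely inside the stable region while still smoothing
  visibly.
* `map-ent`: `γ = 0.05` (`γ · A'1 ≈ 0.7` at the body-average sensitivity),
  giving near-convergence by iteration 20 without noise breakthrough.
* `map-ent-loc`: global `γ = 0.05`, `γ_healthy = γ/2`,
  `γ_hot = 2γ`, switch iteration 10, margin 0.1, healthy level = true
  liver activity. Healthy liver is regularized twice as strongly as the
  global setting while detected hot voxels are regularized half as
  strongly, which is what lowers tumor-ROI RMSE below both global MAP
  variants on the default protocol.

Reconstruction runs on the count scale; `δ` and the healthy level are
user-specified on the phantom activity scale and multiplied by the
count-scale factor internally, so the defaults are invariant to the
simulated count level.

## What the simulations do and do not show

The synthetic study commits an "inverse crime": the reconstruction model
is the same operator that generated the data (same attenuation, same
response), so resolution recovery is optimistic relative to real SPECT,
where the model mismatches the scanner. Scatter, randoms, detector dead
time, 3D effects, and anatomical variability are not modeled. Passing the
comparison tests therefore demonstrates the *relative* behavior of the
four regularization strategies under ideal modeling — noise progression in
unregularized EM, over-smoothing under global priors, improved hot-spot
error under local regularization — not absolute clinical image quality.

## Numerical choices and degenerate inputs

* `0 · ln 0 := 0` in all entropy functionals; the entropy gradient at zero
  pixels is never needed because entropy-family updates are multiplicative
  from strictly positive initialization.
* EM ratio bins with `ḡ_i = 0` contribute 0 to the backprojection; a bin
  with `ḡ_i = 0` but `g_i > 0` makes the log-likelihood `−∞` (impossible
  observation), reported as such.
* Zero-activity pixels are absorbing under MLEM/OSEM/OSL (multiplicative
  updates); entropy-family estimates stay strictly positive.
* A zero full-data sensitivity at a pixel with positive estimate is an
  error; zero *subset* sensitivity (OSEM) leaves the pixel unchanged for
  that sub-iteration.
* The dense-matrix builder (`SystemModel.dense_matrix`) is restricted to
  grids ≤ 32×32 and exists for test oracles.

## Problem sizes used in the test suite

Unit and oracle tests run on dense toy systems (≤ 4 pixels) and 8–16 px
grids. The end-to-end comparison tests run the full 128×128, 64-view
protocol: single-seed checks for EM monotonicity (50 iterations) and a
10-seed ensemble for the qualitative comparison (OSEM noise progression;
local vs global regularization at iteration 20), using majority-of-seeds
criteria since individual noise realizations vary.
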