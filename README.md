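# spectmap

Statistically regularized iterative image reconstruction for 2D emission
tomography (SPECT/PET), built around a comparison of global versus **local**
Bayesian regularization for hot-spot (tumor) imaging.

## The problem

Emission tomography reconstructs a radiopharmaceutical activity map `f` from
Poisson-distributed projection counts `g` related by a linear system model,
`E[g_i] = Σ_j a_ij f_j`, where `a_ij` is the probability that a photon
emitted in pixel `j` is detected in sinogram bin `i` (including attenuation
and collimator-detector blur). The problem is ill-posed: the clinical
standard OSEM (ordered-subsets expectation maximization) maximizes the raw
likelihood and degenerates into noise as iterations proceed, while maximum a
posteriori (MAP) methods with a single global regularization weight smooth
the whole image equally — and tend to flatten exactly the small hot lesions
oncology cares about.

`spectmap` implements four reconstruction algorithms behind one interface:

| algorithm | update | regularization |
|---|---|---|
| `mlem` / `osem` | `f ← f · A'(g/Af) / A'1` | none (early stopping only) |
| `map-gibbs` | one-step-late: `f ← f · A'(g/Af) / (A'1 + β ∂U/∂f)` | global β, Markov-random-field energy `U(f) = Σ_j Σ_{k∈c_j} w_jk V(f_j − f_k)` with edge-preserving potentials |
| `map-ent` | `f ← f · exp(γ (A'(g/Af) − A'1))`, `f⁰ = 1/e` | global entropy prior `−β Σ f ln f`, `γ = 1/β` |
| `map-ent-loc` | same, with per-pixel `γ_k` | **local**: region-wise `β_k` over a partition `C_k`, with an adaptive rule that detects hot voxels (estimate above the healthy-tissue level) and regularizes them separately |

plus everything needed to exercise them: a digital torso phantom (liver,
stomach, and a small tumor at 1.6× liver activity), a matrix-free
rotation-based projector with non-uniform attenuation and depth-dependent
detector response whose adjoint is exact to machine precision, seeded
Poisson data simulation, and a workbench that compares all four algorithms
on identical noisy data via activity profiles, ROI RMSE and tumor contrast
recovery.

## Worked example

```python
import spectmap as sm

spec = sm.ExperimentSpec(seed=0)        # default 128x128 liver phantom,
result = sm.run_experiment(spec)        # 64 views, 1e4 total counts
print(result.summary.to_string(index=False))
```

```
  algorithm  iteration  tumor_rmse  liver_rmse  contrast_recovery
       osem          1    0.534969    0.352270           0.847132
       osem          2    0.512656    0.499024           0.846373
       osem          5    0.762088    0.896300           0.908175
  map-gibbs         10    0.520719    0.365946           0.831946
  map-gibbs         15    0.530499    0.455529           0.737735
  map-gibbs         20    0.532275    0.509418           0.706296
    map-ent         10    0.563732    0.186526           0.759702
    map-ent         15    0.502556    0.209086           0.824113
    map-ent         20    0.463608    0.226580           0.869730
map-ent-loc         10    0.520434    0.085888           0.674354
map-ent-loc         15    0.456572    0.108215           0.748588
map-ent-loc         20    0.435211    0.131002           0.801739
```

Reading the table: OSEM's tumor-ROI RMSE *grows* from pass 1 (0.53) to pass
5 (0.76) — the unregularized iteration amplifies Poisson noise, so stopping
early is the only control. The globally regularized MAP variants are stable
over 20 iterations, and the locally regularized entropy MAP achieves the
lowest tumor-ROI error (0.435 at iteration 20) while keeping the healthy
liver an order of magnitude less noisy than OSEM (liver RMSE 0.13 vs 0.90).
Contrast recovery is the reconstructed tumor:liver ratio divided by the
true 1.6; 1.0 is perfect.

The same comparison is available from the shell:

```bash
spectmap compare --seed 0 --out runs/demo        # writes NIfTI images, CSV
spectmap simulate --seed 1 --out runs/sim        # profiles/metrics, PNG plots
spectmap reconstruct --sinogram runs/sim/counts.csv --config cfg.yaml --out runs/rec
```

## Layout

- `spectmap.phantom` — geometric phantom specs and rasterization
- `spectmap.projector` — system model (rotation + attenuation + response), adjoint, Poisson simulation
- `spectmap.priors` — Gibbs energies, potentials, entropy functionals, region maps
- `spectmap.recon` — the four iterative algorithms and the adaptive region rule
- `spectmap.workbench` — experiment driver, profiles, metrics, artifact output
- `docs/methods.md` — model assumptions, parameter choices, limitations
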