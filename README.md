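# idpreweight

Automated maximum-entropy reweighting of conformational ensembles against
heterogeneous experimental data, with latent-space metrics for comparing
ensembles.

## The problem

Intrinsically disordered proteins (IDPs) populate broad conformational
ensembles. Molecular dynamics (MD) simulations provide atomistic ensembles,
but their accuracy depends on the force field; experiments (NMR chemical
shifts, ³J couplings, SAXS) report ensemble averages that constrain, but do
not determine, the underlying distribution. Integrative refinement
reweights the simulated frames so that ensemble-averaged predictions match
experiment with the *minimal* perturbation of the prior — maximum-entropy
reweighting. The practical difficulty is balancing restraint strengths
across data types without hand tuning. This package automates that balance
with a single free parameter.

## The method

Frames `j` with prior weights `w⁰_j` are reweighted to

    w_j ∝ w⁰_j · exp(−Σ_i λ_i F_ij)

where `F_ij` is the forward-model prediction of observable `i` in frame
`j`. The multipliers λ minimize the convex dual functional

    Γ(λ) = ln Σ_j w⁰_j e^{−Σ_i λ_i F_ij} + Σ_i λ_i O_i^exp + ½ Σ_i λ_i² σ_i²

with per-point Gaussian error scales `σ_i = sqrt(σ_i,MD² + σ_reg²)`:
`σ_i,MD` is the statistical error of the prior-ensemble average (blocking
analysis of the per-frame series) and `σ_reg` is one regularization scale
per data type. `σ_i = 0` forces an exact match; `σ_i → ∞` switches the
restraint off.

The `σ_reg` values are calibrated automatically from the Kish ratio — the
normalized effective sample size `K = (Σ w_i)² / (N Σ w_i²)` of the
reweighted ensemble (`K·N` ≈ the number of frames that retain significant
weight):

1. estimate `σ_i,MD` for every data point by blocking analysis;
2. for each data type alone, find the smallest `σ_reg` whose reweighted
   ensemble keeps `K ≥ K_target` (default 0.10);
3. restrain with all data types, rescaling every per-type `σ_reg` by a
   common global factor, and find the smallest factor keeping
   `K ≥ K_target`.

Accuracy is scored by per-type RMSE, the normalized RMSE_N (ratio to a
reference ensemble), and leave-one-data-type-out cross-validation.
Ensembles are compared quantitatively by embedding all frames into one 2D
latent space (PCA on Cα–Cα distance features, or classical MDS on a
contact-map dissimilarity), estimating weighted densities (Scott-rule KDE
on an 80×80 grid, or 60-bin histograms) over a shared grid, and computing
the overlap integral

    S = ⟨D₁|D₂⟩ / (‖D₁‖‖D₂‖) ∈ [0, 1],

which is 1 for identical densities, 0 for disjoint ones, and whose square
converges to the Kish ratio when a reweighted ensemble is compared with its
uniform parent in the fine-bin limit.

## Worked example

```python
import numpy as np
import idpreweight as ir

# synthetic problem with known ground truth: 2000 frames, 3 data types,
# a biased prior, and noisy targets generated from tilted true weights
dataset, w_true = ir.default_fixture(seed=0)
prior = np.full(dataset.n_frames, 1.0 / dataset.n_frames)

result = ir.run_protocol(prior, dataset, kish_target=0.10)
print(f"final Kish ratio  K = {result.final.kish:.4f}")
print(f"effective frames  K*N = {result.final.kish * dataset.n_frames:.0f}")
for t, r in result.final.per_block_rmse.items():
    prior_r = ir.dataset_rmse(dataset, prior)[t]
    print(f"{t}: RMSE {prior_r:.3f} -> {r:.3f}")
```

Output:

```
final Kish ratio  K = 0.1000
effective frames  K*N = 200
type_0: RMSE 2.364 -> 0.022
type_1: RMSE 2.327 -> 0.022
type_2: RMSE 2.723 -> 0.025
```

The calibrated ensemble keeps 10% of the prior's effective frames (the
requested threshold) while cutting the misfit of every data type by two
orders of magnitude; `result.per_type_sigma_reg` and
`result.sigma_reg_global` hold the calibrated regularization scales, and
`result.scan_trace` the (σ, K, RMSE) curve of the global scan.

The same workflow is available from the shell:

```sh
idpreweight simulate --seed 0 --out-dir sim/
idpreweight calibrate --table sim/type_0_predictions.tsv --meta sim/type_0_meta.tsv \
    --table sim/type_1_predictions.tsv --meta sim/type_1_meta.tsv \
    --table sim/type_2_predictions.tsv --meta sim/type_2_meta.tsv \
    --out-dir run/
```

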