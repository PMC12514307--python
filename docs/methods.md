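# Methods

## Model

Reweighting starts from a prior ensemble: `N` frames with weights `w⁰`
(uniform for an unbiased MD trajectory). Each experimental data type forms
an *observable block*: per-frame forward-model predictions `F_ij` (frame
`j`, observable `i`), targets `O_i^exp`, per-point statistical errors
`σ_i,MD`, and one regularization scale `σ_reg` per block. The posterior is
the minimum-KL (maximum-entropy) distribution whose averages match the
targets within Gaussian errors. Marginalizing the per-point Gaussian error
variables analytically yields the dual problem

    min_λ Γ(λ) = ln Σ_j w⁰_j e^{−Σ_i λ_i F_ij} + Σ_i λ_i O_i^exp + ½ Σ_i λ_i² σ_i²

with `σ_i = sqrt(σ_i,MD² + σ_reg²)`, and the posterior
`w_j ∝ w⁰_j exp(−Σ_i λ_i F_ij)`. Γ is convex; at the optimum
`⟨F_i⟩ = O_i^exp + λ_i σ_i²`. The primal equivalent minimized implicitly is
`KL(w‖w⁰) + ½ Σ_i (⟨F_i⟩ − O_i^exp)²/σ_i²`, which the test suite verifies
directly by brute-force simplex optimization on small problems.

Assumptions: the prior samples all relevant conformational states (a
reweighting method can only reduce weights, not invent conformations);
errors are independent Gaussians per data point; forward models are
evaluated per frame and are exact up to the error budget absorbed by
`σ_i,MD` and `σ_reg`. Reported experimental uncertainties are typically
much smaller than these regularization terms; an optional `exp_error`
field is carried but excluded from `σ_i` by default.

## Numerical choices

* Optimizer: L-BFGS-B on (Γ, ∇Γ), initialized at λ = 0; convergence at
  gradient max-norm ≤ 1e-7 (default), iteration cap 5000. Posterior weights
  are formed by a log-sum-exp-shifted softmax, so no weight underflows to
  NaN even for |λ·F| of several hundred.
* Observables are not standardized: λ carries inverse data units so the
  `λσ²` slack stays interpretable in data units.
* Exact restraints (`σ_i = 0`) are screened by a necessary feasibility
  condition — the target must lie within the min/max range of the
  per-frame predictions over positive-prior frames — and rejected with the
  offending observable ids. Joint convex-hull membership across many exact
  restraints is not checked; a jointly infeasible set surfaces as
  non-convergence instead.
* Zero-weight prior frames contribute −∞ log-weight and can never regain
  mass; zero-weight frames are retained in all containers (discarding is a
  statement about weights, not storage).

## Error estimation

`σ_i,MD` reflects the statistical error of a per-frame prediction's
ensemble average over a correlated trajectory. The blocking method
repeatedly halves the series by pairwise averaging (a trailing odd element
is dropped); at each level the standard error of the mean is estimated as
`sqrt(c₀/(n_b − 1))` from the `n_b` block means (`c₀` their biased sample
variance), with Gaussian-approximation error bars `σ̂/sqrt(2(n_b − 1))`.
The selected value is the first level whose estimate agrees with the next
within one error bar (plateau); if no plateau appears before fewer than 8
blocks remain, the maximum over levels is used — a conservative choice
that avoids underestimating `σ_MD`. Series shorter than 8 points fall back
to the plain standard error of the mean with a warning.

## Calibration protocol

The only scientific knob is the Kish-ratio threshold `K_target`
(default 0.10): the fraction of the prior's effective sample size the
final ensemble must retain. Step 2 searches, for each data type restrained
alone, the smallest `σ_reg` with `K ≥ K_target`; step 3 searches the
smallest global factor multiplying all per-type `σ_reg` values (the factor
rescales `σ_reg`, not the composed `σ_i`, i.e.
`σ_i = sqrt(σ_MD² + (σ_reg,type · σ_global)²)`).

Search scheme: a 40-point log-spaced grid spanning `[1e-3, 1e3]` times the
block's data scale (median absolute prior misfit; the global factor grid is
dimensionless around 1), walked from the weak-restraint end downward with
warm-started multipliers until `K` first drops below target, then log-space
bisection of the bracketing interval to relative precision 1e-3 (≤30
steps). The feasible (upper) end of the final bracket is returned, so
`K ≥ K_target` holds for every successful run. `K(σ_reg)` rises steeply
and monotonically through the threshold region on all synthetic problems
examined; deep in the strong-restraint regime it can dip non-monotonically
by O(1e-3), which the bracketing scan is insensitive to because it only
needs the location of the threshold crossing. `K_target = 1` is handled
exactly: only uniform weights attain `K = 1`, so the prior is returned
with λ = 0.

## Validation

RMSE per data type; RMSE_N = RMSE / RMSE of a user-named reference
ensemble (the reference is a label, not a hard-coded force field); averaged
RMSE_N across types as a single quality index. Leave-one-out
cross-validation withholds one data type, reruns the *entire* calibration
from scratch on the rest (per-type σ_reg are not reused), and scores the
withheld type under the resulting weights, normalized by the prior's RMSE
on that type.

## Ensemble comparison

Frames of all ensembles to compare are embedded once into a shared 2D
latent space; reweighting then changes only the weights attached to the
embedded points. Two embeddings are provided:

* `pca` (default): PCA on Cα–Cα pairwise-distance features. Deterministic,
  dependency-light, and validated as giving results consistent with
  nonlinear energy-landscape embeddings for this purpose.
* `elvim_like`: classical MDS on a contact-map dissimilarity. Per frame,
  soft contact populations `q_ij = 1/(1 + exp((d_ij − d₀)/σ₀))` with
  `d₀ = ε · max(d)` (defaults σ₀ = 1, ε = 0.15); frames are compared by the
  mean absolute contact difference. Rigid-motion invariant by
  construction. External 2D coordinates can be imported instead
  (`method="external"`), since the overlap metric is embedding-agnostic.

Densities over the latent space: Gaussian KDE on an 80×80 grid spanning
the global extrema of the merged embedding, bandwidths by Scott's rule
with the weights' effective sample size `n_eff = 1/Σw² = K·N` in place of
the frame count (scipy's weighted KDE implements exactly this); or
histograms with 60 bins per dimension on shared edges. The overlap
integral is the normalized inner product of the flattened density vectors.
Interpretation limits: for a reweighted ensemble vs its uniform parent, S²
converges to the Kish ratio from above as bins are refined; for two
*independently sampled* ensembles, S decays to zero once bins far
outnumber the frames, so bin counts should stay comparable to the
effective ensemble sizes being compared. A stride-thinning utility
supports down-sampling trajectories before merging.

The α-helical order parameter Sα sums, over all consecutive 6-residue
windows, a rational switch `(1 − (r/r₀)⁸)/(1 − (r/r₀)¹²)` of the window's
best-fit RMSD `r` to an ideal α-helix Cα template (radius 2.3 Å, rise
1.5 Å/residue, twist 100°/residue; `r₀` = 1.0 Å). All template and switch
parameters are configuration; the Cα-only template is a deliberate
simplification of backbone-atom variants of this order parameter.

## Synthetic data

The generators define the study conditions for all end-to-end tests.
Frames are latent points from a 2D, 3-component Gaussian mixture with
prior component probabilities (0.6, 0.3, 0.1); the ground-truth ensemble
tilts these to (0.1, 0.3, 0.6), so the true weights are per-frame
probability ratios with Kish ratio ≈ 0.26 — comfortably above the 0.10
calibration threshold, making recovery feasible but non-trivial.
Observables are fixed random nonlinear maps of the latent coordinate
(linear + tanh terms), 3 blocks × 10 observables by default; targets are
true-ensemble averages plus Gaussian noise (sd 0.02, on an observable
scale of order 1). The default fixture uses N = 2000 frames — large enough
that a K = 0.10 calibration retains ~200 effective frames, small enough
for fast tests.

Not emulated: time correlation between frames (frames are i.i.d., so
blocking analysis reduces to the plain SEM there; correlated-series
behavior is tested separately with AR(1) generators), forward-model
systematic error, and geometric realism (the polymer generator produces
freely jointed Cα chains with no excluded volume or secondary structure).
Passing tests therefore demonstrate the statistical machinery — not that
any particular force field or forward model is accurate.

## Known limitations

* The two-stage calibration (per-type, then one global factor) does not
  jointly optimize per-type σ_reg; that matches its design goal of a
  single free parameter.
* Infeasibility detection for multiple simultaneous exact restraints is a
  per-observable necessary condition only.
* The contact-dissimilarity functional is a documented, fixed choice;
  published nonlinear embedding algorithms differ in detail, which is why
  external embeddings can be supplied.
* Success presupposes a reasonably accurate, well-sampled prior: if the
  prior assigns negligible probability to the experimentally consistent
  region, no reweighting can repair it (weights can only shrink, not
  create, conformations).
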