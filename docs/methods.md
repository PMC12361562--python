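# Methods

This note documents the statistical models implemented in `flournet`, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Data model and notation

Twelve items (0–10 response scale), two per flourishing domain, observed
for n_c respondents in each of C countries with survey weights w. All
inference consumes per-country weighted Pearson correlation matrices
R_c (12×12) with post-deletion sample sizes N_c. Respondents missing any
of the twelve items are removed listwise; weights are normalised to mean 1
(correlations are invariant to their scale). The effective N entering
likelihoods is the nominal complete-case count; the Kish effective sample
size (Σw)²/Σw² is available behind the `kish_n` flag but is not the
default, since the published χ² magnitudes are consistent with nominal
counts.

Edge vectors stack the 66 off-diagonal entries in lower-triangle
column-major order (pairs (j,i), j<i, ordered by column then row).

## Gaussian graphical models

A network is the partial-correlation matrix ω of a correlation matrix R:
ω_ij = −K_ij/√(K_ii K_jj) with K = R⁻¹. The inverse map rescales
(I−ω)⁻¹ to unit diagonal; both maps are exact inverses on the PD cone
(round trip ≤ 1e−12). Per-country edge significance uses the classical
partial-correlation t test, t = ω√((N−2−k)/(1−ω²)) with k = 10 conditioned
variables — deterministic, closed-form, and asymptotically equivalent to
information-matrix SEs at these sample sizes; model-based SEs are used
where the pooled analysis requires them (below). Thresholding at α = 0.05
zeroes non-significant edges without refitting; a prune-and-refit mode
exists but is off by default.

The ML discrepancy is F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p, χ² = (N−1)F, and
the log-likelihood uses the standard Gaussian convention
ℓ = −(N/2)(p ln 2π + ln|Σ| + tr(SΣ⁻¹)), so AIC/BIC magnitudes are
comparable across all models fitted to the same (S, N). Incremental fit
indices use the independence baseline (Σ = I, df = 66); the RMSEA 90% CI
inverts the noncentral χ² distribution.

## Measurement models

Six structures for Σ, all identified by fixing latent variances to 1:

| kind | Σ | free parameters | df |
|---|---|---|---|
| cfa6 | ΛΦΛᵀ + Θ | 12 + 15 + 12 = 39 | 39 |
| bifactor | λ_g λ_gᵀ + Λ_s Λ_sᵀ + Θ | 12 + 12 + 12 = 36 | 42 |
| second_order_g | ΛΦ(γ)Λᵀ + Θ, Φ = γγᵀ + diag(1−γ²) | 12 + 6 + 12 = 30 | 48 |
| latent_network | cfa6 with Φ = pcor⁻¹(Ω_lat), Ω_lat saturated | 39 | 39 |
| residual_network | λλᵀ + Δ(I−Ω_res)⁻¹Δ, Ω_res pruned | 24 + edges | ≥ 1 |
| ggm | Δ(I−Ω)⁻¹Δ, saturated | 66 + 12 = 78 | 0 |

Fitting minimises F by L-BFGS-B with analytic gradients
(dF = tr(G dΣ), G = Σ⁻¹(Σ−S)Σ⁻¹) from five deterministic starts: one
data-driven (loadings from within-domain correlations, factor correlations
from rescaled cross-domain means; the latent network additionally starts
from the cfa6 solution re-expressed through the pcor map) plus seeded
jitters. Convergence is flagged when the projected gradient exceeds 1e−4
or start values disagree by more than 1e−4 in F; non-PD implied matrices
receive a penalised objective value rather than an exception. Boundary
solutions (e.g. a second-order loading at 0.999, a Heywood-type case that
does occur on the published matrix) are reported, not hidden.

Notes on equivalences and identification:

- The saturated latent network reparameterises the free factor-correlation
  matrix, so cfa6 and latent_network share their optimum *whenever the
  cfa6 solution is admissible* (Φ positive definite). On data generated
  from a sparse GGM the unconstrained cfa6 ML solution can have an
  indefinite Φ; the latent network is then a genuine restriction and fits
  slightly worse. Equivalence tests therefore use admissible inputs.
- A saturated residual network under a single factor has 90 parameters for
  78 moments and is not identified. It is estimated by stepwise pruning:
  an initial edge pattern from the residual partial correlations of a
  quick single-factor fit (α = 0.05), surplus edges dropped
  least-significant-first until df ≥ 1, then up to three prune-refit
  rounds. Its convergence report surfaces any start disagreement.
- The saturated ggm is fitted in closed form (ω = pcor(S), δ rescaling the
  diagonal), F = 0, df = 0. The published comparison table shows a network
  row with df = 5 — five pruned edges not identified in the source text —
  which we document rather than imitate; `prune_refit=True` provides the
  pruned variant.
- Because an identified (pruned) residual network nests any sparse GGM
  with fewer parameters than the saturated one, it can undercut the
  saturated ggm by a few AIC points on sparse-network data; the pruned ggm
  then dominates both. The model-comparison tests check exactly that
  ordering.

## Random-effects MAGNA

For country c, the edge vector y_c = vech(R_c) is modelled as
y_c ~ N(ρ, V_c + T) with V_c the Isserlis/Pearson–Filon asymptotic
covariance of sample correlations evaluated at the pooled estimate and
divided by N_c, and T = diag(τ²). T is restricted to diagonal: a full
66×66 random-effects covariance is unidentifiable at C = 22, and only the
per-edge SDs are interpreted. Estimation is on the raw correlation scale
(pooling of raw sample correlations); a Fisher-z option is provided behind
a flag and agrees closely at these effect sizes.

The fit is two-stage marginal maximum likelihood. For fixed τ the fixed
effects have the exact GLS/ML solution ρ(τ) = (Σ W_c)⁻¹ Σ W_c y_c with
W_c = (V_c + T)⁻¹, so the optimiser works only on the 66 τ parameters
(L-BFGS-B, box [0, 0.8], started at the between-country SD minus the mean
sampling variance, truncated at 0) with the analytic profile gradient
∂(−ℓ)/∂τ_k = τ_k Σ_c[(W_c)_kk − ((W_c r_c)_k)²] from the envelope theorem.
The evaluation point of V_c is updated once at the pooled solution (two
outer iterations). τ estimates at the zero boundary are flagged, not
errors. This formulation is deterministic and desk-scale; it is the
marginal (two-stage) counterpart of a one-stage full-information fit, with
the same estimand — small numerical differences from a full-information
implementation are expected and documented rather than reconciled.

Uncertainty: vcov(ρ̂) = (Σ W_c)⁻¹ at the solution (τ treated as known, the
usual random-effects convention, which slightly understates variance at
small C). The pooled network ω̂ = pcor(ρ̂) gets delta-method SEs through a
numerical Jacobian of the pcor map (central differences, h = 1e−6), normal
95% CIs and p-values, and α = 0.05 thresholding. ML τ̂ is biased low by
roughly √((C−1)/C) at C = 22 (≈2%), visible in the recovery simulations.

The heterogeneity pre-test compares the saturated single-country model
(every country its own R_c; perfect fit; 66 parameters per country) with
the pooled saturated model (common matrix = N-weighted mean of the R_c,
the unrestricted common-covariance ML solution; 66 parameters) on AIC/BIC
computed from the full Gaussian log-likelihoods, BIC penalised by ln of
the total N.

## Centrality and the parametric bootstrap

Expected influence is the signed row sum of ω; predictability is
R²(i) = 1 − 1/[R⁻¹]_ii of the network-implied correlation matrix, which
equals the least-squares R² of node i on all others. The difference test
draws B edge-weight vectors from N(ω̂, vcov(ω̂)) — the unthresholded pooled
estimates by default, with a flag for the thresholded network — computes
both indices per draw (predictability via the pcor-inverse map per draw,
batched), and reports p = 2·min(P(diff<0), P(diff>0)) capped at 1 per node
pair. Zero proportions are floored at 2/B, the bootstrap resolution,
rather than reported as exact zero. The default B = 1,000,000 matches the
study; tests run at B = 10⁴–10⁵, where the Monte-Carlo SE of any p-value
is below 0.002 and significance decisions away from the threshold are
stable across B. The Bonferroni level is computed from the node-pair count
(0.05/66) and rounded to 4 decimals (0.0008), matching the reporting
convention.

## Synthetic generator

The generator draws, per country: true correlation structure = pooled
implied marginals + independent N(0, τ_e²) noise per edge (random effects
on the *marginal*-correlation scale, because the reported heterogeneity
SDs concern unconditional associations), projected to the nearest PD
correlation matrix (eigenvalue clipping at 1e−6, rescale to unit diagonal;
idempotent on PD inputs; projection distances logged, a warning when more
than half the draws need projection). Respondents are multivariate normal,
affine-mapped to mean 5/SD 2 on the item scale; clipping to [0,10] and
rounding to integer scores exist as stress-test options but are off by
default so inferential tests see exactly the assumed Gaussian model.
Missingness is injected MCAR at per-country rates drawn from the observed
0.1–1.7% range. Weights are log-normal with σ = 0.3 (design effect ≈ 1.09,
a moderate survey-weighting intensity chosen as a realistic stand-in — how
the real weights were constructed is not public), normalised to mean 1.
All randomness fans out from one seed through `SeedSequence`, so equal
seeds give bitwise-identical studies.

Default conditions mirror the study: 22 countries at the published sample
sizes (total 202,898), the published pooled network as truth, τ = 0.12 on
every edge (the reported average heterogeneity). One consequence worth
knowing: the published network is dense (smallest implied-marginal
eigenvalue ≈ 0.26), so at τ = 0.12 most perturbed draws need PD
projection, which compresses realised per-edge SDs to ≈ 0.11. Recovery
simulations therefore target the band 0.10–0.14 rather than 0.12 exactly.
With well-conditioned sparse truths the projection is rare and the
realised SD matches τ to Monte-Carlo accuracy.

What the generator does **not** emulate: ordinal response styles and
11-point discreteness (items are continuous Gaussians by default),
differential item functioning, non-MCAR missingness, and realistic
post-stratification weight construction. Passing recovery tests therefore
show that the estimator recovers the parameters of the model it assumes at
the study's scale — not that real survey data satisfy those assumptions.

## Numerical conventions and problem sizes

- PD checks via eigenvalue sign; singular inputs raise with the condition
  number; a 1e−10 ridge stabilises near-singular sampling covariances.
- Optimiser tolerances: ftol 1e−15/gtol 1e−10 (measurement models, needed
  for the cfa6/latent-network agreement at χ² resolution), gtol 1e−8
  (MAGNA τ). Line-search stalls are accepted only when the projected
  gradient is already negligible.
- Test problem sizes were chosen to exercise every claim at desk scale on
  one CPU: recovery at the full 22-country design over 100 replications,
  sampling-covariance validation against 10,000 Monte-Carlo datasets at
  n = 500, bootstrap difference tests at 10⁴–10⁵ draws.

## Known limitations

- vcov(ρ̂) conditions on τ̂; CI coverage of pooled edges runs ~0.93–0.95 in
  simulation at C = 22 (inside the accepted 0.90–0.99 band) rather than
  nominal 0.95 exactly.
- The residual network's stepwise pruning is a deterministic heuristic,
  not an exhaustive search; its reported convergence state should be
  inspected before interpreting it.
- The heterogeneity AIC/BIC comparison uses correlation-scale likelihoods;
  its information criteria are internally comparable but not numerically
  comparable to implementations that model full covariance matrices.
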