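# Methods

## Generating model

Data are simulated at the latent level. Independent standard normals
f₀, T, ζ₁…ζ₄, δ₁…δ₁₂ are combined as

    η_j = γ_j f₀ + τ_j T + ζ_j        j = 1..4
    Y_i = λ η_{j(i)} + δ_i            i = 1..12, three indicators per state

with ζ and δ scaled so that every state and every indicator has unit
variance; indicators are therefore marginally N(0, 1) and the population
covariance has the closed form

    cov(Y_i, Y_k) = λ²                      same state
    cov(Y_i, Y_k) = λ² (γ_j γ_m + τ_j τ_m)  states j ≠ m.

Defaults: λ = 0.8, γ = (0.4, 0.4, 0.4, 0.4), τ = (0, 0, 0.4, 0.4), f₀ ⟂ T.

**Why 0.4.** The magnitudes of the structural paths are the one knob the
design leaves open, and they control how badly the multistate model
(Model 1) misfits. They were set, before any percentage-level runs, by a
noncentral-χ² calculation to make Model 1 a *mild* misspecification: its
population RMSEA is 0.052 — inside (0.01, 0.08), so Model 1 still "passes"
the RMSEA convention — while its exact-fit test and the Δχ² comparison
reject essentially always from n = 500 on. Smaller values (e.g. 0.25)
give a population discrepancy so small that the Δχ² test has only ~73%
power at n = 500, which contradicts the operating characteristics the
study is built to exhibit.

**Likert coarsening.** Continuous scores are cut at k−1 equally spaced
thresholds dividing [−3, 3] into k equal intervals (k ∈ {3, 5, 7});
values beyond ±3 are clamped into the extreme categories, so there are no
missing data. Symmetric thresholds on symmetric data keep the response
distributions skew-free by construction. Correlations are then computed
on the raw category codes (product-moment, deliberately not polychoric:
the resulting attenuation *is* the range-restriction threat under study).

**Seeding.** Every replication draws from
`SeedSequence(base_seed, spawn_key=(condition, replication, attempt))`,
so runs are bit-reproducible, replications are independently re-runnable,
and a replication whose categorized sample has a zero-variance column
(possible at n = 100, k = 3) is resampled with the next attempt index and
counted, keeping the replication count per cell exact.

## Model specifications

Both models are declarative free/fixed parameter tables over

    Sigma(theta) = Lambda (Gamma Phi Gamma' + Psi) Lambda' + Theta.

Model 1: four orthogonal states, factor variances fixed to 1, 12 loadings
and 12 error variances free (24 free, df 54). Orthogonality matters: if
Model 1 freely correlated its states, Model 2 would be nested inside it
and could never fit better.

Model 2: f₀ → η₁..η₄ with the η₁ path fixed at 1, T → η₃, η₄ with the η₃
path fixed at 1, var(f₀) = var(T) = 1 (the four unit constraints), first
loadings of η₂ and η₄ fixed at 1 as reference indicators, everything else
free: 30 free parameters, parameter-count df 48. The generating
population lies exactly in this family (the package tests this to 1e−10),
so Model 2 is correctly specified throughout the study.

## The identification subtlety

The threat factor connects only two states, and both of those states keep
free disturbance variances. At the level of implied moments, T's
contributions t₃²·var(T) and t₄²·var(T) to the state variances are
indistinguishable from ψ₃ and ψ₄; the only moment that identifies a
threat parameter is the cross-block excess t₃t₄·var(T). Consequently the
Jacobian of vech Σ(θ) has rank 29, not 30 — a one-dimensional ridge of
parameter vectors implies the identical covariance matrix — and this is
intrinsic to the model class: no admissible re-gauging consistent with
the four unit constraints removes it while keeping the generating
population in the family (we checked fixing both threat paths, reference
loadings on η₃, and freeing var(T)).

The package therefore distinguishes two df notions. `count_df` is the
naive count, p(p+1)/2 − #free (48 for Model 2); `effective_df` subtracts
the Jacobian *rank* instead (49), and the fit statistics use the
effective value. The distinction is not cosmetic: simulated χ² values for
Model 2 at n = 750–1000 have mean ≈ 49.2 and variance ≈ 100 over 1000
replications — a χ²(49), not a χ²(48) — and referring them to df 48 would
depress exact-fit acceptance to ≈ 92.5% where a calibrated test sits at
95%. The Δχ² test between the models accordingly uses Δdf = 54 − 49 = 5.
(Published tables in this literature report Δdf = 3, implying a Model 2
with df 51; no parameterization consistent with the stated model
structure and constraints yields that count, so the package uses the
value its own specifications imply.)

## Estimation

The ML discrepancy F(S, Σ) = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimized by
L-BFGS-B with the analytic gradient dF/dθ_k = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹) ∂Σ/∂θ_k],
where the ∂Σ/∂θ_k are assembled in closed form per parameter role.
Variance parameters are log-transformed, so positivity holds by
construction. Start values are deterministic (loadings 0.7 × the sign of
the correlation with the factor's first indicator, variances 0.5, paths
0.3). Tolerances: gradient 1e−8; a full-memory BFGS polish runs when the
L-BFGS-B line search stalls short of that, and one jittered restart is
attempted on outright failure. A fit that still fails is returned with
`converged = False` — never an exception — and excluded from percentage
denominators (with the attempted count reported alongside). Under the
study's conditions non-convergence is rare (0 of 1000 at n ≥ 500
continuous in the calibration runs); a multistart audit (6 extra random
starts, 60 replications) found no lower minima than the default path.

The sample Pearson correlation matrix is treated as a covariance matrix
with χ² = (n−1)·F̂ — the classic convention, statistically non-ideal for
ordinal codes, but that defect is part of what the study measures. For
these models the implied family is invariant to per-variable rescaling,
so fitting the correlation rather than the covariance matrix changes
nothing about the statistic.

Decision rules: exact fit accepts when the χ² p-value ≥ α = 0.05 (α is a
package choice; it matches the ≈95% acceptance of the correctly specified
model); RMSEA passes when strictly below 0.08; the Δχ² test refers
χ²₁ − χ²₂ to χ²(Δdf) at α = 0.05 and is only valid when both fits
converged.

## Monte Carlo harness

The default grid crosses n ∈ {100, 500, 750, 1000, 5000} with
{3, 5, 7, continuous} — 20 cells — at 1000 replications per cell,
overridable for desk-scale work. Each cell aggregates five percentages:
exact-fit acceptance per model, Δχ² significance, and RMSEA < 0.08 per
model. The acceptance script and the heavier tests use 300 replications
per cell, which puts ~3-percentage-point Monte Carlo error bars (3 SEs)
on percentages near 95 and keeps a cell run in the tens of seconds.

## Design algebra

The `design_algebra` module is a self-contained account of *why* a threat
is detectable in the first place. Crossing occasion (pre f₀ / post f₁)
with group (control / experimental) gives a 4×4 moment table; under the
classical-test-theory null — observed = true + error, one stable true
score per unit, no treatment, no threat — five of its moments (set A) and
three more (set B) are equal. The simulator draws per-unit true scores,
adds cell-specific measurement error, and optionally adds independent
treatment/threat shifts to the experimental post-test; `check_equalities`
is a descriptive, scale-invariant tolerance check (default 5% relative),
not a formal multigroup SEM test — the formal version is exactly the
multigroup extension the simulation study defers.

Two regimes are worth distinguishing. With `error_var = 0` (perfectly
reliable measurement) the null design satisfies both sets exactly, and
the package's strict checks run there. With `error_var > 0`, variances
inflate by the error variance while covariances do not, so set A — which
mixes both — fails: unreliability itself masquerades as a design
violation, which is the module's way of showing that the equalities are
statements about true scores, not raw observed scores. An independent
shift on the experimental post-test leaves both sets intact and surfaces
only in that cell's variance, localizing the disturbance.

## What the simulations do and do not show

The generator reproduces the study's stated conditions: multivariate
normal latent structure, equal loadings, symmetric categorization, exact
replication counts. Real questionnaire data violate most of this —
unequal loadings, skewed and floor/ceiling-afflicted items, missingness,
non-normal latents — so passing results here say the *decision rules
behave as advertised under the ideal generating model*, not that they are
robust. Known limitations: percentages for n = 100 cells and for
exact-fit acceptance under coarse categorization depend heavily on
estimator-era convergence behavior and are not stable reproduction
targets; polychoric-based estimation, skewed thresholds, multigroup
designs and mean structures are out of scope.
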