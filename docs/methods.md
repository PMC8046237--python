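# Methods

This note documents the statistical models implemented in `epicmap`, the
calibration of the synthetic cohort generator, the numerical choices that
matter, and what the test suite does and does not demonstrate.

## The mapping problem

EPIC summarises prostate-cancer HRQoL as 0–100 scores (four domains;
ten function/bother sub-domains; higher = better), obtained from Likert
items by the linear transform `100·(raw − min)/(max − min)`. EQ-5D-3L
describes health on five dimensions at three levels; a value set converts
each of the 243 states into a utility anchored at 1 for state 11111.
A mapping algorithm predicts the EQ-5D utility from EPIC scores and
optional covariates (age, race, Zubrod performance status, PSA category),
so trials that collected only EPIC can feed cost-utility models.

Utilities in this population are strongly ceiling-inflated: roughly 55 %
of patients report full health exactly, and the remainder cluster near
0.8. This mixture shape is what motivates comparing OLS against
censoring-aware alternatives.

## Functional forms

**OLS.** Direct linear mapping, always with an intercept. The residual
scale exposed is the maximum-likelihood `σ̂ = √(SSR/n)` so that the
censoring-free Tobit reduction is an exact identity.

**Upper-censored Tobit.** `y = min(y*, 1)` with `y* ~ N(x'β, σ²)`.
Observations recorded exactly at 1 contribute `log Φ((x'β − 1)/σ)` to the
log-likelihood; all others the normal log-density. We treat *exact
equality with 1* as censoring: the tariff returns exactly 1.0 only for
full health, so no tolerance band is needed, and legitimately
supra-ceiling responses in synthetic data are not mis-flagged.
Optimisation is BFGS over `(β, log σ)` — the log parameterisation keeps
σ positive — from OLS start values, with the analytic gradient; the
Hessian at the optimum (numerically differentiated) gives Wald standard
errors. Three prediction policies are exposed: the latent mean `x'β`,
`min(x'β, 1)` (the default — published Tobit prediction maxima of exactly
1.00 are consistent with a hard truncation), and the closed-form censored
expectation `E[min(Y*,1)] = x'β·Φ(α) − σφ(α) + 1·(1 − Φ(α))` with
`α = (1 − x'β)/σ`.

**Two-part.** Part 1: logistic regression on the indicator `y = 1`;
part 2: OLS on the strict subset `y < 1`. Predictions recombine as the
unconditional expectation `p·1 + (1 − p)·ŷ₂`. The recombination rule is a
modelling choice of this package (the alternative — reporting the parts
separately — does not yield a single mapped utility). Degenerate inputs
are handled explicitly: no ceiling cases ⇒ `p ≡ 0` and the model *is*
part 2; all ceiling cases ⇒ estimation error (part 2 unidentified);
perfect separation in part 1 is flagged (`part1_converged_ = False`, BFGS
coefficients retained) rather than raised.

**Design groups.** Group 1/3/5 use the four domains, 2/4/6 the ten
sub-domains; 3–4 add age and race, 5–6 add Zubrod and the PSA ≥ 4
indicator. Polynomial columns are literal powers of the 0–100 scores and
of age in years (no centering — the published full model prints raw
polynomial coefficients), and interactions are literal products. The
group-6 design with a cubic in age and score×Zubrod products spans exactly
the 26 regressors of the built-in full model, which the tests verify by
signature comparison.

**Forward stepwise.** Entry requires the smallest candidate p-value below
`sle = 0.25`; after each entry, included regressors with p above
`slstay = 0.25` are removed worst-first. P-values are t-tests (OLS) or
Wald tests (Tobit); for the two-part form a candidate's entry p-value is
the *smaller* of its two parts' p-values, so a regressor informative for
either the ceiling probability or the sub-ceiling mean can enter — a
package choice, documented here because the convention is not fixed in
the literature. Ties break by canonical column order, making selection
deterministic. Weak hierarchy is enforced by default: a product column may
enter only while both parents are included (and leaves when a parent
leaves); `hierarchy=False` overrides. Note that with an entry threshold of
0.25 a pure-noise candidate still enters in roughly a quarter of
replicates — that is the threshold working as specified, not a defect.

## Performance assessment

The analyzable cohort splits 70/30 into estimation and validation samples;
the estimation size is `ceil(0.70·n)` (1,092 records give 765/327, with a
float-fuzz guard so e.g. `0.7·1090` does not round up spuriously). K-fold
cross-validation (default k = 5; k = n is leave-one-out) assigns folds by
slicing a seeded permutation into contiguous blocks, remainder one per
fold; when the table carries an `id` column records are ordered by it
first, so reports are invariant to row order. Each fold's predicted
residual sum of squares (PRESS) is summed over folds before dividing:
`RMSE = √(Σ PRESS_k / n)` — with unequal folds this weights folds by size,
unlike averaging per-fold RMSEs. MAE is the mean absolute held-out
residual; it is reported alongside RMSE but model ranking uses RMSE
(ascending, ties broken by fewer regressors then label). External
validation scores a frozen model with no refitting, using the population
(biased) mean square so that a constant model at the observed mean scores
exactly the outcome's population SD. Rendered reports show
cross-validation RMSE to 5 decimals and validation RMSE to 6, matching the
conventional table formats; full precision is kept internally.
Bland–Altman limits are `mean(d) ± 1.96·SD(d)` with `d = predicted −
observed`.

## Synthetic cohort generator

A Gaussian copula joins one utility margin and fourteen EPIC margins.

*Utility margin.* Mixture: point mass `p = 0.55` at exactly 1, otherwise a
Beta on `[0.28, 1)` whose two moments are solved so the overall mixture
has mean 0.90 and SD 0.13; the implied Beta(≈6.7, ≈3.0) has its mode at
≈0.81, reproducing the observed second peak near 0.8. Non-ceiling draws
are kept strictly below 1.

*EPIC margins.* Each score is a **censored** (clipped) normal on [0, 100]:
`x = clip(μ + σz, 0, 100)`, with `(μ, σ)` solved by least squares so the
censored mean/SD equal the target mean/SD exactly in population. Clipping
(rather than truncation) is deliberate: real EPIC scales pile up at 100
(and sexual scales at 0), and a truncated normal on [0,100] cannot reach
the sexual-bother SD of 32.9 at mean 64 (the uniform limit caps near
28.9), while a censored normal can.

*Dependence.* Only utility–score Pearson correlations are prescribed
(on the observed scale). For each pair the latent copula correlation is
found by Brent root-finding on a fixed 20,000-draw reference panel — a
deterministic calibration device, separate from the per-run seed — so the
*observed* correlation hits its target (calibration error ≈ the panel's
sampling noise, well inside the ±0.05 test bands). Score–score latent
correlations are not reported anywhere; they default to 0.4 within the
instrument. This placeholder is user-overridable and is the main
structural assumption of the generator. The assembled matrix is checked
for positive definiteness and, if needed, projected to the nearest
positive-definite correlation matrix; if the projection moves any
utility–score entry by more than 0.02 the parameters are rejected as
jointly infeasible.

*Demographics.* Age ~ N(66.4, 7.3²) clipped to [40, 90]; race-other,
Zubrod-1 and PSA ≥ 4 are independent Bernoulli draws at rates 0.175,
0.062, 0.797. Demographics are independent of the HRQoL block — a known
simplification (see limitations).

*Linear-truth harness.* For estimator-recovery tests,
`generate_linear_truth` draws `y* = β₀ + x'β + N(0, σ)` with iid
standard-normal regressors, optionally censored at 1. The defaults
(`β₀ = 1.0`, `β = (0.15, −0.08, 0.05)`, `σ = 0.1`) place the latent mean
exactly at the ceiling, giving ~50 % censoring — inside the 40–55 % band
the recovery checks target.

*What passing tests show.* Calibration tests demonstrate that the
generator reproduces the prescribed *marginals and pairwise
utility–score correlations* — not that it reproduces real trial data.
In particular the conditional mean E[utility | scores] induced by the
copula is only approximately linear; the within-EPIC correlation of 0.4
is invented; demographics carry no HRQoL signal (so covariate terms in
fitted models are genuinely null in synthetic cohorts); and there is no
item-level or longitudinal structure. The cross-validation finding that
OLS outperforms Tobit on these cohorts mirrors the mechanism claimed for
the real data (misspecification of the latent normal under a
ceiling-inflated mixture) but is a property of the synthetic conditions.

## Numerical choices

- Tobit convergence: BFGS success, or a gradient-norm fallback (BFGS can
  report precision loss while already at the optimum); an unconverged fit
  withholds coefficients and predictions.
- Rank checks precede every fit; collinear columns are named via pivoted
  QR.
- Ceiling detection everywhere is exact equality with 1.0 (see above).
- Utilities are hard-bounded above by 1 only; negative utilities are legal
  (states worse than dead).
- Stepwise ties break by canonical column order; the candidate sweep keeps
  the earlier column on exact p-value ties.
- Acceptance-script problem sizes: 100 replicates of n = 565 for the mean
  (the replicate structure averages away single-cohort noise) and one
  n = 10,000 cohort for the SD, ceiling percentage and correlations —
  sizes at which the Monte-Carlo error is several times smaller than the
  reporting tolerances.

## Known limitations

- The packaged value set is a synthetic stand-in with the published US
  valuation's *structure*, not its coefficients; production scoring
  requires loading a transcribed published tariff.
- Candidate mapping algorithms beyond the two printed equations are not
  shipped (their coefficients are not published in the main text); the
  registry and JSON model format are the extension point.
- The generator's within-EPIC dependence and independent demographics are
  placeholders, documented above.
- No uncertainty intervals around mapped utilities (no published
  variance–covariance matrices to build them from).
- EQ-5D-5L, 3L↔5L crosswalks, and non-US value sets are out of scope as
  built-ins (loadable as data).
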