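# Methods

## The problem

Cross-sectional surveys such as HINTS record, for each respondent, whether a
health-care provider ever encouraged them to use an online medical record
(Z, binary), how often they accessed it in the last 12 months (D, five
ordered bands: 0 / 1–2 / 3–5 / 6–9 / 10+), and 5-point Likert self-efficacy
items (Y). Whether portal usage *causes* higher self-efficacy cannot be read
off an association: demographics and socioeconomics (X) influence all three
variables, unmeasured traits (U) may influence both D and Y, and the
direction of causality between D and Y is itself unknown.

The package treats encouragement as an instrument in an encouragement
design and adds two components around standard IV estimation:

1. a **causal-direction testing framework** based on the fixed causal
   diagram Z → D → Y (or Z → D ← Y), with X observed and common to all
   three, and U latent between D and Y; and
2. **effect estimation** as the Angrist–Imbens compliance-weighted average
   of per-unit effects for the multi-valued ordinal treatment, via TSLS.

## Direction testing

Two conditional-independence hypotheses are tested:

* **Test A**: Z ⫫ Y | X, D. If Y causes D, then D is a collider on
  Z → D ← Y and conditioning on it opens the path, so Test A rejects.
* **Test B**: Z ⫫ Y | X. If D causes Y, the chain Z → D → Y is open, so
  Test B rejects.

The (A, B) rejection pattern maps to a four-way verdict: (retain, reject) →
treatment causes outcome; (reject, retain) → outcome causes treatment;
(retain, retain) → inconclusive; (reject, reject) → reported as its own
`both_rejected` category with an unobserved-confounding caveat, because
simultaneous rejection is the signature of U acting through the collider at
D. α = 0.05 throughout, matching the significance level conventional for
the overall test.

**Test construction.** The default statistic is a 1-df likelihood-ratio test
nested in a proportional-odds (cumulative-logit) model of Y on the
conditioning set: confounders enter one-hot with a first-level reference; D
enters Test A as a linear 0–4 score by default (a dummies option exists;
the linear score preserves degrees of freedom when high-usage cells are
sparse). The model is fit by an in-package analytic-gradient MLE (L-BFGS-B,
thresholds parametrized as level-1 plus log-spacings), warm-starting the
full model from the nested one; this runs ~30× faster than generic ordinal
MLE wrappers, which matters because the calibration experiments refit it
thousands of times. Non-convergence falls back to the efficient score test
at the restricted MLE (observed information by finite differences of the
analytic gradient), logged. A constant instrument short-circuits to
statistic 0, p = 1.

The robustness alternative keeps the same statistic but permutes Z within
strata of the conditioning set (exact joint-level strata when coarse enough,
otherwise deciles of an estimated propensity of Z given the conditioning
design), with the add-one Monte-Carlo p-value (1 + #{perm ≥ obs})/(1 + B),
B = 2000 by default.

Both tests of a pair run on the identical row set (complete in Z, D, Y, X
after imputation) so their p-values are comparable.

## Effect estimation

The estimand is β = Σ_j ω_j E[Y(j) − Y(j−1) | D(1) ≥ j > D(0)] with
ω_j ∝ P(D ≥ j | Z=1) − P(D ≥ j | Z=0), the weighted average of per-unit
effects over compliers at each treatment step. It is estimated by TSLS with
Y numeric on the 1–5 Likert scale (the only coding under which the estimate
reads as "Likert points per usage level"), the confounders one-hot in both
stages, and heteroskedasticity-robust (HC0) sandwich standard errors by
default (homoskedastic optional; the sandwich uses stage-2 residuals formed
with the observed D). With no covariates the estimate equals the Wald ratio
exactly. Weights are estimated by the empirical CDF differences; small
negative estimates (sampling noise under monotonicity) are flagged, never
clipped. First-stage strength is reported as the partial F (squared t) of Z.

`verify_weighted_identity` is a diagnostic that simulates from the
structural model, where potential values are stored, and compares the
Monte-Carlo mean of TSLS against the ground-truth ω-weighted per-unit
effect.

## Missing data

Respondents missing the analysed outcome are discarded; a missing
instrument response is conservatively recoded as "no encouragement";
missing confounders are completed by chained equations (per-variable
multinomial-logistic conditionals on the instrument and the other
confounders, stochastic draws from the fitted distribution, 10 sweeps,
ascending-missingness visit order, single completed dataset by default —
there is no evidence multiple-imputation pooling is needed for the
downstream tests, which take one completed table). Treatment missingness
has no stated rule in the study design; such rows are kept in descriptives
and excluded from tests and TSLS with a logged count. The imputer never
alters an observed cell and is reproducible given its seed.

## The synthetic survey generator

The generator is a structural causal model producing (table, ground truth)
pairs. X is drawn from stated marginals; Z is Bernoulli with a logistic
index in standardized X codes; latent treatment and outcome indices are
linear in standardized X, U ~ N(0,1), and logistic noise (normal optional),
discretized by fixed cutpoints. Monotone compliance D(1) ≥ D(0) is exact by
construction: the treatment noise is shared across the two counterfactual
instrument arms and the instrument coefficient is constrained ≥ 0.
Potential outcomes Y(j) are stored for every level j, making estimands
computable from ground truth. The reverse scenario generates Y without D
and feeds the realized (centred) Y back into the treatment index; it is
mutually exclusive with a nonzero forward effect.

**Calibration.** Defaults are fixed once against the published survey
margins: P(Z=1) ≈ 0.43; α_Z and the first treatment cutpoint solve the
never-user rates by arm (0.90 not encouraged, 0.40 encouraged); remaining
cutpoints match the overall usage margins, giving a 49/31/10/9 split among
users. On the outcome side the cutpoints are evenly spaced (spacing 1) and
the noise scale is σ_Y = 0.22, solved so that the observed-scale weighted
estimand equals the configured τ (0.1396 at τ = 0.14; 0.2982 at τ = 0.30,
at 4M draws). This is the load-bearing numerical choice: discretizing a
latent index compresses effects, so without this calibration a latent τ
would not equal the Likert-scale estimand that TSLS targets, and coverage
statements about τ would be meaningless. A side effect is that the
generated Likert margins are more peaked than the survey's outcome
margins — usage margins are matched exactly, outcome margins are not.

**Presets** (all n = 3200): `forward_null` (τ=0), `forward_weak` (τ=0.14,
the published effect size), `forward_strong` (τ=0.30), `forward_confounded`
(τ=0.14 with κ_U=0.6, λ_U=0.5 — naive OLS is visibly biased, TSLS is not),
`reverse` (δ=0.30 feedback of Y on D), and `heterogeneous` (step effects
0.1/0.3/0.5/0.5, for the weighted-identity check). Forward presets
randomize Z (γ_ZX = 0): with Z marginally independent of X the population
Wald identity holds exactly, which is what makes the estimator's bias and
coverage checkable against τ. The reverse preset keeps Z dependent on X
(γ_ZX = (−0.2, 0.35, 0.4)) so that, under the null of Test B, conditioning
on X is genuinely required — a stricter calibration check than a fully
randomized null. Presets carry survey-like MCAR missingness (2.5% outcomes,
2% instrument, 1% treatment, 3% confounders); the Monte-Carlo experiment
harness zeroes these by default because the properties it certifies
(type-I error, coverage, verdict recovery) concern the tests and estimator,
not the imputer, and refitting chained equations inside every replicate
would dominate runtime.

The generator emulates margins and causal structure, not the survey's
sampling design: no strata, clustering, weights, or jackknife replicates,
and MCAR rather than differential nonresponse. Passing tests therefore
certify the statistical machinery under the stated conditions, not
robustness to informative sampling or informative missingness.

## Experiment sizes and numerical choices

Calibration experiments use 500–1000 replicates at the survey scale
(n = 3000–3200), sized so binomial Monte-Carlo standard errors are ≤ 0.016
for rates near 0.05–0.5 while a full run stays in minutes on one core.
Chi-square expected counts of zero are hard errors advising level pooling;
expected counts below 5 warn. LRT statistics are clipped at 0 (warm starts
make tiny negative values a numerical impossibility beyond 1e-6).
p-values print in journal style (".001", "<.001" below 5e-4). The TSLS
first stage errors out below |coef| < 1e-8; collinear covariate columns are
dropped with a warning via a QR sweep. All randomness flows through
`numpy.random.default_rng` seeds; identical (config, seed) pairs are
byte-reproducible end to end, including the pipeline's JSON report.

## Known limitations

* The exact test construction behind the study's printed "overall" p-values
  is not public; the proportional-odds LRT and stratified permutation test
  implemented here satisfy the same hypotheses but need not reproduce those
  p-values numerically, and the respondent-level survey file is not shipped.
* Test A's validity for the forward direction degrades when U is strong
  (D is then a collider even in the forward model); the
  `forward_confounded` preset exists to quantify that distortion rather
  than hide it — expect `both_rejected` verdicts there.
* The proportional-odds model is used as a working model for the
  conditional law of Y; the permutation variant guards against its
  misspecification but both condition on the same design.
* Single imputation understates confounder-imputation uncertainty in
  downstream standard errors; with the study's ~3% confounder missingness
  the effect is negligible, but heavy missingness would call for proper
  multiple-imputation pooling.
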