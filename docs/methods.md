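# Methods

## The choice model

The response is the choice rating on the six-point no-zero scale, treated
as numeric on {−3…−1, 1…3}; the midpoint of this scale is 0.  The three
utility regressors are constructed per trial as

* instrumental = usefulness rating (−3…+3),
* hedonic = feel-if-know − feel-if-not-know (−6…+6),
* cognitive = think-frequency rating (−3…+3),

and each is mean-centred within participant × timepoint before modelling
(centring changes only the intercept of any per-subject regression; slope
invariance is tested).  The expectation rating is sign-flipped for
negative-valence items so that high always means "expects good news"; it is
carried as a descriptive covariate but does not enter the choice models.

Two estimators operate on this table:

1. **Per-participant OLS** of choice on the three utilities (intercept +
   three slopes), requiring at least 4 trials and a full-rank design; a
   rank-deficient design (any constant utility column) flags the
   participant instead of emitting weights, mirroring the zero-variance
   exclusion.  These per-subject triples (β1, β2, β3) feed the dominance,
   stability and psychopathology analyses.
2. **A crossed linear mixed model** with the utilities as fixed effects,
   by-participant random intercept and slopes, and a by-item random
   intercept.  Participants and items are fully crossed, so the model does
   not factor into independent groups.

### Mixed-model estimation

The solver (`infoseek._lmm`) maximises the profiled likelihood: with
`V* = I + Z Λ² Z'` (Λ the relative random-effect scales), both the fixed
effects and the residual variance have closed forms given Λ, leaving an
optimisation over 5 log-scale parameters (diagonal by-participant
covariance — one variance per random term — plus the item variance).
Cross-products (Z'Z, Z'X, …) are computed once; each likelihood evaluation
costs one dense Cholesky of a q×q matrix, q = 4·n_subjects + n_items.  A
fit at 300 participants × 40 trials takes ~2 s on one core.  The optimiser
is L-BFGS-B with a Nelder–Mead polish on abnormal termination; a fit that
still fails is returned with `converged=False`, never dropped silently.
The solver is validated against statsmodels `MixedLM` (variance-components
formulation of the same crossed structure) on small fixtures, where the two
agree in fixed effects to ~1e-3 with our optimum at least as high in
likelihood.

Estimation is maximum likelihood (not REML) whenever fits enter the model
comparison, because the candidate models differ in fixed effects; a
`reml=True` flag is available for reporting final estimates.  The
by-participant random covariance is diagonal by default — more robust on
40-trial subjects — with an unstructured (Cholesky-parameterised)
alternative by flag.  Fixed-effect t tests use Satterthwaite-type
approximate degrees of freedom computed numerically from the observed
information of the deviance in the variance parameters (the lmerTest
construction); df are therefore fractional, and the method is recorded on
the fit.

### Model comparison

The candidate space is the 7 nonempty subsets of the three utilities plus,
when confidence ratings are present, the 8 specs containing confidence
(confidence alone and each utility subset augmented with it) — 15 in all.
Every fit stores (logLik, k, n_obs) and recomputes AIC = 2k − 2·logLik and
BIC = k·ln(n_obs) − 2·logLik from them; a mismatch fails the fit's
self-check.  k counts fixed effects plus variance components including the
residual.  n_obs is the number of trial-level observations; BIC rankings
depend on this convention, so it is fixed and documented here.  Fits over
different observation sets refuse to rank.  Non-converged fits are listed
apart from the ranking.

## Dominance classification

Weights are compared by absolute magnitude by default: a negative weight
(an avoidance-driving motive) is as strong a motive as a positive one, and
ratio rules on signed values are ill-defined for mixed signs.  With
magnitudes m1 ≥ m2 ≥ m3: tier "twofold" when m1 ≥ 2·m2, else "one_25" when
m1 ≥ 1.25·m2, else none.  Exact equality at a threshold counts as meeting
it; ties for the largest magnitude yield no dominant motive.  A signed
comparison mode exists for sensitivity analysis; classification is
invariant to positive rescaling of the triple.

## Stability

Per-participant movement between timepoints is the Euclidean distance
between weight triples, √((x2−x1)² + (y2−y1)² + (z2−z1)²) over
(instrumental, hedonic, cognitive).  The permutation null re-pairs T1
triples with a uniform random permutation of T2 triples that has no fixed
point, so every participant is genuinely mismatched (rejection sampling;
an unrestricted-permutation flag exists for sensitivity).  The observed
pairing is not included in the null set.  Reported: the proportion of
iterations whose permuted mean distance exceeds the observed mean, and the
mean and range of the permuted-minus-observed differences.  The statistic
is invariant to adding a constant vector to every participant's weights at
both timepoints.

ICCs are computed per motive after profile-centring: for each participant
× timepoint, the mean of that participant's three betas is subtracted, so
the coefficient quantifies stability of the *relative* motive profile.
The sentence "mean centred the betas for each participant and time" also
admits a grand-mean reading; both are implemented
(`centering='profile'|'grand'`), profile is the default.  The form is
ICC(2,1) — two-way random effects, absolute agreement, single measures —
via pingouin, with ICC(3,1) by flag; a mean-squares closed form serves as
the oracle in tests.  Zero between-subject variance returns a 0-bounded
ICC with a degenerate flag.

## Psychopathology

Items are z-scored across participants (sample SD, n−1; a toggle disables
z-scoring for the raw-score sensitivity check), multiplied by their factor
weights and summed per dimension; the average score is the mean of the
three dimension scores.  Zero-variance items are z-scored to 0 (keeping
the weight-matrix mapping total) with a warning; participants missing any
item are flagged incomplete and excluded from association analyses.

The mixed ANCOVA (dimension as a 3-level within-subject factor; β1, β2,
β3, age, gender as covariates) is realised in two strata.  The
between-subject stratum is the OLS regression of participant-mean scores
on the covariates: each single-df covariate main effect is exactly the
squared t of the simplified average-score regression (asserted in tests);
gender is dummy-coded with the most frequent level as reference and tested
as a partial-F block when it has more than two levels.  The within-subject
stratum regresses deviations from the participant mean on dimension and
dimension × covariate terms, with 2n − p error degrees of freedom (each
participant's three deviations sum to zero).  Partial correlations between
each beta and the average score controlling age and gender are computed by
explicit residual-on-residual regression (df = n − 2 − #controls), which
remains exact at |r| → 1 and under constant controls.  Per-questionnaire
associations are simple regressions of each beta on each instrument total,
Bonferroni-corrected across instruments (p_adj = min(1, m·p)); the
instrument-level design is under-specified in the source analyses and this
regression reading is the package's interpretation.  All p-values are two
sided.

## The synthetic generator

The generator emulates the statistical structure the estimators assume,
not any deposited dataset's empirical marginals.  Per subject s: weights
w_s ~ N(μ, Σ) and intercept α_s ~ N(α0, σα²); per trial, three correlated
latent ratings (correlation matrix `rating_corr`, scale `rating_sd`) are
discretised to 7-point scales; the two feel ratings are built as a shared
affect level ± half the hedonic latent, so their difference carries the
hedonic signal.  The latent choice is α_s + w_s·ũ + item effect + ε with
ũ the *emitted* (discretised) utilities, then discretised to the no-zero
scale (latents in (−0.5, 0.5) map to ±1 by sign; exactly 0 maps to +1).
Second-timepoint weights follow an AR(1)-style construction
w2 = μ + ρ(w1 − μ) + √(1−ρ²)·η with η ~ N(0, Σ), applied in latent weight
space so ρ maps interpretably onto the ICC; intercepts are treated the
same way.  The questionnaire battery builds a latent composite
γ·(w_C − μ_C) + covariate terms + noise per subject, adds
dimension-specific disturbances, and emits 1–5 item ratings loading on a
random sparse positive item × dimension weight matrix (three dimensions,
nine instrument labels).  Everything is reproducible from a single seed.

Default conditions mirror the self-trait task: 80 subjects × 40 trials,
population mean weights (0.114, 0.123, 0.091), intercept mean 0.43 and SD
1.2 (matching a between-participant mean desire of ~0.43, SD ~1.3),
between-subject weight SD 0.15 per motive (no published value; chosen to
produce the broad spread of individual weight triples such tasks show),
residual SD 1.0, item-effect SD 0.3, rating SD 1.5 with inter-rating
correlation 0.3 (inter-rating correlations are not available numerically,
so this default is explicitly arbitrary and configurable), T1→T2
autocorrelation 0.6, and ψ-coupling γ = −2.5, which yields a measured
partial correlation of ≈ −0.25 between the cognitive weight and the
average psychopathology score at default scale — the magnitude reported
for self-trait studies of this kind.

What discretisation implies for recovery: emitting genuine Likert integers
clips the latent choice at ±3 and therefore attenuates mixed-model fixed
effects by roughly 5–10% relative to the latent generating weights (about
1–1.4 reported SEs at 300 × 40).  With discretisation off the estimators
recover the generating weights exactly (noise-free case) or without bias,
which is tested; recovery tests on discretised data therefore check mean
absolute error against a 0.03 bound and estimator bias against twice the
reported SE, rather than per-replicate coverage.  Passing tests show the
estimators are correct for data with this linear latent structure; they do
not certify behaviour under features real raters produce that the
generator omits (response styles, item-content effects, missingness,
attention lapses beyond a flag column).

## Problem sizes and numerical choices

Simulation-based tests run at the sizes the analyses target (recovery at
300 × 40 over 20 replicates; model selection at 60 × 30 over 50 replicates
with strong distinct weights (0.45, 0.30, 0.18); permutation calibration
at 100 subjects, 2000 iterations; coupling detection at 500 subjects over
20 replicates), all seeded and completing in ~1.5 minutes total.
Optimiser bounds keep log relative variances in [−14, 8]; variance
profiles that lose positive definiteness return +∞ to the optimiser.
Degenerate inputs have defined behaviour throughout: all-equal nonzero
participant means raise a zero-variance error in the midpoint test,
constant covariates drop out of partial-correlation controls harmlessly,
and a single item or participant is rejected before mixed-model fitting.

## Known limitations

* Choice is modelled linearly on the numeric scale; ordinal-response
  models are out of scope.
* No Bayesian hierarchical estimation; no by-item random slopes (they are
  deliberately excluded from the random structure for convergence, and the
  comparison space does not include them).
* The factor weights for psychopathology scoring are an input; the factor
  analysis that produces them is not re-derived.
* The permutation scheme's fixed-point exclusion and the profile-centring
  before ICC are documented interpretations of under-specified procedures;
  both have flags to switch to the alternative reading.
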