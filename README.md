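# infoseek

Analysis pipeline for Likert-scale information-seeking tasks in which
participants rate, for each of ~40 items of information, how much they want
to receive it (six-point scale, −3…+3 with 0 excluded) together with proxies
for three value-of-information motives:

* **instrumental utility** — how useful the information would be in guiding
  action (−3…+3);
* **hedonic utility** — expected feeling if the information were known minus
  expected feeling if it were never known (−6…+6);
* **cognitive utility** — how often the participant thinks about the concept
  (−3…+3).

The core model treats each choice rating as a linear function of the three
utilities,

```
choice_ij = α + β1·I_ij + β2·H_ij + β3·C_ij + a_i + b1_i·I_ij + b2_i·H_ij
            + b3_i·C_ij + u_j + ε_ij
```

with utilities centred within participant, by-participant random intercept
`a_i` and slopes `b_i`, and a by-item random intercept `u_j` (participants
and items fully crossed).  The package provides:

* **data_io** — long-format CSV validation and the study's exclusion rules
  (more than one failed attention check out of five; any utility input or
  the choice constant across a participant's trials at a timepoint);
* **utility_construction** — the three regressors, confidence covariate,
  valence-reversed expectation and within-participant centring;
* **choice_models** — per-participant OLS weights (β1, β2, β3), the crossed
  mixed-effects model (maximum likelihood, Satterthwaite-type df), and the
  BIC/AIC comparison of 15 candidate models (all nonempty utility subsets,
  plus every subset augmented with the confidence rating);
* **motive_profiles** — dominant-motive classification (a motive dominates
  "twofold" when its weight magnitude is at least twice both others; a
  weaker tier at 1.25×) and the choice-midpoint t test;
* **stability** — Euclidean distance between a participant's weight triples
  at two timepoints, a mismatched-pairing permutation test of whether the
  observed mean movement is smaller than chance, and per-motive intraclass
  correlations (ICC(2,1) on profile-centred betas);
* **psychopathology** — transdiagnostic dimension scores (z-scored
  questionnaire items weighted by published factor loadings, summed per
  dimension: anxious-depression, social withdrawal, compulsive behaviour
  and intrusive thought) and their association with the motive weights
  (repeated-measures ANCOVA, average-score regression, partial
  correlations controlling age and gender, per-questionnaire tests with
  Bonferroni correction);
* **synthetic_data** — a generator with the same statistical structure
  (latent per-subject weights, correlated Likert ratings, two-timepoint
  autocorrelation, configurable coupling between the cognitive weight and a
  latent psychopathology composite), so every stage is testable without
  participant data;
* **pipeline / cli** — one-command runs over all stages with CSV/JSON
  reports.

## Worked example

```python
import pandas as pd
from infoseek.synthetic_data import GeneratorConfig, generate_dataset
from infoseek import utility_construction as uc, choice_models as cm, stability as stab

bundle = generate_dataset(GeneratorConfig(n_subjects=80, n_trials=40, seed=1))
trials = pd.concat([bundle.trials_t1, bundle.trials_t2], ignore_index=True)
util = uc.center_within_participant(uc.build_utilities(trials))

fit = cm.fit_mixed_model(util[util["timepoint"] == "T1"])
print(fit.fixed_effects.round(3).to_string(index=False))
```

```
        term  estimate    se  tvalue     df  pvalue
   intercept     0.267 0.124   2.149 98.526   0.034
instrumental     0.120 0.019   6.242 87.133   0.000
     hedonic     0.117 0.020   5.897 80.183   0.000
   cognitive     0.045 0.021   2.119 80.162   0.037
```

All three utilities carry significant positive weight: desire for
information rises with expected usefulness, with the expected affective
benefit of knowing, and with how often the concept is thought about.  The
stability of the per-participant weights across the two timepoints:

```python
weights, _ = cm.fit_subject_weights(util)
w1 = weights[weights.timepoint == "T1"]; w2 = weights[weights.timepoint == "T2"]
res = stab.permutation_stability_test(w1, w2, n_iter=10_000, seed=1)
print(f"actual mean distance: {res.actual_mean_distance:.3f}")
print(f"proportion of mismatched pairings farther apart: {res.proportion_actual_smaller:.4f}")
```

```
actual mean distance: 0.345
proportion of mismatched pairings farther apart: 1.0000
```

Participants moved far less in (β1, β2, β3) space between timepoints than
mismatched participant pairings do (all 10,000 permutations produced a
larger mean distance), i.e. the motive profile is stable within person.

The same analyses are available from the shell:

```bash
infoseek simulate --seed 1 --n-subjects 80 --out data/
infoseek run-all --seed 1 --out reports/
```

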