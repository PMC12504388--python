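# conjointcheck

Bayesian conjoint checks of interval scalability for dichotomous
item-response data.

## The problem

Scores built from test or questionnaire items are routinely treated as
interval-scaled — differences between scores are compared, averaged and
regressed on — but interval scaling is an empirical property that is
rarely tested. Additive conjoint measurement (ACM) gives it testable
content: if the log-odds of a correct response is an additive function
of person ability θ and item difficulty b, as the Rasch model asserts,

    logit P(X_ij = 1) = θ_i − b_j,

then the observable proportions p(s, j) — the fraction of examinees with
sum score s answering item j correctly — must satisfy the cancellation
axioms of ACM on every 3 score-group × 3 item sub-table ("3-matrix"):

* **single cancellation** — p(s, j) is nondecreasing in s within every
  item, and nondecreasing in item easiness within every score group;
* **double cancellation** (Luce–Tukey) — if p(2,1) ≥ p(1,2) and
  p(3,2) ≥ p(2,3) on the anti-diagonals, then p(3,1) ≥ p(1,3), and the
  mirror-image implication with all inequalities reversed.

Observed proportions carry binomial sampling noise, so raw order
reversals prove nothing. The Bayesian conjoint check (BCC) puts a
posterior on each 3-matrix's nine true proportions — independent binomial
likelihoods under a uniform prior truncated to the axiom-satisfying
region — and flags a cell when its empirical value falls outside the
95% equal-tailed credible interval. The headline statistic is the
**weighted proportion of violations**: the fraction of flagged cells
over many randomly sampled 3-matrices, each cell weighted by the number
of examinees in its score group.

Because even Rasch-generated data produce nonzero violation rates that
depend on N, test length, and difficulty spread, the statistic has no
universal cutoff. The package therefore calibrates it with a parametric
bootstrap: fit the Rasch model by conditional maximum likelihood,
resimulate many datasets from the fitted probabilities, run the check on
each, and read off the percentile of the observed statistic in that null
distribution. A percentile above the chosen cutoff (90/95/99) rejects
the hypothesis that the data are compatible with interval scaling.

## Worked example

```python
import numpy as np
from conjointcheck import (
    MCMCConfig, bootstrap_null, compare_to_null,
    draw_item_params, draw_person_params, run_bcc, simulate_responses,
)

# simulate a 1000-examinee, 50-item test whose items vary in
# discrimination (a ~ U(0.5, 1.7)) — a non-Rasch, non-interval process
persons = draw_person_params(1000, mean=0.0, sd=1.0, seed=1)
items = draw_item_params(50, diff_mean=0.0, diff_scale=1.44,
                         disc="uniform(0.5,1.7)", seed=2)
data = simulate_responses(persons, items, seed=3)

cfg = MCMCConfig(burn_in=300, kept_draws=600, seed=4)
summary = run_bcc(data, m=600, cfg=cfg)
null = bootstrap_null(data, b_reps=40, m=600, cfg=cfg, seed=5)
verdict = compare_to_null(summary.weighted_prop, null)
print(f"weighted violation proportion: {summary.weighted_prop:.4f}")
print(f"null mean: {null.values.mean():.4f}  (B = {len(null.values)})")
print(f"percentile in null: {verdict.percentile:.1f}")
print(f"rejected at 95% cutoff: {verdict.rejected_at[95]}")
```

Output:

```
weighted violation proportion: 0.0798
null mean: 0.0617  (B = 40)
percentile in null: 100.0
rejected at 95% cutoff: True
```

The observed violation proportion (0.0798) exceeds every value in the
Rasch-null distribution, so a scale built from these data by a Rasch
calibration should not be interpreted as interval — which is correct,
since the generating process had unequal discriminations. The same
pipeline on Rasch-generated data typically lands at an unremarkable
percentile.

The same workflow is available from the shell:

```sh
conjointcheck simulate -n 1000 -j 50 --diff-scale 1.44 --disc "uniform(0.5,1.7)" \
    --seed 1 -o data.csv
conjointcheck audit data.csv -b 40 -m 600 --seed 2 -o audit_out/
```

which writes `verdict.json`, the null distribution, and a plot of the
null with the observed statistic marked. See `conjointcheck --help` for
the `check`, `null`, `study1` and `study2` subcommands.

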