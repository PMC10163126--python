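# isletquant

Quantitative analysis of T cell infiltration in the human pancreas:
per-islet infiltration categories and densities, donor-level aggregation,
rank-based group comparisons, and the **30–30 rule** — a density-threshold
classifier that labels a donor as type-1-diabetic-like when the pooled CD3+
density over at least 30 randomly selected islets reaches 30 cells/mm².

## The problem

Insulitis — immune-cell infiltration of the islets of Langerhans — is the
histological hallmark of type 1 diabetes, but classical definitions count
islets above a fixed cell threshold (≥6 CD3+ or ≥15 CD45+ cells) and ignore
islet size. Because islet area varies by more than an order of magnitude on
a tissue section, the same cell count means very different things in a
small and a large islet. This package works with *densities*: for each
islet, the number of infiltrating cells divided by the islet area
(cells/mm²), and for each donor the **pooled density**

```
D = Σ_islets CD3+ count / Σ_islets islet area   [cells/mm²]
```

computed over all analysed islets (islets formed by ≥30 cells; smaller
objects are treated as detection artefacts). Islets are further classified
by their CD3+ count as non-infiltrated (0), moderately infiltrated (1–5)
or highly infiltrated (≥6 cells — the classical insulitis count).

The classifier is derived as a binary decision rule on the donor pooled
density: the ROC curve over labelled non-diabetic vs type 1 diabetic
donors gives the AUC, Youden's J (sensitivity + specificity − 1) selects
the optimal cut-point, and Monte-Carlo subsampling of n islets per donor
(10,000 iterations per n) quantifies how sensitivity and specificity
depend on the number of islets analysed — the basis of the "minimum 30
islets, 30 cells/mm²" operating point.

Because the underlying donor tissue images are not redistributable, the
package ships a calibrated synthetic-cohort generator
(`default_study_profile()`): group-level infiltration fractions, pooled
and exocrine densities, islet-area laws, the ICI/IDI (insulin-containing /
insulin-deficient islet) mixture and inter-donor heterogeneity are encoded
as generator targets, so the whole pipeline is exercisable and testable
end-to-end. See `docs/methods.md` for the generative model and its
calibration.

Intended users: groups doing quantitative histopathology of pancreatic
tissue (e.g. QuPath cell-detection exports) who want standardised
infiltration metrics, and methodologists studying density-threshold donor
classification.

## Worked example

```python
from isletquant import (default_study_profile, generate_cohort,
                        summarize_cohort, group_summary, ThresholdRuleModel)

cohort = generate_cohort(default_study_profile(), seed=7)   # 33 donors
summaries = summarize_cohort(cohort, min_cells=30)
g = group_summary(summaries)
g[g.metric == "pooled_density_cd3"][["group", "mean", "sd"]]
#  ND    16.5 ±  4.9  cells/mm²
#  AAB2  56.3 ± 19.4
#  T1D   73.1 ± 20.8

model = ThresholdRuleModel(cohort)        # ND vs T1D donors
result = model.fit(seed=7)
print(result.summary())
```

```
      Density threshold classifier (pooled CD3+ cells/mm^2)
==================================================================
Negative class: ND     n donors:   15
Positive class: T1D    n donors:   10
Cellularity filter: islets with >= 30 cells
------------------------------------------------------------------
AUC:                  1.0000  (95% CI 1.0000, 1.0000)
Optimal threshold:   37.2015  cells/mm^2 (Youden)
Youden J:             1.0000
==================================================================
```

The donor groups are well separated on pooled density (non-diabetic donors
around 17 cells/mm², recent-onset type 1 diabetic donors around 75), so
the full-data classifier is near-perfect and the Youden-optimal cut lands
in the high-30s — the rationale for a round 30 cells/mm² reference value.
The Monte-Carlo validation shows how the rule degrades when fewer islets
are available:

```python
result.sens_spec_table(threshold=30.0, n_grid=(10, 30, 50),
                       iterations=2000, seed=7).round(3)
#  n_islets  sensitivity_mean  sensitivity_sd  specificity_mean  specificity_sd
#        10             0.832           0.110             0.836           0.091
#        30             0.948           0.069             0.919           0.068
#        50             0.977           0.047             0.955           0.052
```

At 30 islets the rule keeps both operating characteristics above 0.9 on
this cohort; with only 10 it loses roughly ten points of each.
`result.classify(...)` applies the rule iteratively to unlabelled (e.g.
autoantibody-positive) donors and reports, per donor, the fraction of
iterations classified type-1-diabetic-like.

The same stages are available from the shell:

```
isletquant run --seed 7 --out-dir out/          # simulate → quantify → aggregate → rule
isletquant rule derive --islets out/islets.csv --out-dir out/
```

Real data enter through `isletquant.io`: per-islet CSV/TSV tables, or
GeoJSON islet boundaries plus cell-detection point tables in spatial mode
(`isletquant quantify --mode spatial`), where cells are assigned to an
islet when inside or within a 15 µm adjacency buffer of its boundary.

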