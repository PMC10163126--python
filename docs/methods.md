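# Methods

This note documents the quantitative model behind `isletquant`: the
per-islet and per-donor metrics, the density-threshold donor classifier,
the synthetic-cohort generative model and its calibration, the numerical
choices, and what the shipped tests do and do not demonstrate about real
tissue data.

## Quantities and definitions

The unit of observation is an islet profiled on a 2-D tissue section.
Each islet carries its parenchymal area (mm²), total cell (nucleus) count,
insulin status (ICI = insulin-containing, IDI = insulin-deficient /
pseudoatrophic, or UNKNOWN) and infiltrating T cell counts per marker:
CD3+ (all T cells), split into CD3+CD8+ (cytotoxic) and CD3+CD8−
(predominantly CD4+).

* **Inclusion filter.** Only islets formed by ≥ `min_cells` cells
  (default 30) are analysed; smaller objects are treated as possible
  segmentation artefacts. The filter is a hard partition, and excluded
  islets are retained in a separate table for audit.
* **Infiltration categories.** By CD3+ count: NONE (0), LOW (1–5),
  HIGH (≥ 6 — the count used by consensus insulitis definitions). The
  three categories are an exact partition, so per-donor percentages obey
  `pct_all = pct_low + pct_high`.
* **Islet density** = count / islet area (cells/mm²).
* **Pooled donor density** `D = Σ counts / Σ areas` over the donor's
  analysed islets — the area-weighted mean of islet densities. This is the
  score the classifier operates on. The unweighted mean of islet
  densities over stated subsets (all / LOW / HIGH islets) is also
  computed, because group-level comparisons conventionally use the
  per-donor-mean framing; the two are labelled distinctly and never mixed.
* **Exocrine density** = exocrine marker count / (total section area −
  endocrine area).
* **Endocrine:exocrine ratio** = pooled islet density / exocrine density,
  optionally restricted to ICI or IDI islets.
* Metrics with empty denominators (a donor with no analysed islets, no
  CD8+ cells, …) propagate as NaN — "undefined", never silently zero.
  This matters in practice: roughly half of non-diabetic donors have no
  HIGH islet at all, and conflating "no data" with "zero" would bias
  group means.

In spatial mode, cell detections (x, y in µm with marker flags) are
assigned to islet boundary polygons: a cell counts toward an islet when it
lies inside the closed polygon or within an adjacency buffer of its
boundary (default 15 µm ≈ one cell diameter; peri-islet T cells count as
infiltrating in standard insulitis definitions). A cell matching several
islets goes to the nearest boundary, exact ties to the lowest islet id.
Islet area — hence density — always uses the parenchymal polygon alone,
never the buffered region. Unassigned CD3+ cells accrue to the exocrine
counts. 1 mm² = 10⁶ µm² is defined in exactly one place.

## The density-threshold classifier (30–30 rule)

Donors are summarised by their pooled CD3+ density and labelled
(non-diabetic vs type 1 diabetic). The model surface follows the
statsmodels convention: `ThresholdRuleModel(cohort).fit()` returns a
results object with

* **AUC**, computed exactly as the tie-aware pairwise win fraction
  P(score⁺ > score⁻) + ½·P(equal) over all donor pairs, with a percentile
  bootstrap CI (donors resampled within class, 2,000 resamples by
  default — the CI method is a package choice, as is common when a study
  does not state one);
* the **optimal threshold** by Youden's J (sensitivity + specificity − 1)
  over candidate cut-points placed at midpoints between adjacent sorted
  unique scores, with ±1 sentinels; classification is score ≥ threshold →
  type-1-diabetic-like (ties positive, a deterministic convention). Ties
  in J break to the lowest threshold. If no cut-point beats J = 0 the
  threshold is flagged degenerate (NaN);
* Monte-Carlo validation: per donor and islet count n, the pooled density
  of n islets sampled **without replacement** is recomputed over many
  iterations (10,000 by default). `threshold_distribution` re-derives the
  optimal threshold per iteration; `sens_spec_table` fixes the threshold
  (30 cells/mm²) and reports mean ± SD sensitivity and specificity per n;
  `classify_donor` reports the fraction of iterations a donor exceeds the
  threshold. Donors with fewer than n analysed islets contribute all
  their islets rather than being dropped — dropping would silently remove
  exactly the sparse donors the rule is meant to serve.

Each (donor, n) pair draws from its own RNG substream (seeded from the
master seed, a CRC of the donor id, and n), so tables are bit-reproducible
and independent of grid order. Subsampling is vectorised by arg-partition
of uniform keys, giving exact uniform without-replacement samples.

## Synthetic cohort generative model

Real donor tissue is not redistributable, so the pipeline is exercised on
synthetic cohorts whose group-level summaries are *calibrated targets*,
not fitted quantities. The shipped default profile encodes three groups —
15 non-diabetic donors (~341 islets each), 8 double autoantibody-positive
(~192) and 10 recent-onset type 1 diabetic (~201) — with targets: LOW/HIGH
fractions 17.1%/0.4%, 33%/4.5%, 32.5%/8.2%; pooled CD3+ densities
17.3/55.4/74.8 cells/mm²; exocrine densities 34.8/55.4/85.4 cells/mm²;
mean islet areas 0.019/0.021/0.021 mm²; 40.5% ICI in the diabetic group;
count–area Spearman correlation 0.35; CD8+ fractions implied by
CD8−:CD8+ ratios of 0.36/0.30/0.45.

Per donor d, islet i:

* number of islets ~ Poisson(group mean); islet areas lognormal with the
  target arithmetic mean and log-sd σ_A = 0.8 (a documented knob — only
  the group means are published; 0.8 gives the order-of-magnitude area
  spread typical of islet sections);
* infiltration indicator Z_i ~ Bernoulli(p_i) with
  `logit p_i = α + σ_d·u_d + β·z_i`, where u_d is the donor random effect
  (σ_d = 0.5 by default) and z_i the standardised log-area. α is solved by
  Gauss–Hermite quadrature (40 nodes over both the area law and the donor
  effect) so the *marginal* infiltration probability equals the target
  exactly. β couples infiltration to islet size — larger islet profiles
  are more likely to be touched by at least one T cell — and is calibrated
  by bisection so the pooled Spearman correlation between count and area
  (estimated on a fixed-seed 60,000-islet simulation) meets the 0.35
  target. Placing the size coupling on the infiltration probability
  rather than on the positive-count mean is a deliberate design choice:
  mean-scaling interacts with the area mixture so strongly that the
  non-diabetic group's rare-HIGH target becomes unattainable, while
  contributing almost nothing to the rank correlation;
* given infiltration, the CD3+ count is zero-truncated negative binomial.
  Because its mean does not depend on area, the pooled-density constraint
  reduces to a fixed truncated mean m₊ = D·Ā/p_inf, and the dispersion k
  is solved so P(count ≥ 6 | ≥ 1) meets its target. P(≥6|≥1) as a function
  of k at fixed truncated mean is non-monotone (interior maximum) with a
  narrow achievable band, so roots are bracketed on a 25-point log-k grid
  before Brent refinement, and infeasible target combinations raise a
  calibration error naming the constraint;
* CD3+CD8+ counts are Binomial(CD3+, group CD8+ fraction); CD8− is the
  remainder;
* in the diabetic group, islets are ICI with probability 0.405 and the two
  statuses get separate count laws: infiltration extent in ratio
  55.4 : 34 (ICI : IDI), pooled densities in ratio 1.525, and area means
  in the published ICI:IDI ratio rescaled to preserve the overall group
  mean area (the published per-status and overall means are mutually
  inconsistent at the published ICI fraction; the overall mean wins
  because the density targets are defined against it). Per-status
  P(≥6|≥1) values are solved jointly within their feasible bands so the
  *overall* HIGH fraction (8.2%) is exact; the per-status HIGH contrast is
  therefore reproduced in direction, not in printed magnitude;
* islet cellularity is area / 4×10⁻⁶ mm² per cell; 3% of detected objects
  are sub-threshold artefacts (tiny areas) so the ≥30-cell filter is
  genuinely exercised; exocrine area is lognormal (mean 100 mm² per
  section, a realistic section size) and exocrine counts are Poisson at a
  donor-level lognormal density (σ = 0.3) mean-corrected to the target.

**Donor random effects are Latin-hypercube stratified**: the n donor
quantiles are a random permutation of stratified uniforms mapped through
Φ⁻¹, so each donor's effect is still exactly N(0,1) marginally but an
8–15-donor group covers the donor distribution evenly. With i.i.d. draws
the realised group mean wanders several percent from the calibration
target purely through donor-draw luck; stratification removes most of
that variance while leaving per-donor spread intact. The cost is that
cohorts are no longer invariant to changing another group's donor count.

Reproducibility: one master seed; per-(group, donor) substreams via
`numpy.random.SeedSequence`, so identical seeds give identical cohorts.

## Statistical tests

Group comparisons are rank-based, with the donor as the unit of analysis:
Kruskal–Wallis (tie-corrected, via scipy) with Dunn's pairwise z-tests on
the pooled mean ranks, Bonferroni-adjusted over all pairs (Dunn's
procedure is implemented here; scipy does not ship it). Paired ICI/IDI
comparisons use the Wilcoxon signed-rank test — exact null distribution
for ≤ 25 untied non-zero pairs, normal approximation with tie correction
otherwise; zero differences are dropped by default (classical policy),
with Pratt's method available. Spearman correlation uses tie-aware ranks
with the t-approximation p value and a permutation option. Two-sided
α = 0.05 throughout.

## Problem sizes and tolerances in the test suite

The test suite regenerates cohorts at the full study scale (33 donors,
~8,700 islets; a few seconds each) and checks that group means recover
their calibration targets within pre-registered Monte-Carlo bands (±3
points for LOW fractions, ±0.3/±1.5/±2 points for HIGH by group, ±10%
for densities, ±5 points for %ICI). Because a single 8-donor group mean
has a Monte-Carlo sd comparable to the tightest of these bands, the
recovery checks average three independent cohorts — they test the
calibration, not one draw's luck. Monte-Carlo machinery is verified
against exhaustive oracles: pairwise AUC, brute-force threshold scans
(1,000 random donor sets), 2ⁿ sign-pattern enumeration for the signed-rank
test, a 1,000-cohort null simulation for type-I error (≤ 6% at nominal
5%), and 1,000 random point/polygon instances against an independent
ray-casting + segment-distance oracle for the spatial assignment.

## What passing tests do and do not show

The generator reproduces published *group-level* summaries with realistic
overdispersion, donor heterogeneity and size–infiltration coupling. It
does not emulate: spatial clustering of infiltrates within a section,
correlations between islet metrics and donor covariates (age, C-peptide,
disease duration), CD20+/CD45+ populations, section-to-section variation
within a donor, or 3-D islet structure (an IDI profile may be an ICI
elsewhere in the organ). Classifier operating characteristics measured on
synthetic cohorts (e.g. AUC ≈ 1.0, sensitivity/specificity ≈ 0.9+ at 30
islets) are properties of the calibrated generative model, not estimates
for real donors — on real validation tissue the published figures are
lower (AUC 97.3%, sensitivity 0.94/specificity 0.87 at n = 30), and no
synthetic experiment here can stand in for that validation.

## Known limitations

* The ZTNB count family constrains which (mean, tail) combinations are
  attainable; profiles encoding heavier-than-NB tails will fail
  calibration loudly rather than silently approximate.
* `percent_change` at group level is computed from group means (matching
  the published framing, e.g. 62.9% vs printed 62.7% for the ICI/IDI
  extent contrast from rounded inputs); the mean of per-donor changes is
  also emitted and generally differs.
* Spatial mode assumes polygons are simple and coordinates share one
  frame; multi-section mosaics must be registered upstream.
* The Youden criterion is the only threshold rule implemented (pluggable
  by design); cost-sensitive criteria would move the cut-point.
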