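# Methods

`gcmarkers` re-implements, as a tested library, a complementary-biomarker
analysis for gastric cancer: screening expression data for membrane markers
that are silent in confounding normal tissues but frequently and strongly
expressed in tumors; quantifying how a *pair* of partially redundant,
partially exclusive markers (CDH17, the intestinal-type cadherin, and
CLDN18, the gastric-type claudin, with CLDN7 as a comparative control)
jointly covers cases; the semi-quantitative tissue-microarray (TMA)
immunohistochemistry (IHC) score system and the subgroup partition it
induces; two-way hierarchical clustering of both expression and IHC
matrices; and the survival / categorical statistics used to compare the
subgroups. Patient-level study data are not deposited anywhere, so seeded
synthetic generators emulate each input's statistical structure.

## The expression screen

The substrate is a probes × samples matrix of positive MAS5-style signal
scores with one column per systemic normal tissue and one per tumor sample.
Each probe is reduced to two order statistics:

* `normal_max` — the maximum over a ten-tissue normal panel (esophagus,
  pancreas, spleen, adipose, lymph node, artery, vein, peripheral blood
  cells, monocyte, macrophage). Stomach, colon and small intestine are
  excluded by design: the markers of interest are physiologically expressed
  there, and those organs do not confound nodal imaging.
* `tumor_kth` — the k-th largest tumor value (descending sort, 1-based,
  ties counted), k = 40 of 56 tumors by default, i.e. the marker must be
  high in ≥ 71.4% of cases.

A probe is selected iff `normal_max < 150` (strict) and `tumor_kth ≥ 500`
(inclusive). The boundary semantics follow the rule's wording and are
pinned by explicit tests. Thresholds are absolute signal scores; no ratio
normalization is applied. Tissue labels are matched case-insensitively with
collapsed whitespace; labels outside the panel ∪ excluded ∪ {tumor}
vocabulary are ignored with a warning so that richer tissue panels do not
break the screen.

## IHC score system

Membranous staining is scored per core as the proportion of positive tumor
cells binned to 0–10: 0% → 0, otherwise `ceil(pct/10)` (so 51–60% → 6).
Duplicate cores per site (primary lesion `Pr`, lymph-node metastasis `LN`)
are summed to a 0–20 IHC score. When only one core is evaluable the score
is doubled to keep the 0–20 scale and flagged `imputed` so downstream
analyses can exclude it; when none is, the score is missing. (The source
material leaves missing cores blank without stating a policy; doubling plus
a flag is this package's choice.)

Marker bands partition 0–20:

| marker  | ++    | +    | −    |
|---------|-------|------|------|
| CDH17   | 18–20 | 9–17 | 0–8  |
| CLDN18  | 14–20 | 6–13 | 0–5  |
| CLDN7   | 12–20 | 8–11 | 0–7  |

The CLDN18 and CLDN7 negative intervals are complements of the stated
++/+ ranges and are flagged `derived` in the scheme metadata. Any
alternative scheme is validated to partition 0–20 without gaps or overlaps.

Joint CDH17/CLDN18 bands of the primary lesion assign the subgroup:
Group 1 = CDH17(++) with CLDN18(+/−); Group 2 = CDH17(++)/CLDN18(++) or
CDH17(+)/CLDN18(+); Group 3 = CDH17(−) with any CLDN18; the two remaining
combinations (CDH17(+) with CLDN18(++) or (−)) are unclassified. Over the
full 21 × 21 integer score grid this partition contains 42 / 93 / 189 / 117
cells respectively — a refactoring-stable invariant asserted in tests.
Classification uses primary-lesion scores only; LN scores never override
them. Whole sections are summarized by four categories of the 0–10 score
(8–10 → 1, 5–7 → 2, 1–4 → 3, 0 → 4) over ten arbitrary primary-lesion
regions plus one category per metastatic node.

## Panel coverage

Calls are boolean per case × marker, derived either from a numeric
threshold (inclusive ≥, mirroring the screen's tumor floor) or from a band
scheme (positive = band above negative). A case is covered by a panel when
positive for at least one member; missing calls count as negative, since an
unevaluable core cannot demonstrate positivity. Printed percentages use
half-away-from-zero rounding (50/56 → 89.3, 98/106 → 92.5, 40/56 → 71.4,
465/1496 → 31 at zero decimals). `best_panel_greedy` generalizes two-marker
coupling to greedy set cover with lexicographic tie-breaks; an exhaustive
enumerator exists for small marker sets and bounds the greedy trace in
tests.

## Clustering

Distances follow the conventions of the Cluster 3.0 desktop tool:
City Block distance as the **mean** absolute difference over jointly
observed components and correlation distance as 1 − Pearson r, both
pairwise-complete so that missing LN scores (cores without a cancer
component) neither bias nor break the analysis. Mean (not sum) aggregation
keeps distances comparable across missingness patterns. Correlation is
centered by default; the uncentered cosine variant is exposed via
`centered=False`. Expression matrices are first transformed with
log base 150 (scores < 1 clipped to 0), so the screen's normal ceiling maps
to 1.0.

Agglomeration is UPGMA: merge the closest pair, with
d(A∪B, C) = (|A|·d(A,C) + |B|·d(B,C)) / (|A|+|B|). Ties break on the
smallest (id, id) pair in cluster-creation order and the left child of each
merge is the earlier-created cluster; no optimal leaf ordering is applied —
both choices trade aesthetics for determinism. Merge heights are
non-decreasing (enforced as a dendrogram invariant). `two_way_cluster`
clusters rows (cases, City Block) and columns (markers/antibodies,
correlation) independently — the metric-to-axis mapping follows the
original analysis — and reorders the matrix by both leaf orders. Trees are
exported as Newick (branch length = parent height − child height) and as
clustered-table + row/column tree TSVs mirroring the CDT/GTR/ATR convention
of TreeView-style viewers.

Correctness is pinned two ways: equivalence with a naive O(n³) re-scan
agglomerator on random instances (n ≤ 12), and equality of merge heights
with `scipy.cluster.hierarchy.linkage(method="average")` on complete data.

## Survival and categorical statistics

Records are disease-specific survival times (days from surgery; deaths from
other causes and patients alive at last follow-up are censored, event = 0).
Kaplan-Meier estimation and Cox proportional-hazards regression go through
lifelines; Cox uses Breslow tie handling (lifelines' method, and the
simplest adequate at this scale — no alternative tie method is offered),
Newton-Raphson with its default tolerance, Wald CIs, and raises on
non-convergence rather than returning silent output. Ordinal three-level
covariates are coded 0/1/2.

The weighted log-rank family is implemented directly: at each event time
the observed-minus-expected vector and its hypergeometric covariance are
accumulated with weight w = number at risk (Gehan-Breslow generalized
Wilcoxon, the default — it emphasizes early differences), w = 1 (log-rank)
or w = the left-continuous modified KM estimate (Peto-Prentice). The
statistic is z'V⁻z over g−1 groups with p from χ²(g−1); for two groups with
total n ≤ 12 an exact permutation p over all label assignments is available
and is the default at that size. lifelines' Wilcoxon-weighted log-rank
serves as an independent cross-check in tests, never as the implementation.

Fisher's exact test (two-sided, hypergeometric) and the Pearson chi-square
test wrap scipy; when any expected count is below 5 the chi-square result
is flagged and a seeded Monte-Carlo exact p (10⁵ margin-preserving tables
via `scipy.stats.random_table`) is attached. Mann-Whitney U enumerates the
permutation distribution exactly (midranks for ties) for total n ≤ 12 and
otherwise uses the tie- and continuity-corrected normal approximation. No
multiple-testing correction is applied to pairwise group comparisons; they
are reported raw.

## Synthetic data

The generators define the study conditions; they are deterministic given
their config (one `numpy` Generator seeded per call, independent of call
order).

**Expression** (default 10,000 probes — the probe universe size is
configurable since the effective pre-filtering of the original array is
unknown — over 13 normal tissues + 56 tumors): background probes draw
log-normal signal (meanlog 3.5, sdlog 1.0; median ≈ 33, right-skewed like
MAS5 scores, with a vanishing chance of 40 of 56 tumors exceeding 500).
Planted markers (default 3) are uniform 1–100 on the normal panel, ≥ 600 in
at least k tumors, and high in the excluded digestive tissues to exercise
the exclusion. Decoys (default 5 per mode) each violate exactly one
criterion: `normal_leaky` (one panel tissue at 200–2000), `tumor_weak` (all
tumors ≤ 450), `tumor_rare` (strong in fewer than k tumors). A defensive
post-check damps any background row that would pass both criteria, so the
screen's hit set equals the planted set by construction.

**TMA** (default 106 cases, latent group weights 30:30:38:8 matching the
observed subgroup sizes): each case draws a latent group, then a
(CDH17, CLDN18) primary aggregate uniformly over that group's score box;
CLDN7 tracks CDH17 at lower intensity; LN aggregates are the primary ±3
(clipped). Aggregates split into duplicate cores differing by at most
`replicate_noise` (default 2; with noise 0 only even aggregates are drawn
so duplicates can be identical). LN cores are deleted independently with
probability 0.10 by default, emulating nodal cores without a cancer
component. Because primary aggregates never leave their latent box, the
band classifier recovers latent labels exactly — a designed identifiability
property, not an empirical claim about real TMAs.

**Survival**: exponential event times per group, independent exponential
censoring, administrative cap; time = min of the three, event = 1 iff the
event time wins. Example hazards used in the examples and CLI default to
mean survivals of ~6.6 years (Group 1) vs ~3 years (Group 2) and ~2.5 years
(Group 3), qualitatively reproducing a better-prognosis
CDH17-hyperexpressing group.

What the generators do **not** emulate: probe-level microarray physics or
MAS5 itself, staining-intensity variation (the score is proportion-only),
correlated censoring, covariate structure (stage, histology, nodal counts)
linked to outcome. Passing tests therefore demonstrate the pipeline's
internal correctness and identifiability under its stated assumptions, not
clinical reproduction of the original cohort — whose patient-level results
(exact group sizes, hazard ratios, survival curves) cannot be regenerated
from published information.

## Numerical choices and degenerate inputs

* Percentages print with half-away-from-zero rounding via `decimal` (no
  binary-float surprises at .5 boundaries).
* `log150` of scores < 1 is clipped to 0 (signal scores are positive;
  avoids divergence at 0).
* Distance functions reject empty overlap (City Block), fewer than two
  joint observations or zero variance (correlation) with guidance.
* The weighted log-rank covariance uses a pseudoinverse, and a zero
  observed-minus-expected vector short-circuits to statistic 0, p = 1.
* Scores are integers end-to-end; fractional *percentages* are accepted by
  the proportion-to-score map, fractional *scores* are not.
* Monte-Carlo chi-square adds one to numerator and denominator (never
  reports p = 0); all simulation helpers take explicit seeds.

## Problem sizes in the test suite

The suite favors small, fully checkable instances: oracle-equivalence on
random matrices up to 200 × 50 (screen) and n ≤ 12 (UPGMA, exact tests),
2,000-replicate null calibration of the Gehan test and a 500-replicate,
n = 500 Cox parameter-recovery study — sizes at which exhaustive oracles
and simulation error bars are both meaningful on a single CPU.
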