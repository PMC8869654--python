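# Methods

## Data model

The central object is the master table: a proteins × samples matrix of
precursor-area intensities with explicit missingness. A protein absent from
a sample's quantification report carries no measured area, so absence is
stored as missing (NaN), distinct from any numeric value. Zero or empty
intensities in input reports are treated as "not detected" and dropped at
parse time (logged); duplicated accessions within one report are a hard
error rather than being aggregated, since no merge rule could be justified
and silent aggregation corrupts quantification.

## Normalization and presence filtering

Each sample is rescaled to parts per million of its detected total:
`X' = X / Σ Xᵢ · 10⁶`, the sum running over detected entries only (no zero
imputation). This makes columns comparable across total ion current but is
*compositional*: spiked-in mass shifts the per-sample total, so estimated
ratios of unspiked proteins are slightly biased away from 1 when a large
fraction of total intensity is differential. With study-scale backgrounds
(≥ ~1000 proteins, ≤ ~5% of intensity spiked) this bias is well under 1–2%;
the fold-recovery test therefore runs at the 2000-protein scale.

The presence filter keeps a protein if it is detected in at least a fraction
*t* (default 0.55) of the samples of at least one group. The fraction test
is exact — 4/7 ≈ 0.571 passes, 3/7 and 4/8 fail — with no rounding. The
filter is applied per pair-wise comparison over the two groups being
compared (the default; a single global filter across all groups is available
via `filter_scope: global`), because the filtering scope is genuinely open
and per-comparison filtering uses each comparison's own evidence.
Normalization precedes filtering.

## Differential abundance

Per protein, a two-sided Mann–Whitney U test compares the per-sample
normalized intensities of case vs control with missing entries entered as 0.
Zeros tie at the bottom ranks, so a protein detected in controls but absent
from cases still receives a meaningful p-value — this is what allows
"only in wt" proteins to appear among the significant downregulated list.
The test is exact (enumeration) when both groups have ≤ 8 observations and
the pooled values are tie-free; zeros from missingness force the normal
approximation with tie correction and, by default, continuity correction
(configurable, since borderline p-values depend on it). When the U statistic
equals its null mean the two-sided p is defined as exactly 1.

The fold change is the ratio of group means over *detected* values (means
are the summary used throughout the downstream correlation analysis);
detection in only one group yields the `only_in_case` / `only_in_control`
sentinel instead of a number. Classification: up if p ≤ 0.05 and
(ratio ≥ 1.5 or only-in-case); down if p ≤ 0.05 and (ratio ≤ 0.67 or
only-in-control); otherwise unchanged. The α comparison is inclusive
(p = 0.05 is significant). No multiple-testing correction is applied to
protein-level p-values; BH adjustment is available as an optional
annotation. Note the discreteness of the exact test: for 8 vs 7 samples the
achievable size at nominal 0.05 is 0.0401, and for 3 vs 3 groups no
arrangement reaches 0.05 at all (minimum p = 0.1) — group size, not effect
size, is then the binding constraint.

## Consistency and aging correction

A protein is consistent when classified in the same direction in both the
early and late disease comparisons; proteins absent from either comparison
(e.g. removed by its presence filter) cannot be consistent. Aging
correction removes every candidate that is also significantly changed
(either direction) between the age-matched control groups. Direction-
agnostic removal is the default — an age effect in any direction undermines
the disease attribution — with a direction-matched option
(`match_direction=True`) for the stricter reading. The cross-tissue overlap
keeps consistent proteins whose classification in a second-tissue/model
comparison matches their direction.

## Enrichment

Over-representation of a query list against GMT gene sets uses the
hypergeometric law on (k overlap, K set size in background, n query size,
N background size). "Two-sided" is defined as the doubled smaller tail
capped at 1 — a reproducible, standard convention — with a one-sided
(upper-tail) option. The background defaults to the proteins passing the
presence filter of the relevant comparison: the tested universe is what was
quantified. BH step-up adjustment is delegated to statsmodels and verified
in tests against the explicit step-up formula.

## Cross-study comparison and clustering

Cross-study agreement is the Spearman correlation between per-protein mean
normalized intensity (natural-log scale, detected values, over a chosen
sample subset) and an external accession → mean-intensity summary on the
shared accessions (≥ 3 required). For heatmap export, each selected row is
standardized to mean 0, unit variance (n−1 denominator) over detected
entries; missing entries become 0 after scaling. Row and column orders come
from agglomerative clustering with Ward linkage on Euclidean distances,
using scipy's deterministic merge-order dendrogram convention for the leaf
order (identical rows merge first and are adjacent; well-separated pairs
stay contiguous).

## Synthetic data

The generator emulates the features of LFQ data the pipeline's statistics
depend on, with the study's six-group design (7/8/8/8/5/3 samples) as the
default:

- **Abundance law**: per-protein baseline drawn log-normally, log₁₀ mean 6,
  sd 1 (precursor-area-like positive skew; both are config fields).
- **Noise**: multiplicative log-normal, mean-preserving, at a chosen
  within-group CV (default 20%, a typical LFQ within-group variability).
- **Spikes**: fold-change multipliers in chosen groups; "only-in-group"
  spikes detectable nowhere else; an age effect multiplies both 4-month
  groups (WT4 and INS4), so a disease spike combined with an age spike is a
  candidate in both disease comparisons yet significant in the aging
  comparison — the aging-confounded case.
- **Missingness**: uniform thinning (detection_rate) times a logistic
  dropout in log₁₀ abundance (midpoint + steepness), reproducing
  low-abundance dropout and the only-in-wt phenomenon.

A single integer seed drives one generator stream, making tables
bit-reproducible.

Two benchmark scenarios deliberately use full detection (detection_rate 1,
no dropout): the null calibration, where every protein must reach the exact
test, and the spike-recovery benchmark, where ground truth must be
attainable so that sensitivity measures the statistics rather than the
missingness process. Under the study design this recovers all 100 spikes
with zero false discoveries and a null significant fraction matching the
achievable size. The `study_mirror` scenario instead keeps realistic
missingness; there, zero-imputed rank tests lose power at both stages and
only ~70–90% of spiked proteins survive the two-stage consistency rule —
a faithful reminder that passing the clean benchmark does not bound
sensitivity on real data, where missingness, correlated protein modules and
peptide-level effects (none of which are simulated) further reduce it.

## Numerical choices and degenerate inputs

- ppm conservation is asserted to relative tolerance 1e-9; z-scaled rows to
  the same tolerance.
- A sample with no detected proteins, a constant row sent to z-scaling, a
  protein undetected in both compared groups, an empty sample in the rank
  test, and inconsistent hypergeometric counts are all hard errors naming
  the offending item — silent recovery would hide upstream corruption.
- Written tables use `repr` floats so rerunning a configuration reproduces
  outputs byte for byte.

## Limitations

- The enrichment background used by the original pathway tooling is
  unknown, so published pathway tables are treated as qualitative; the
  package tests its enrichment statistic against enumeration oracles
  instead.
- The cross-study correlation of ~0.7 reported against an external
  glomerular dataset requires that external dataset and is not reproduced;
  the correlation routine is verified on constructed data (self, reversed,
  monotone-distorted rankings).
- Ratio definition (group means over detected values) is the only summary
  consistent with the rest of the workflow, but other choices (medians,
  detected-pair means) would change borderline classifications.
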