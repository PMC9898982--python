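# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Cohort model and expression screen

A cohort is a log2 intensity matrix (genes × samples) where each sample
carries a disease stage (MGUS, SMM, MM) and a molecular subgroup — four IgH
translocation groups t(4;14), t(11;14), t(14;16), t(14;20) and two
hyperdiploid groups D1/D2 — or is a pooled healthy plasma-B control. All
expression statistics are computed per stage on **group medians**, not on
individual samples: the seven medians of a stage (six subgroups + control)
are the unit of the z-score, matching the one-cell-per-subgroup heatmap
convention this analysis style uses. Standard deviations use the n−1
(sample) denominator throughout, so three medians 1, 2, 3 standardize to
−1, 0, 1. Constant rows get all-zero z with a flag rather than NaNs.

A (gene, subgroup, stage) is **upregulated** when two screens pass
conjunctively:

* median log2 difference vs control > 1 with two-tailed Mann–Whitney
  p < 0.05, and
* z-score difference vs control strictly > 2.

The Mann–Whitney implementation is `scipy.stats.mannwhitneyu`: the exact
null distribution when min(n₁, n₂) ≤ 8 and the pooled sample is tie-free,
otherwise the normal approximation with mid-ranks, tie-corrected variance
and continuity correction. The exact path is validated against a
from-scratch enumeration over all C(n₁+n₂, n₁) rank assignments. An
all-equal degenerate input returns p = 1. No multiple-testing correction is
applied by default (the screen is reported at raw p); Benjamini–Hochberg can
be applied downstream on the report table if desired.

The **cross-stage panel** is the intersection over stages of the genes
upregulated in ≥ 1 subgroup; the **consistency set** of a panel gene is the
intersection over stages of its upregulated subgroups (possibly empty, when
the subgroup shifts between stages).

## Methylation

CpG methylation is a fraction in [0, 1] in memory (auto-detected from
percent inputs: any value > 1 means the file is percent-scaled) and percent
in reports. A DMR's per-group level is the median over member-CpG fractions
× 100. Differential methylation is the signed difference against the
control median; |ΔM| > 10 points flags hyper/hypo. Promoters are
[TSS − 2000, TSS + 500) strand-aware — wide enough to contain the ~855-bp
upstream features this analysis cares about — and the gene body is the rest
of the gene; promoter wins when an interval overlaps both.

Because DMR calling pipelines differ, DMR intervals are accepted as input;
a fallback segmenter clusters sorted CpGs with inter-CpG gaps ≤ 200 bp and
keeps clusters of ≥ 3 sites.

The methylation–expression link is the squared Pearson correlation between
the per-group methylation summaries and per-group expression medians,
computed on raw medians (R² is affine-invariant, so percent-vs-fraction and
z-scoring do not change it), significant strictly above 0.4. When a gene has
several DMRs of the requested region class, the per-group summary is the
**median of DMR medians** (robust to one outlier region); the mean is
available via `aggregate="mean"`. Zero variance in either vector makes R²
undefined and is flagged rather than coerced.

## Chromatin integration

Peaks carry a MACS2-style −log10 p signal and are filtered strictly above
50. The overlap engine merges same-mark peaks and sums covered bases per
DMR; a (DMR, mark) pair is recorded at ≥ 50 bp. The percentage distribution
divides each mark's pair count by the **total number of overlapping pairs**
(rounded half-up) — the only denominator convention under which the three
canonical configurations (2 DMRs × 3 marks; 3 + 7×3 DMR-mark pairs) yield
33%, 13% and 29% simultaneously. Whether the underlying convention in the
field counts pairs or base pairs is genuinely ambiguous; pair counting is
adopted because it reproduces all published exemplars at once.

State classification is rule-based over the gene region ∪ promoter
(priority super-enhancer > active enhancer > bivalent > none):

* **bivalent** — H3K27me3 covers ≥ 20% of the promoter, H3K4me1 or H3K4me3
  touches the promoter, and no H3K27ac lies in the region;
* **active enhancer** — the H3K4me3 ∩ H3K27ac co-covered span, merged over
  ≤ 1 kb gaps, reaches 5 kb, and the median methylation of DMRs overlapping
  that domain is intermediate (20–60%);
* **super-enhancer** — the broad co-domain plus H3K4me1 over it, at least
  one BRD4, MED1 and DHS peak inside it, and overlapping DMR methylation
  depleted below 20%.

The 5-kb broad-domain cutoff is deliberately conservative (the exemplar
domain is 12 kb; no published cutoff exists) and configurable, as are the
methylation band edges (the published intermediate exemplar is 40%). The
super-enhancer rule reuses the *structural* active-enhancer criterion but
carries its own methylation band: the intermediate band belongs to the
active-enhancer call only, since a domain cannot be simultaneously at 20–60%
and below 20%. H3K36me3 presence and MAF-site proximity are recorded as
evidence but never change the call. This is not ROSE-style rank-based SE
calling — no stitching or signal ranking — because the phenomenon being
modelled is a descriptive state transition on one locus, not a genome-wide
SE census.

The CTCF window takes the nearest CTCF peak ending at/before the TSS and
the nearest starting at/after the 3′ end, each within 50 kb, and spans peak
start to peak end; both flanks are required (a one-sided flank is not an
insulated window).

## Perturbation readouts

**Pyrosequencing.** Per-CpG deltas are mean treated − mean control in
percentage points. Significance comes from a two-way ANOVA with factors
condition × CpG site and interaction (statsmodels OLS); each CpG's p-value
is the condition contrast within that CpG tested against the full-model
residual mean square (default α = 0.001). Under the null with Gaussian
noise this contrast is exactly t-distributed, and the simulation suite
confirms type-I calibration within the binomial band at 1000 null runs.

**qPCR.** ΔCt = mean Ct(target) − mean Ct(reference) per condition, paired
by replicate; ΔΔCt = ΔCt(treated) − ΔCt(control); fold = 2^−ΔΔCt. The fold
is reciprocal under swapping conditions. The p-value is a Mann–Whitney test
on per-replicate ΔCt values. Dox-uninduced samples are treated as an extra
negative-control condition with expected fold ≈ 1.

**Dose–response.** Viability (normalized to untreated = 1) is fitted with
the 4-parameter log-logistic v(c) = bottom + (top − bottom)/(1 + (c/IC50)^h)
by least squares (`scipy.optimize.curve_fit`), initialized from the data
(top/bottom from the extreme means, IC50 from the concentration nearest
half-range, h = 1). Because the input is normalized and the tested range
(25 nM–2 µM) barely samples the upper plateau, a free top is weakly
identified and strongly correlated with the IC50; the top is therefore
anchored to 1 ± 0.05 (configurable `top_tolerance`). With that anchor,
simulated 5%-CV noise gives IC50 recovery within 20% of truth in 100/100
seeded runs (86/100 with a free top). A mean response that fails to
decrease with dose refuses the fit; an IC50 outside the tested range is
flagged extrapolated.

## Synthetic cohort: what it emulates, and what it does not

The generator plants the study conditions directly:

* **Expression** — additive log2 effects on per-gene baselines with i.i.d.
  Gaussian noise (default sd 0.45, matching the ±0.4–0.7 group spreads the
  cohort emulates). The headline gene (ITGB7-like, baseline 8.60) carries
  +4.36/+4.25 log2 in t(14;16)/t(14;20) at all stages; seven further genes
  complete an 8-gene cross-stage panel with subgroup-specific effects; two
  integrins are planted pan-subgroup down. Default cohort size is 10
  samples per subgroup per stage plus 4 control pools — chosen so the whole
  suite runs in seconds; the real cohort sizes (103/190/53) remain available
  through the config.
* **Methylation** — per-DMR per-group planted medians: ITGB7 body DMRs
  hypomethylated (~5%) in the MF cluster, intermediate (40%) in t(4;14),
  high (55%) in controls; DSG2 body DMRs at 45/72/84% in t(4;14) with a
  near-zero promoter; ITGAE promoter DMRs hypermethylated in the MF cluster.
  CpGs are drawn around the medians (default sd 3 points) and truncated to
  [0, 1]. The DSG2-like gene has exactly two distinct group levels, so its
  noise-free methylation–expression R² is exactly 1 (the collinearity
  oracle); the ITGB7-like pattern is monotone but not collinear, giving a
  high but sub-unity R².
* **Chromatin** — peaks realizing each planted state per cell line
  (primary-B bivalent, H929 active enhancer, MM1S/SACHI super-enhancer,
  U-266 unchanged), including a 12-kb co-domain and CTCF flanks at TSS−6 kb
  and 3′+3 kb around the 14-kb gene (a 23-kb window). Boundary jitter is
  available for robustness tests; planted states survive ±200 bp jitter in
  ≥ 95% of seeded runs.
* **Perturbation** — pyro shifts of +25 points at 6/8, 4/6 and 3/3 CpGs of
  three targeted DMRs; qPCR Ct values constructed so 2^−ΔΔCt equals the
  planted folds (3.0 / 1.0 / 3.2 per sgRNA, 1.0 without Dox); viability from
  the 4PL curve with planted IC50 0.11/0.10/0.08 µM at 24/48/72 h.

Not emulated: probe-level microarray artefacts, read-level bisulfite noise
and coverage variation, peak-calling uncertainty, copy-number or breakpoint
structure, inter-patient heterogeneity beyond i.i.d. noise, and any
correlation structure across genes. Passing the recovery suite therefore
shows the *pipeline logic* is correct under the planted model — it does not
certify performance on real cohorts, where effect sizes, noise and
confounding are less benign.

## Determinism and problem sizes

A single integer seed drives every generator through
`numpy.random.default_rng`; pipeline reruns with the same seed are
byte-identical (reports carry no timestamps, floats are rendered at 6
significant digits). Test-suite problem sizes are desk-scale by design:
1000-instance overlap-oracle sweeps, 200-sample Mann–Whitney enumeration
checks, 1000 null ANOVA simulations, 100-seed IC50 and jitter recovery runs.
`scripts/acceptance.py` recomputes the headline quantities from scratch at
those sizes; its perturbation worked examples use the generators' zero-noise
calibration limit, where recovery of the planted values is exact by
construction and any deviation would expose an implementation defect.

## Known limitations

* The enhancer classifier's thresholds (5-kb domain, 20/60% bands, 20%
  promoter coverage) are calibrated to the planted architectures and the
  published exemplars, not learned; real loci near a threshold will flip
  with small input changes.
* The per-gene methylation summary (median of DMR medians) is one of
  several defensible aggregations; with few DMRs per gene the median/mean
  choice can move R² across the 0.4 cutoff.
* The exact Mann–Whitney path refuses ties; tied data silently use the
  approximate path, which is anti-conservative for very small n.
* The IC50 top-anchor assumes honest normalization; if untreated wells are
  mis-normalized by more than 5%, widen `top_tolerance` or re-normalize.
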