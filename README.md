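# ren — regulatory epigenetic networks of adhesion genes in multiple myeloma

`ren` is an analysis pipeline for a recurring question in myeloma genomics:
when an adhesion gene such as *ITGB7* is overexpressed in a cytogenetic
subgroup — t(4;14), t(11;14), t(14;16), t(14;20), or the hyperdiploid D1/D2
groups — is that overexpression *epigenetically enhanced*, i.e. coupled to
loss of DNA methylation and acquisition of enhancer or super-enhancer
chromatin? The package integrates four layers of evidence, each as an
independently runnable stage over plain TSV/BED/bedGraph files:

1. **Expression** — per-stage (MGUS → SMM → MM) differential expression of an
   adhesion-gene panel against pooled healthy plasma-B controls. A gene is
   called up in a subgroup when the median log2 difference exceeds 1 at
   Mann–Whitney p < 0.05 **and** its z-score over the seven group medians
   exceeds the control z by more than 2. Genes up in at least one subgroup at
   every stage form the cross-stage panel; the subgroups where a panel gene
   is up at *all* stages define its consistency set.
2. **Methylation** — per-group median methylation of differentially
   methylated regions (DMRs), differential-methylation calls at |ΔM| > 10
   percentage points vs control, promoter/body annotation, and the
   methylation–expression link as squared Pearson correlation across group
   medians (significant above R² = 0.4).
3. **Chromatin** — DMR × histone-mark overlaps (≥ 50 summed bp, peaks
   filtered at −log10 p signal > 50), their percentage distribution over
   marks, a rule-based classifier for bivalent / active-enhancer /
   super-enhancer states (H3K27me3, H3K4me1/3, H3K27ac, H3K36me3, BRD4,
   MED1, DHS), and detection of CTCF-flanked insulated windows.
4. **Perturbation** — readouts of targeted DNA-methylation induction
   (dCas9–DNMT3A + sgRNAs): per-CpG pyrosequencing deltas with a two-way
   ANOVA (condition × CpG), ΔΔCt qPCR fold change (2^−ΔΔCt vs *GAPDH*), and
   4-parameter log-logistic IC50 fits for BET-inhibitor (JQ1) dose–response.

Because cohort-scale patient data of this kind are not freely
redistributable, the package ships a **synthetic-cohort generator** with
planted ground truth (effect sizes, DMR shifts, chromatin architectures,
fold changes, IC50s). Every stage is testable against what was planted, and
in the zero-noise limit recovery is exact.

## Worked example

```python
import numpy as np
from ren import synthetic
from ren.core_io import Stage, Subgroup
from ren.expression import (differential_expression,
                            differential_expression_table, upregulated_sets,
                            cross_stage_panel, subgroup_consistency)

truth = synthetic.default_truth(seed=7)
cohort = synthetic.simulate_cohort_expression(
    10, list(truth.baselines), truth, noise_sd=0.0,
    rng=np.random.default_rng(7))

rec = differential_expression(cohort, "ITGB7", Subgroup.T14_16, Stage.MM)
print(f"ITGB7 t(14;16) MM: median {rec.median_subgroup:.2f} vs control "
      f"{rec.median_control:.2f} -> log2FC {rec.log2fc:.2f}, "
      f"p = {rec.p_value:.2e}, {rec.direction}")

records = differential_expression_table(cohort)
up = upregulated_sets(records)
print("cross-stage panel:", ", ".join(sorted(cross_stage_panel(up))))
cons = subgroup_consistency(up)
print("ITGB7 consistent subgroups:",
      ", ".join(s.value for s in sorted(cons["ITGB7"])))
```

prints

```
ITGB7 t(14;16) MM: median 12.96 vs control 8.60 -> log2FC 4.36, p = 4.39e-04, up
cross-stage panel: CD28, CD86, DSG2, ITGA4, ITGA8, ITGAE, ITGB7, VCAM1
ITGB7 consistent subgroups: T14_16, T14_20
```

The ITGB7-like gene sits 4.36 log2 units (≈ 21-fold linear) above the 8.60
control baseline in the t(14;16) subgroup; eight genes survive the
cross-stage screen, and ITGB7's upregulation is consistent in exactly the
MAF-driven cluster (t(14;16) + t(14;20)). With realistic noise
(`noise_sd=0.45`, the spread of the group standard deviations the cohort
emulates) the same run gives `log2FC 4.66, p = 2.00e-03` and a 6-gene panel
at this small desk-scale cohort — border-line genes near the z-difference
cutoff drop in and out.

## Command line

```
ren run --out run_dir --seed 7        # full simulate -> report bundle
ren simulate / expr / meth / chrom / perturb   # individual stages on files
ren figures --bundle run_dir          # plain numeric matrices for plots
```

`ren run` writes `de.tsv`, `panel.tsv`, `meth_report.tsv`,
`correlation.tsv`, `overlaps.tsv`, `pie.tsv`, `states.tsv`, `ctcf.tsv`,
three `perturb_*.tsv` tables and a `manifest.json` recording seed,
thresholds and per-output provenance. Reruns with the same seed are
byte-identical. Thresholds live in a YAML config (`ren run --config
cfg.yaml`), CLI flags override file values.

## Layout

```
src/ren/core_io.py       domain types, BED/narrowPeak/bedGraph/TSV readers, writers
src/ren/synthetic.py     cohort generator with planted truth
src/ren/expression.py    differential expression, z-scores, panels
src/ren/methylation.py   DMR summaries, DM calls, methylation-expression R^2
src/ren/chromatin.py     overlap engine, pie shares, state classifier, CTCF
src/ren/perturbation.py  pyro ANOVA, ddCt fold change, IC50 fits
src/ren/pipeline.py      orchestration, config, figure exports
src/ren/cli.py           click CLI
docs/methods.md          models, assumptions, parameter choices, limitations
```
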