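"""DMR summarization, differential-methylation calls and methylation-expression
correlation.

Differential methylation is called against the control group at a >10
percentage-point threshold; the methylation-expression link is the squared
Pearson correlation between per-group methylation summaries and per-group
expression medians, significant above R^2 = 0.4. A fallback CpG-cluster
segmenter is provided for inputs that ship per-CpG calls without DMR
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CpGSite, DMR, GenomicInterval, Subgroup, log

CONTROL = Subgroup.CONTROL.value


@dataclass
class MethylationExpressionCorrelation:
    gene: str
    region_class: str  # promoter | body
    r_squared: float  # nan when undefined (zero variance)
    n_points: int
    passes_cutoff: bool
    undefined: bool = False


def call_dmrs(
    cpgs: list[CpGSite], min_cpg: int = 3, max_gap: int = 200
) -> list[GenomicInterval]:
    """Cluster sorted CpGs into candidate DMR intervals.

    Consecutive CpGs with gaps <= ``max_gap`` bp (previous end to next start)
    join one cluster; clusters of >= ``min_cpg`` sites become DMRs spanning
    the first CpG start to the last CpG end.
    """
    dmrs: list[GenomicInterval] = []
    cluster: list[CpGSite] = []

    def flush() -> None:
        if len(cluster) >= min_cpg:
            dmrs.append(
                GenomicInterval(
                    cluster[0].interval.chrom,
                    cluster[0].interval.start,
                    cluster[-1].interval.end,
                )
            )

    for site in cpgs:
        if cluster and (
            site.interval.chrom != cluster[-1].interval.chrom
            or site.interval.start - cluster[-1].interval.end > max_gap
        ):
            flush()
            cluster = []
        cluster.append(site)
    flush()
    return dmrs


def summarize_dmr(
    dmr: DMR | GenomicInterval, cpgs: list[CpGSite], dmr_id: str = "", gene: str = ""
) -> DMR:
    """Per-group median methylation (%) over the CpGs inside a DMR interval."""
    if isinstance(dmr, DMR):
        interval, dmr_id, gene, region_class = dmr.interval, dmr.id, dmr.gene, dmr.region_class
    else:
        interval, region_class = dmr, "intergenic"
    members = [s for s in cpgs if interval.overlap(s.interval) > 0]
    if not members:
        raise ValueError(f"DMR {dmr_id or interval} contains no CpG sites")
    groups = sorted({g for s in members for g in s.methylation})
    medians = {}
    for group in groups:
        vals = [s.methylation[group] for s in members if group in s.methylation]
        medians[group] = float(np.median(vals) * 100.0)
    return DMR(
        id=dmr_id or f"{interval.chrom}:{interval.start}-{interval.end}",
        interval=interval, gene=gene, region_class=region_class,
        n_cpg=len(members), median_methylation=medians,
    )


def differential_methylation(
    dmr: DMR, threshold: float = 10.0, control: str = CONTROL
) -> tuple[DMR, dict[str, str]]:
    """Annotate a DMR with signed DM vs control and hyper/hypo/unchanged flags.

    DM > +threshold points is "hyper", DM < -threshold "hypo".
    """
    if control not in dmr.median_methylation:
        raise ValueError(f"DMR {dmr.id}: control group {control!r} median missing")
    ctrl = dmr.median_methylation[control]
    flags: dict[str, str] = {}
    for group, med in dmr.median_methylation.items():
        if group == control:
            continue
        dm = med - ctrl
        dmr.dm_vs_control[group] = dm
        flags[group] = "hyper" if dm > threshold else "hypo" if dm < -threshold else "unchanged"
    return dmr, flags


def annotate_region(
    interval: GenomicInterval,
    gene_model: GenomicInterval,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> str:
    """Classify an interval as promoter / body / intergenic for a gene model.

    Promoter is [TSS - upstream, TSS + downstream) strand-aware; body the rest
    of the gene past the promoter edge. Promoter wins when both overlap.
    """
    if interval.chrom != gene_model.chrom:
        return "intergenic"
    if gene_model.strand == "-":
        tss = gene_model.end
        promoter = GenomicInterval(
            gene_model.chrom, max(0, tss - promoter_downstream), tss + promoter_upstream
        )
        body = (gene_model.start, max(gene_model.start + 1, tss - promoter_downstream))
    else:
        tss = gene_model.start
        promoter = GenomicInterval(
            gene_model.chrom, max(0, tss - promoter_upstream), tss + promoter_downstream
        )
        body = (tss + promoter_downstream, gene_model.end)
    if interval.overlap(promoter) > 0:
        return "promoter"
    if body[1] > body[0]:
        body_iv = GenomicInterval(gene_model.chrom, body[0], body[1])
        if interval.overlap(body_iv) > 0:
            return "body"
    return "intergenic"


def methylation_expression_correlation(
    gene: str,
    dmrs: list[DMR],
    expr_medians: dict[str, float],
    region_class: str,
    cutoff: float = 0.4,
    aggregate: str = "median",
) -> MethylationExpressionCorrelation:
    """Squared Pearson correlation between per-group methylation and expression.

    The per-group methylation summary is the median (or mean) of that group's
    DMR medians over the gene's DMRs of the requested region class; it is
    correlated against the per-group expression medians over groups present in
    both. Zero variance in either vector makes R^2 undefined (flagged).
    """
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    agg = np.median if aggregate == "median" else np.mean
    selected = [d for d in dmrs if d.gene == gene and d.region_class == region_class]
    groups = sorted(
        set(expr_medians)
        & set.intersection(*(set(d.median_methylation) for d in selected))
        if selected else set()
    )
    if len(groups) < 3:
        raise ValueError(
            f"{gene}/{region_class}: need >= 3 groups with methylation and "
            f"expression medians, got {len(groups)}"
        )
    meth = np.array([agg([d.median_methylation[g] for d in selected]) for g in groups])
    expr = np.array([expr_medians[g] for g in groups])
    if np.ptp(meth) == 0 or np.ptp(expr) == 0:
        log.info("%s/%s: zero variance, R^2 undefined", gene, region_class)
        return MethylationExpressionCorrelation(
            gene=gene, region_class=region_class, r_squared=float("nan"),
            n_points=len(groups), passes_cutoff=False, undefined=True,
        )
    r, _ = stats.pearsonr(meth, expr)
    r2 = float(r * r)
    return MethylationExpressionCorrelation(
        gene=gene, region_class=region_class, r_squared=r2,
        n_points=len(groups), passes_cutoff=r2 > cutoff,
    )


def dmr_report(
    dmrs: list[DMR], flags: dict[str, dict[str, str]] | None = None
) -> pd.DataFrame:
    """Long-format DMR table: one row per (DMR, group)."""
    rows = []
    for d in dmrs:
        for group, med in sorted(d.median_methylation.items()):
            rows.append(
                {
                    "dmr_id": d.id, "gene": d.gene, "region_class": d.region_class,
                    "chrom": d.interval.chrom, "start": d.interval.start,
                    "end": d.interval.end, "n_cpg": d.n_cpg, "group": group,
                    "median_methylation_pct": med,
                    "dm_vs_control": d.dm_vs_control.get(group, float("nan")),
                    "flag": (flags or {}).get(d.id, {}).get(group, ""),
                }
            )
    return pd.DataFrame(rows)
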