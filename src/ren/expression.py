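"""Differential expression of adhesion genes per subgroup and stage.

Per-stage statistics are computed on group medians: z-scores are taken over
the 7 group medians (6 disease subgroups + control) of a stage, the fold
screen is the median log2 difference against control with a two-tailed
Mann-Whitney U p-value, and the cross-stage panel keeps genes upregulated in
at least one subgroup at every disease stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    DISEASE_STAGES,
    DISEASE_SUBGROUPS,
    ExpressionMatrix,
    Stage,
    Subgroup,
    log,
)

#: Default adhesion-gene panel: 18 alpha-integrins, 8 beta-integrins,
#: 8 non-integrin adhesion molecules, and the co-stimulatory pair CD28/CD86.
ADHESION_PANEL = [
    "ITGA1", "ITGA2", "ITGA2B", "ITGA3", "ITGA4", "ITGA5", "ITGA6", "ITGA7",
    "ITGA8", "ITGA9", "ITGA10", "ITGA11", "ITGAD", "ITGAE", "ITGAL", "ITGAM",
    "ITGAV", "ITGAX",
    "ITGB1", "ITGB2", "ITGB3", "ITGB4", "ITGB5", "ITGB6", "ITGB7", "ITGB8",
    "ICAM1", "MUC1", "CDH1", "CDH2", "CD44", "DSG2", "NCAM1", "VCAM1",
    "CD28", "CD86",
]


@dataclass
class DifferentialExpressionRecord:
    gene: str
    stage: Stage
    subgroup: Subgroup
    median_subgroup: float
    median_control: float
    log2fc: float
    p_value: float  # nan when undefined (group too small)
    z_subgroup: float
    z_control: float
    z_diff: float
    direction: str  # up | down | ns


def group_medians(expr: ExpressionMatrix) -> pd.DataFrame:
    """Median and sample sd (ddof=1) per gene for every (stage, subgroup) group
    plus the pooled control.

    Single-sample groups get sd 0 with ``sd_undefined`` flagged; an empty
    group raises, naming the group.
    """
    cells: list[tuple[Stage, Subgroup]] = [
        (stage, sg) for stage in DISEASE_STAGES for sg in DISEASE_SUBGROUPS
    ]
    cells.append((Stage.CONTROL, Subgroup.CONTROL))
    rows = []
    for stage, sg in cells:
        idx = expr.sample_index(stage=stage, subgroup=sg)
        if idx.size == 0:
            raise ValueError(f"empty group: stage={stage.value} subgroup={sg.value}")
        block = expr.values[:, idx]
        med = np.median(block, axis=1)
        if idx.size > 1:
            sd = block.std(axis=1, ddof=1)
            undefined = False
        else:
            sd = np.zeros(block.shape[0])
            undefined = True
        for g, m, s in zip(expr.genes, med, sd):
            rows.append(
                {"gene": g, "stage": stage.value, "subgroup": sg.value,
                 "median": float(m), "sd": float(s), "n": int(idx.size),
                 "sd_undefined": undefined}
            )
    return pd.DataFrame(rows)


def zscore_by_group(medians: pd.DataFrame, stage: Stage) -> pd.DataFrame:
    """Z-scores per gene over the 7 group medians of one stage.

    Returns a genes x groups frame (6 subgroup columns + CONTROL) plus a
    boolean ``constant`` column flagging all-equal rows (z set to 0).
    """
    sub = medians[
        (medians["stage"] == stage.value)
        | (medians["subgroup"] == Subgroup.CONTROL.value)
    ]
    wide = sub.pivot_table(index="gene", columns="subgroup", values="median")
    order = [sg.value for sg in DISEASE_SUBGROUPS] + [Subgroup.CONTROL.value]
    wide = wide[[c for c in order if c in wide.columns]]
    if wide.shape[1] < 2:
        raise ValueError("need >= 2 group medians per gene for z-scores")
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)
    constant = sd == 0
    z = wide.sub(mean, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    z["constant"] = constant
    if constant.any():
        log.info("%d constant gene rows flagged at stage %s", constant.sum(), stage.value)
    return z


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed Mann-Whitney U p-value.

    Exact when min(n1, n2) <= 8 and the pooled sample has no ties; otherwise
    the normal approximation with mid-ranks, tie correction and continuity
    correction. Degenerate all-equal input returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and min(x.size, y.size) <= 8:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def differential_expression(
    expr: ExpressionMatrix,
    gene: str,
    subgroup: Subgroup,
    stage: Stage,
    log2fc_threshold: float = 1.0,
    alpha: float = 0.05,
    z_table: pd.DataFrame | None = None,
) -> DifferentialExpressionRecord:
    """Median log2 fold change vs control with a Mann-Whitney p-value.

    Groups smaller than 3 get p = nan and direction "ns" (with a warning).
    ``z_table`` (from :func:`zscore_by_group`) fills the z fields when given.
    """
    sub = expr.gene_values(gene, stage=stage, subgroup=subgroup)
    ctrl = expr.gene_values(gene, stage=Stage.CONTROL, subgroup=Subgroup.CONTROL)
    med_s, med_c = float(np.median(sub)), float(np.median(ctrl))
    log2fc = med_s - med_c
    if min(sub.size, ctrl.size) < 3:
        log.warning(
            "group too small for p-value: %s %s %s (n=%d vs %d)",
            gene, stage.value, subgroup.value, sub.size, ctrl.size,
        )
        p = float("nan")
    else:
        p = mann_whitney_p(sub, ctrl)
    direction = "ns"
    if np.isfinite(p) and p < alpha:
        if log2fc > log2fc_threshold:
            direction = "up"
        elif log2fc < -log2fc_threshold:
            direction = "down"
    z_s = z_c = float("nan")
    if z_table is not None and gene in z_table.index:
        z_s = float(z_table.loc[gene, subgroup.value])
        z_c = float(z_table.loc[gene, Subgroup.CONTROL.value])
    return DifferentialExpressionRecord(
        gene=gene, stage=stage, subgroup=subgroup,
        median_subgroup=med_s, median_control=med_c, log2fc=log2fc,
        p_value=p, z_subgroup=z_s, z_control=z_c, z_diff=z_s - z_c,
        direction=direction,
    )


def differential_expression_table(
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    log2fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> list[DifferentialExpressionRecord]:
    """All (gene, subgroup, stage) differential-expression records."""
    genes = genes if genes is not None else expr.genes
    med = group_medians(expr)
    records = []
    for stage in DISEASE_STAGES:
        z = zscore_by_group(med, stage)
        for gene in genes:
            for sg in DISEASE_SUBGROUPS:
                records.append(
                    differential_expression(
                        expr, gene, sg, stage,
                        log2fc_threshold=log2fc_threshold, alpha=alpha, z_table=z,
                    )
                )
    return records


def zdiff_select(
    z_table: pd.DataFrame, threshold: float = 2.0
) -> set[tuple[str, Subgroup]]:
    """(gene, subgroup) pairs whose z-score exceeds control by > threshold."""
    if Subgroup.CONTROL.value not in z_table.columns:
        raise ValueError("z table must contain a CONTROL column")
    out = set()
    for sg in DISEASE_SUBGROUPS:
        diff = z_table[sg.value] - z_table[Subgroup.CONTROL.value]
        for gene in z_table.index[diff > threshold]:
            out.add((gene, sg))
    return out


def upregulated_sets(
    records: list[DifferentialExpressionRecord],
    z_threshold: float = 2.0,
) -> dict[Stage, set[tuple[str, Subgroup]]]:
    """Per-stage sets of upregulated (gene, subgroup) pairs.

    "Upregulated" applies both printed screens conjunctively: direction "up"
    (log2fc > 1 at p < alpha) and z-difference vs control > ``z_threshold``.
    """
    out: dict[Stage, set[tuple[str, Subgroup]]] = {s: set() for s in DISEASE_STAGES}
    for rec in records:
        if rec.direction == "up" and rec.z_diff > z_threshold:
            out[rec.stage].add((rec.gene, rec.subgroup))
    return out


def cross_stage_panel(
    up_sets: dict[Stage, set[tuple[str, Subgroup]]]
) -> set[str]:
    """Genes upregulated in >= 1 subgroup at every disease stage."""
    missing = [s.value for s in DISEASE_STAGES if s not in up_sets]
    if missing:
        raise ValueError(f"missing stage(s): {missing}")
    per_stage = [
        {gene for gene, _ in up_sets[stage]} for stage in DISEASE_STAGES
    ]
    return set.intersection(*per_stage)


def subgroup_consistency(
    up_sets: dict[Stage, set[tuple[str, Subgroup]]]
) -> dict[str, set[Subgroup]]:
    """For each panel gene, the subgroups in which it is up at all 3 stages.

    A panel gene whose subgroup shifts between stages maps to an empty set.
    """
    panel = cross_stage_panel(up_sets)
    out: dict[str, set[Subgroup]] = {}
    for gene in sorted(panel):
        per_stage = [
            {sg for g, sg in up_sets[stage] if g == gene} for stage in DISEASE_STAGES
        ]
        out[gene] = set.intersection(*per_stage)
    return out
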