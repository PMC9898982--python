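"""Synthetic cohort generator with planted ground truth.

Emulates the study conditions end to end: a 6-subgroup myeloma cohort with
pooled healthy plasma-B controls and planted subgroup-specific log2 effects;
CpG-level methylation with planted hypo-/hyper-methylated DMRs; per-mark peak
landscapes realizing bivalent / active-enhancer / super-enhancer
architectures; and perturbation readouts (pyrosequencing, qPCR, viability)
with planted effect sizes. Every generator is deterministic given a seed, and
with all noise parameters at zero each downstream stage recovers the planted
truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    Assay,
    CpGSite,
    DISEASE_STAGES,
    DISEASE_SUBGROUPS,
    DMR,
    ExpressionMatrix,
    GenomicInterval,
    Mark,
    PeakSet,
    PerturbationTable,
    SampleRecord,
    Stage,
    Subgroup,
)

#: Representative cell line per molecular background.
CELL_LINES: dict[str, Subgroup] = {
    "primaryB": Subgroup.CONTROL,
    "H929": Subgroup.T4_14,
    "U266": Subgroup.T11_14,
    "MM1S": Subgroup.T14_16,
    "SACHI": Subgroup.T14_20,
}

GROUPS = [s.value for s in DISEASE_SUBGROUPS] + [Subgroup.CONTROL.value]

_GENE_LENGTH = 14_000  # ITGB7-scale gene body
_GENE_SPACING = 100_000
_CHROM = "chr12"


@dataclass
class SyntheticTruth:
    """Planted effects and states used as the recovery oracle."""

    seed: int
    baselines: dict[str, float]
    #: (gene, subgroup, stage) -> additive log2 effect
    planted_up: dict[tuple[str, Subgroup, Stage], float]
    #: gene -> 0-based half-open model (TSS at interval start, + strand)
    gene_models: dict[str, GenomicInterval]
    #: DMRs carrying planted per-group median methylation (%)
    planted_dmrs: list[DMR]
    #: gene -> cell line -> state label
    planted_states: dict[str, dict[str, str]]
    #: qPCR condition -> planted fold change vs the dCas9-only control
    planted_qpcr_folds: dict[str, float]
    planted_qpcr_fold: float = 3.2
    #: time point (h) -> planted IC50 (uM)
    planted_ic50: dict[int, float] = field(default_factory=dict)
    #: pyro DMR id -> (n_cpg, planted shift in points, targeted CpG indices)
    pyro_design: dict[str, tuple[int, float, tuple[int, ...]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for (gene, _, _), eff in self.planted_up.items():
            if gene not in self.baselines:
                raise ValueError(f"planted gene {gene!r} absent from gene list")
        for fold in self.planted_qpcr_folds.values():
            if fold <= 0:
                raise ValueError(f"planted fold must be > 0, got {fold}")


def _plant_all_stages(
    out: dict, gene: str, subgroups: list[Subgroup], effect: float
) -> None:
    for sg in subgroups:
        for stage in DISEASE_STAGES:
            out[(gene, sg, stage)] = effect


def default_truth(seed: int = 0) -> SyntheticTruth:
    """The default planted scenario mirroring the study's headline pattern.

    Eight genes are consistently upregulated across all three disease stages,
    each in its characteristic subgroup(s); the ITGB7-like gene carries the
    largest effect (+4.36 log2 over an 8.60 baseline) in the MF cluster
    (t(14;16) and t(14;20)), with body DMRs hypomethylated in that cluster,
    intermediate (40%) in t(4;14) and high (55%) in controls. Chromatin
    architectures plant bivalent (primary B), active-enhancer (H929) and
    super-enhancer (MM1S) states on ITGB7.
    """
    from .expression import ADHESION_PANEL

    genes = list(ADHESION_PANEL)
    rng = np.random.default_rng(seed)
    baselines = {
        g: float(b) for g, b in zip(genes, np.round(rng.uniform(6.5, 10.5, len(genes)), 2))
    }
    baselines["ITGB7"] = 8.60
    baselines["ITGA4"] = 9.06
    baselines["DSG2"] = 7.50

    planted: dict[tuple[str, Subgroup, Stage], float] = {}
    _plant_all_stages(planted, "ITGA4", [Subgroup.T11_14], 1.8)
    _plant_all_stages(planted, "ITGA8", [Subgroup.D1], 1.6)
    _plant_all_stages(planted, "DSG2", [Subgroup.T4_14], 1.8)
    _plant_all_stages(planted, "VCAM1", [Subgroup.T11_14, Subgroup.D1], 1.7)
    _plant_all_stages(planted, "ITGAE", [Subgroup.T14_16, Subgroup.T14_20], 2.2)
    _plant_all_stages(planted, "CD28", [Subgroup.T14_16, Subgroup.T14_20], 1.9)
    _plant_all_stages(planted, "CD86", [Subgroup.T14_16, Subgroup.T14_20], 1.6)
    for sg, eff in ((Subgroup.T14_16, 4.36), (Subgroup.T14_20, 4.25)):
        _plant_all_stages(planted, "ITGB7", [sg], eff)
    # a couple of pan-subgroup downregulated integrins, as in real cohorts
    _plant_all_stages(planted, "ITGA5", list(DISEASE_SUBGROUPS), -1.5)
    _plant_all_stages(planted, "ITGAL", list(DISEASE_SUBGROUPS), -1.3)

    gene_models = {
        g: GenomicInterval(
            _CHROM, 1_000_000 + i * _GENE_SPACING,
            1_000_000 + i * _GENE_SPACING + _GENE_LENGTH, "+",
        )
        for i, g in enumerate(genes)
    }

    planted_dmrs = _default_dmrs(gene_models)

    planted_states = {
        "ITGB7": {
            "primaryB": "bivalent",
            "H929": "active_enhancer",
            "MM1S": "super_enhancer",
            "U266": "none",
            "SACHI": "super_enhancer",
        }
    }

    return SyntheticTruth(
        seed=seed,
        baselines=baselines,
        planted_up=planted,
        gene_models=gene_models,
        planted_dmrs=planted_dmrs,
        planted_states=planted_states,
        planted_qpcr_folds={
            "dCas9-DNMT3A+sgRNA-1": 3.0,
            "dCas9-DNMT3A+sgRNA-2": 1.0,
            "dCas9-DNMT3A+sgRNA-3": 3.2,
            "noDox": 1.0,
        },
        planted_qpcr_fold=3.2,
        planted_ic50={24: 0.11, 48: 0.10, 72: 0.08},
        pyro_design={
            "DMR-1": (8, 25.0, (1, 2, 3, 4, 5, 7)),
            "DMR-2": (6, 25.0, (1, 2, 3, 4)),
            "DMR-3": (3, 25.0, (1, 2, 3)),
        },
    )


def _dmr_grid(model: GenomicInterval, n: int, width: int = 160) -> list[GenomicInterval]:
    """n DMR intervals spread along the gene body (past the promoter zone)."""
    body_start = model.start + 1_000
    step = (_GENE_LENGTH - 2_000) // n
    return [
        GenomicInterval(model.chrom, body_start + i * step, body_start + i * step + width)
        for i in range(n)
    ]


def _meth(control: float, **overrides: float) -> dict[str, float]:
    d = {g: control for g in GROUPS}
    d.update(overrides)
    return d


def _default_dmrs(gene_models: dict[str, GenomicInterval]) -> list[DMR]:
    dmrs: list[DMR] = []

    # ITGB7: 9 body DMRs, 62 CpGs; hypomethylated in the MF cluster,
    # intermediate in t(4;14), high in control (DMR-8/9 unchanged).
    itgb7 = gene_models["ITGB7"]
    cpg_counts = [6, 7, 7, 7, 7, 7, 7, 7, 7]
    for i, (iv, n_cpg) in enumerate(zip(_dmr_grid(itgb7, 9), cpg_counts), start=1):
        if i <= 7:
            meth = _meth(55.0, T14_16=5.0, T14_20=6.0, T4_14=40.0, T11_14=50.0,
                         D1=52.0, D2=53.0)
        else:  # DMR-8/9 stay near control
            meth = _meth(55.0, T14_16=55.0, T14_20=55.0, T4_14=40.0)
        dmrs.append(
            DMR(id=f"ITGB7_DMR-{i}", interval=iv, gene="ITGB7", region_class="body",
                n_cpg=n_cpg, median_methylation=meth)
        )

    # DSG2: 9 DMRs, 72 CpGs; 4 promoter (near-zero methylation) + 5 body,
    # of which DMR-7/8/9 are highly methylated in t(4;14) (45/72/84%).
    dsg2 = gene_models["DSG2"]
    prom_ivs = [
        GenomicInterval(dsg2.chrom, dsg2.start - 1_800 + i * 450,
                        dsg2.start - 1_800 + i * 450 + 160)
        for i in range(4)
    ]
    body_ivs = _dmr_grid(dsg2, 5)
    body_meth = [
        _meth(1.0),
        _meth(1.0),
        _meth(8.0, T4_14=45.0),
        _meth(10.0, T4_14=72.0),
        _meth(12.0, T4_14=84.0),
    ]
    for i, iv in enumerate(prom_ivs, start=1):
        dmrs.append(DMR(id=f"DSG2_DMR-{i}", interval=iv, gene="DSG2",
                        region_class="promoter", n_cpg=8, median_methylation=_meth(1.0)))
    for i, (iv, meth) in enumerate(zip(body_ivs, body_meth), start=5):
        dmrs.append(DMR(id=f"DSG2_DMR-{i}", interval=iv, gene="DSG2",
                        region_class="body", n_cpg=8, median_methylation=meth))

    # ITGAE: 3 promoter DMRs, 12 CpGs; atypically hypermethylated in the MF
    # cluster despite high expression.
    itgae = gene_models["ITGAE"]
    for i in range(3):
        iv = GenomicInterval(itgae.chrom, itgae.start - 1_500 + i * 500,
                             itgae.start - 1_500 + i * 500 + 160)
        dmrs.append(
            DMR(id=f"ITGAE_DMR-{i + 1}", interval=iv, gene="ITGAE",
                region_class="promoter", n_cpg=4,
                median_methylation=_meth(25.0, T14_16=80.0, T14_20=78.0, T4_14=35.0,
                                         T11_14=30.0, D1=30.0, D2=32.0))
        )
    return dmrs


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def simulate_cohort_expression(
    n_per_group: int,
    genes: list[str],
    truth: SyntheticTruth,
    noise_sd: float = 0.45,
    n_control: int = 4,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Simulate a log2 expression cohort with planted additive effects.

    Each (subgroup, stage) cell gets ``n_per_group`` samples; ``n_control``
    pooled healthy plasma-B samples form the control. Per-sample Gaussian
    noise with sd ``noise_sd`` (log2 units) is added on top of the planted
    baseline + effect.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for gene in {g for g, _, _ in truth.planted_up}:
        if gene not in genes:
            raise ValueError(f"planted gene {gene!r} absent from gene list")
    rng = rng if rng is not None else np.random.default_rng(truth.seed)

    samples: list[SampleRecord] = []
    for stage in DISEASE_STAGES:
        for sg in DISEASE_SUBGROUPS:
            for k in range(n_per_group):
                samples.append(
                    SampleRecord(f"{stage.value}_{sg.value}_{k + 1}", stage, sg)
                )
    for k in range(n_control):
        samples.append(SampleRecord(f"CTRL_pool_{k + 1}", Stage.CONTROL, Subgroup.CONTROL))

    values = np.empty((len(genes), len(samples)))
    for i, gene in enumerate(genes):
        base = truth.baselines.get(gene, 8.0)
        for j, s in enumerate(samples):
            effect = truth.planted_up.get((gene, s.subgroup, s.stage), 0.0)
            values[i, j] = base + effect
    values += rng.normal(0.0, noise_sd, size=values.shape) if noise_sd > 0 else 0.0
    return ExpressionMatrix(list(genes), samples, values)


def simulate_methylation_landscape(
    truth: SyntheticTruth,
    cpg_noise_sd: float = 3.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[CpGSite], list[DMR]]:
    """Simulate per-CpG methylation fractions around the planted DMR medians.

    ``cpg_noise_sd`` is in percentage points; fractions are truncated to
    [0, 1]. Returns the CpG sites together with the planted DMR intervals.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 1)
    cpgs: list[CpGSite] = []
    for dmr in truth.planted_dmrs:
        for frac in dmr.median_methylation.values():
            if not 0.0 <= frac <= 100.0:
                raise ValueError(f"planted methylation out of [0,100]: {frac}")
        span = len(dmr.interval) - 2
        positions = dmr.interval.start + np.round(
            np.linspace(0, span, dmr.n_cpg)
        ).astype(int)
        for pos in positions:
            meth = {}
            for group, pct in dmr.median_methylation.items():
                noise = rng.normal(0.0, cpg_noise_sd) if cpg_noise_sd > 0 else 0.0
                meth[group] = float(np.clip((pct + noise) / 100.0, 0.0, 1.0))
            cpgs.append(CpGSite(GenomicInterval(dmr.interval.chrom, int(pos), int(pos) + 2), meth))
    cpgs.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return cpgs, [DMR(d.id, d.interval, d.gene, d.region_class, d.n_cpg,
                      dict(d.median_methylation)) for d in truth.planted_dmrs]


_STATES = ("bivalent", "active_enhancer", "super_enhancer", "none")


def simulate_chromatin_peaks(
    truth: SyntheticTruth,
    cell_line: str,
    signal: float = 60.0,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[PeakSet]:
    """Emit per-mark peak sets realizing each gene's planted chromatin state.

    * bivalent: H3K27me3 + H3K4me1 confined to the promoter.
    * active_enhancer: a 12-kb H3K4me3 + H3K27ac co-occupied body domain.
    * super_enhancer: the broad domain plus H3K4me1, BRD4, MED1 and DHS.
    Enhancer/SE genes also get CTCF flanks at TSS-6 kb and 3'-end+3 kb.
    ``jitter_sd`` adds Gaussian jitter (bp) to every peak boundary.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 2)
    peaks: dict[Mark, list[tuple[GenomicInterval, float]]] = {m: [] for m in Mark}

    def add(mark: Mark, chrom: str, start: int, end: int) -> None:
        if jitter_sd > 0:
            start = int(start + rng.normal(0, jitter_sd))
            end = int(end + rng.normal(0, jitter_sd))
        peaks[mark].append((GenomicInterval(chrom, max(0, start), max(start + 1, end)), signal))

    for gene, states in truth.planted_states.items():
        state = states.get(cell_line, "none")
        if state not in _STATES:
            raise ValueError(f"unknown planted state {state!r} for gene {gene}")
        model = truth.gene_models[gene]
        chrom, tss, end3 = model.chrom, model.start, model.end
        if state == "none":
            continue
        if state == "bivalent":
            add(Mark.H3K27me3, chrom, tss - 1_500, tss + 400)
            add(Mark.H3K4me1, chrom, tss - 900, tss + 100)
            continue
        # broad H3K4me3 + H3K27ac co-domain over the body (12 kb)
        dom_start, dom_end = tss + 1_000, tss + 13_000
        add(Mark.H3K4me3, chrom, dom_start, dom_end)
        add(Mark.H3K27ac, chrom, dom_start, dom_end)
        add(Mark.CTCF, chrom, tss - 6_000, tss - 5_800)
        add(Mark.CTCF, chrom, end3 + 2_800, end3 + 3_000)
        if state == "super_enhancer":
            add(Mark.H3K4me1, chrom, dom_start, dom_end)
            add(Mark.H3K36me3, chrom, dom_start + 2_000, dom_end)
            add(Mark.BRD4, chrom, tss + 4_000, tss + 6_000)
            add(Mark.MED1, chrom, tss + 4_500, tss + 6_500)
            add(Mark.DHS, chrom, tss + 3_000, tss + 3_600)
            add(Mark.MAF, chrom, tss - 600, tss - 400)
            add(Mark.MAF, chrom, tss + 100, tss + 300)
    return [PeakSet(mark=m, cell_line=cell_line, peaks=p) for m, p in peaks.items()]


def simulate_perturbation_assays(
    truth: SyntheticTruth,
    reps: int = 3,
    pyro_noise_sd: float = 0.0,
    ct_noise_sd: float = 0.0,
    viability_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, PerturbationTable | dict[str, PerturbationTable]]:
    """Simulate the perturbation readouts with planted effect sizes.

    Returns ``{"pyro": {dmr_id: table}, "qpcr": table, "viability": table}``.
    Pyro tables compare "uninduced" vs "induced" conditions per CpG; qPCR Ct
    values are constructed so 2^-ddCt equals each condition's planted fold in
    the noise-free limit; viability follows a 4-parameter log-logistic curve
    with the planted per-time-point IC50.
    """
    if reps < 3:
        raise ValueError("reps must be >= 3")
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 3)

    pyro_tables: dict[str, PerturbationTable] = {}
    baseline = 10.0
    for dmr_id, (n_cpg, shift, targeted) in truth.pyro_design.items():
        rows = []
        for cpg in range(1, n_cpg + 1):
            for cond in ("uninduced", "induced"):
                mean = baseline + (shift if cond == "induced" and cpg in targeted else 0.0)
                for r in range(1, reps + 1):
                    noise = rng.normal(0, pyro_noise_sd) if pyro_noise_sd > 0 else 0.0
                    rows.append((cond, r, str(cpg), float(np.clip(mean + noise, 0, 100))))
        pyro_tables[dmr_id] = PerturbationTable(
            Assay.PYRO,
            pd.DataFrame(rows, columns=["condition", "replicate", "key", "value"]),
        )

    ref_ct, target_ct_control = 18.0, 22.0
    qrows = []
    for cond, fold in [("dCas9", 1.0), *truth.planted_qpcr_folds.items()]:
        target_ct = target_ct_control - np.log2(fold)
        for gene, ct in (("ITGB7", target_ct), ("GAPDH", ref_ct)):
            for r in range(1, reps + 1):
                noise = rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                qrows.append((cond, r, gene, float(ct + noise)))
    qpcr = PerturbationTable(
        Assay.QPCR, pd.DataFrame(qrows, columns=["condition", "replicate", "key", "value"])
    )

    concentrations = [0.025, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 2.0]  # uM
    top, bottom, hill = 1.0, 0.08, 1.3
    vrows = []
    for hours, ic50 in truth.planted_ic50.items():
        for c in concentrations:
            v = bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)
            for r in range(1, reps + 1):
                factor = rng.normal(1.0, viability_cv) if viability_cv > 0 else 1.0
                vrows.append((f"JQ1_{hours}h", r, f"{c:g}", float(max(0.0, v * factor))))
    viability = PerturbationTable(
        Assay.VIABILITY,
        pd.DataFrame(vrows, columns=["condition", "replicate", "key", "value"]),
    )
    return {"pyro": pyro_tables, "qpcr": qpcr, "viability": viability}


# ---------------------------------------------------------------------------
# Serialization of the synthetic cohort in the dialects core_io reads
# ---------------------------------------------------------------------------


def write_cohort(
    outdir: str | Path,
    truth: SyntheticTruth,
    expr: ExpressionMatrix,
    cpgs: list[CpGSite],
    dmrs: list[DMR],
) -> dict[str, Path]:
    """Write expression matrix + sheet, per-group bedGraphs, DMR BED, models BED
    and a truth.tsv serializing the planted effects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    df = expr.to_frame()
    paths["matrix"] = outdir / "expression.tsv"
    df.to_csv(paths["matrix"], sep="\t", float_format="%.6g", index_label="gene")
    sheet = pd.DataFrame(
        [(s.sample_id, s.stage.value, s.subgroup.value) for s in expr.samples],
        columns=["sample_id", "stage", "subgroup"],
    )
    paths["samples"] = outdir / "samples.tsv"
    sheet.to_csv(paths["samples"], sep="\t", index=False)

    for group in GROUPS:
        p = outdir / f"methylation_{group}.bedgraph"
        with open(p, "w") as fh:
            for site in cpgs:
                if group in site.methylation:
                    fh.write(
                        f"{site.interval.chrom}\t{site.interval.start}\t"
                        f"{site.interval.end}\t{site.methylation[group]:.6g}\n"
                    )
        paths[f"methylation_{group}"] = p

    paths["dmrs"] = outdir / "dmrs.bed"
    with open(paths["dmrs"], "w") as fh:
        for d in dmrs:
            fh.write(f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t{d.id}\n")

    paths["gene_models"] = outdir / "gene_models.bed"
    with open(paths["gene_models"], "w") as fh:
        for gene, iv in truth.gene_models.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene}\t0\t{iv.strand}\n")

    truth_rows = [
        {"kind": "effect", "gene": g, "group": sg.value, "stage": st.value, "value": eff}
        for (g, sg, st), eff in sorted(truth.planted_up.items())
    ]
    truth_rows += [
        {"kind": "state", "gene": g, "group": cl, "stage": "", "value": state}
        for g, states in truth.planted_states.items()
        for cl, state in sorted(states.items())
    ]
    truth_rows.append(
        {"kind": "seed", "gene": "", "group": "", "stage": "", "value": truth.seed}
    )
    paths["truth"] = outdir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
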