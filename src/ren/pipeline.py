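"""End-to-end pipeline: simulate -> expression -> methylation -> chromatin ->
perturbation, with a single config, file-based stage hand-offs and a run
manifest. Stage outputs are plain TSVs so any stage can be rerun or audited
in isolation; reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    DISEASE_SUBGROUPS,
    GenomicInterval,
    Mark,
    Stage,
    Subgroup,
    load_config,
    log,
    write_report,
)
from . import chromatin, expression, methylation, perturbation, synthetic


@dataclass
class Thresholds:
    log2fc: float = 1.0
    p: float = 0.05
    z_diff: float = 2.0
    dm: float = 10.0
    r2: float = 0.4
    overlap_bp: int = 50
    signal: float = 50.0
    anova_alpha: float = 0.001

    def validate(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name!r} must be positive, got {value}")


@dataclass
class PipelineConfig:
    outdir: str = "ren_run"
    seed: int = 7
    simulate: bool = True
    n_per_group: int = 10
    n_control: int = 4
    expression_noise_sd: float = 0.45
    cpg_noise_sd: float = 3.0
    pyro_noise_sd: float = 2.0
    ct_noise_sd: float = 0.1
    viability_cv: float = 0.05
    reps: int = 3
    aggregate: str = "median"  # DMR -> gene methylation summary
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        self.thresholds.validate()
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = load_config(path)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        thr = Thresholds(**raw.pop("thresholds", {}))
        cfg = cls(thresholds=thr, **raw)
        cfg.validate()
        return cfg


def _expr_medians_by_group(med: pd.DataFrame, stage: Stage) -> dict[str, dict[str, float]]:
    """gene -> group -> expression median for one stage (+ pooled control)."""
    sub = med[(med["stage"] == stage.value) | (med["subgroup"] == "CONTROL")]
    out: dict[str, dict[str, float]] = {}
    for _, row in sub.iterrows():
        out.setdefault(row["gene"], {})[row["subgroup"]] = row["median"]
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns the manifest dict (also written as manifest.json). Any stage
    failure propagates with the stage named.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds
    manifest: dict = {
        "package": "ren",
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": dataclasses.asdict(thr),
        "outputs": {},
    }

    def record(name: str, path: Path, stage: str, n: int) -> None:
        manifest["outputs"][name] = {"path": path.name, "stage": stage, "rows": n}

    truth = synthetic.default_truth(cfg.seed)
    try:
        # --- simulate ----------------------------------------------------
        rng = np.random.default_rng(cfg.seed)
        expr = synthetic.simulate_cohort_expression(
            cfg.n_per_group, list(truth.baselines), truth,
            noise_sd=cfg.expression_noise_sd, n_control=cfg.n_control, rng=rng,
        )
        cpgs, dmr_intervals = synthetic.simulate_methylation_landscape(
            truth, cpg_noise_sd=cfg.cpg_noise_sd, rng=rng
        )
        paths = synthetic.write_cohort(outdir, truth, expr, cpgs, dmr_intervals)
        record("truth", paths["truth"], "simulate", len(truth.planted_up))
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        # --- expression ---------------------------------------------------
        med = expression.group_medians(expr)
        de_records = expression.differential_expression_table(
            expr, log2fc_threshold=thr.log2fc, alpha=thr.p
        )
        de_path = write_report(de_records, outdir / "de.tsv")
        record("de", de_path, "expression", len(de_records))
        up_sets = expression.upregulated_sets(de_records, z_threshold=thr.z_diff)
        panel = expression.cross_stage_panel(up_sets)
        consistency = expression.subgroup_consistency(up_sets)
        panel_rows = [
            {"gene": g, "consistent_subgroups": ",".join(sorted(s.value for s in sgs))}
            for g, sgs in sorted(consistency.items())
        ]
        panel_path = write_report(
            panel_rows, outdir / "panel.tsv", columns=["gene", "consistent_subgroups"]
        )
        record("panel", panel_path, "expression", len(panel_rows))
    except Exception as exc:
        raise RuntimeError(f"stage 'expression' failed: {exc}") from exc

    try:
        # --- methylation --------------------------------------------------
        summarized = [methylation.summarize_dmr(d, cpgs) for d in dmr_intervals]
        flags: dict[str, dict[str, str]] = {}
        for d in summarized:
            _, f = methylation.differential_methylation(d, threshold=thr.dm)
            flags[d.id] = f
        meth_path = write_report(
            methylation.dmr_report(summarized, flags), outdir / "meth_report.tsv"
        )
        record("meth_report", meth_path, "methylation", sum(
            len(d.median_methylation) for d in summarized))

        expr_med = _expr_medians_by_group(med, Stage.MM)
        corr_rows = []
        for gene in sorted({d.gene for d in summarized if d.gene}):
            for region_class in ("promoter", "body"):
                if not any(
                    d.gene == gene and d.region_class == region_class
                    for d in summarized
                ):
                    continue
                corr = methylation.methylation_expression_correlation(
                    gene, summarized, expr_med[gene], region_class,
                    cutoff=thr.r2, aggregate=cfg.aggregate,
                )
                corr_rows.append(corr)
        corr_path = write_report(corr_rows, outdir / "correlation.tsv")
        record("correlation", corr_path, "methylation", len(corr_rows))
    except Exception as exc:
        raise RuntimeError(f"stage 'methylation' failed: {exc}") from exc

    try:
        # --- chromatin ----------------------------------------------------
        state_rows, overlap_rows, pie_rows, ctcf_rows = [], [], [], []
        for cell_line, group in synthetic.CELL_LINES.items():
            peaksets = synthetic.simulate_chromatin_peaks(
                truth, cell_line, rng=np.random.default_rng(cfg.seed + 17)
            )
            filtered = [
                chromatin.filter_peaks_by_signal(ps, thr.signal) for ps in peaksets
            ]
            marks = {ps.mark: ps for ps in filtered}
            records = chromatin.overlap_dmr_marks(
                summarized, filtered, min_overlap=thr.overlap_bp
            )
            for rec in records:
                overlap_rows.append(
                    {"cell_line": cell_line, "dmr_id": rec.dmr_id,
                     "mark": rec.mark.value, "overlap_bp": rec.overlap_bp}
                )
            if records:
                dist = chromatin.overlap_fraction_distribution(records)
                for mark, share in sorted(dist.shares.items()):
                    pie_rows.append(
                        {"cell_line": cell_line, "mark": mark.value,
                         "share_pct": share, "total_pairs": dist.total_pairs}
                    )
            for gene, states in truth.planted_states.items():
                model = truth.gene_models[gene]
                promoter = GenomicInterval(model.chrom, model.start - 2000,
                                           model.start + 500)
                meth_by_dmr = [
                    (d.interval, d.median_methylation[group.value])
                    for d in summarized
                    if d.gene == gene and group.value in d.median_methylation
                ]
                call = chromatin.classify_chromatin_state(
                    model, promoter, marks, meth_by_dmr,
                    gene=gene, cell_line=cell_line,
                )
                state_rows.append(
                    {"gene": gene, "cell_line": cell_line, "state": call.state,
                     "planted": states.get(cell_line, "none"),
                     "evidence": ";".join(f"{k}={v}" for k, v in call.evidence)}
                )
                window = chromatin.detect_ctcf_window(gene, model, marks[Mark.CTCF])
                if window is not None:
                    ctcf_rows.append(
                        {"gene": gene, "cell_line": cell_line,
                         "chrom": window.window.chrom,
                         "start": window.window.start, "end": window.window.end,
                         "width_bp": len(window.window)}
                    )
        states_path = write_report(
            state_rows, outdir / "states.tsv",
            columns=["gene", "cell_line", "state", "planted", "evidence"],
        )
        record("states", states_path, "chromatin", len(state_rows))
        overlaps_path = write_report(
            overlap_rows, outdir / "overlaps.tsv",
            columns=["cell_line", "dmr_id", "mark", "overlap_bp"],
        )
        record("overlaps", overlaps_path, "chromatin", len(overlap_rows))
        pie_path = write_report(
            pie_rows, outdir / "pie.tsv",
            columns=["cell_line", "mark", "share_pct", "total_pairs"],
        )
        record("pie", pie_path, "chromatin", len(pie_rows))
        ctcf_path = write_report(
            ctcf_rows, outdir / "ctcf.tsv",
            columns=["gene", "cell_line", "chrom", "start", "end", "width_bp"],
        )
        record("ctcf", ctcf_path, "chromatin", len(ctcf_rows))
    except Exception as exc:
        raise RuntimeError(f"stage 'chromatin' failed: {exc}") from exc

    try:
        # --- perturbation -------------------------------------------------
        assays = synthetic.simulate_perturbation_assays(
            truth, reps=cfg.reps, pyro_noise_sd=cfg.pyro_noise_sd,
            ct_noise_sd=cfg.ct_noise_sd, viability_cv=cfg.viability_cv,
            rng=np.random.default_rng(cfg.seed + 29),
        )
        pyro_rows = []
        for dmr_id, table in assays["pyro"].items():
            results, _ = perturbation.pyro_anova(
                table, "uninduced", "induced", alpha=thr.anova_alpha
            )
            for r in results:
                pyro_rows.append({"dmr": dmr_id, **dataclasses.asdict(r)})
        pyro_path = write_report(pyro_rows, outdir / "perturb_pyro.tsv")
        record("perturb_pyro", pyro_path, "perturbation", len(pyro_rows))

        qpcr_rows = []
        for cond in truth.planted_qpcr_folds:
            fc = perturbation.ddct_fold_change(
                assays["qpcr"], "ITGB7", "GAPDH", "dCas9", cond
            )
            qpcr_rows.append({"condition": cond, **dataclasses.asdict(fc)})
        qpcr_path = write_report(qpcr_rows, outdir / "perturb_qpcr.tsv")
        record("perturb_qpcr", qpcr_path, "perturbation", len(qpcr_rows))

        ic50_rows = [
            dataclasses.asdict(perturbation.fit_ic50(assays["viability"], hours))
            for hours in sorted(truth.planted_ic50)
        ]
        ic50_path = write_report(ic50_rows, outdir / "perturb_ic50.tsv")
        record("perturb_ic50", ic50_path, "perturbation", len(ic50_rows))
    except Exception as exc:
        raise RuntimeError(f"stage 'perturbation' failed: {exc}") from exc

    manifest["panel_genes"] = sorted(panel)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete: %d outputs under %s", len(manifest["outputs"]), outdir)
    return manifest


def make_figures(outdir: str | Path) -> dict[str, Path]:
    """Export the numeric matrices behind the figures from a report bundle.

    Writes one plain-matrix TSV per stage: z-score heatmap matrices (per
    stage), pie shares, and dose-response curve points. No styling, numbers
    only.
    """
    outdir = Path(outdir)
    out: dict[str, Path] = {}
    de_path = outdir / "de.tsv"
    if not de_path.exists():
        raise FileNotFoundError(f"bundle member missing: {de_path}")
    de = pd.read_csv(de_path, sep="\t")
    for stage in ("MGUS", "SMM", "MM"):
        sub = de[de["stage"] == stage]
        mat = sub.pivot_table(index="gene", columns="subgroup", values="z_subgroup")
        mat = mat[[sg.value for sg in DISEASE_SUBGROUPS]]
        p = outdir / f"fig_heatmap_{stage}.tsv"
        mat.to_csv(p, sep="\t", float_format="%.6g")
        out[f"heatmap_{stage}"] = p

    pie_path = outdir / "pie.tsv"
    if not pie_path.exists():
        raise FileNotFoundError(f"bundle member missing: {pie_path}")
    pie = pd.read_csv(pie_path, sep="\t")
    p = outdir / "fig_pie.tsv"
    if pie.empty:
        pd.DataFrame(columns=["cell_line", "mark", "share_pct"]).to_csv(
            p, sep="\t", index=False
        )
    else:
        pie[["cell_line", "mark", "share_pct"]].to_csv(p, sep="\t", index=False)
    out["pie"] = p

    ic50_path = outdir / "perturb_ic50.tsv"
    if not ic50_path.exists():
        raise FileNotFoundError(f"bundle member missing: {ic50_path}")
    fits = pd.read_csv(ic50_path, sep="\t")
    conc = np.geomspace(0.025, 2.0, 25)
    rows = []
    for _, fit in fits.iterrows():
        v = fit["bottom"] + (fit["top"] - fit["bottom"]) / (
            1.0 + (conc / fit["ic50"]) ** fit["hill"]
        )
        for c, vi in zip(conc, v):
            rows.append({"time_point": fit["time_point"], "conc_uM": c, "viability": vi})
    p = outdir / "fig_dose_curves.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    out["dose_curves"] = p
    return out
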