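"""DMR x chromatin-mark overlap statistics and rule-based enhancer calling.

Overlaps between DMRs and signal-filtered peaks count at >= 50 summed bp;
their mark-wise percentage distribution reproduces the pie-chart convention
(denominator = all overlapping (DMR, mark) pairs). Chromatin states are
called by explicit rules: a bivalent promoter (H3K27me3 + H3K4 methylation,
no acetylation), a broad H3K4me3/H3K27ac co-domain with intermediate DNA
methylation (active enhancer), or that domain plus H3K4me1, BRD4, MED1 and
DHS with low methylation (super-enhancer). A CTCF flank heuristic detects
the insulated activation window around a gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import DMR, GenomicInterval, Mark, PeakSet, log


@dataclass
class OverlapRecord:
    dmr_id: str
    mark: Mark
    overlap_bp: int


@dataclass
class OverlapDistribution:
    shares: dict[Mark, int]  # integer percent, rounded half-up
    total_pairs: int


@dataclass
class ChromatinStateCall:
    gene: str
    cell_line: str
    state: str  # bivalent | active_enhancer | super_enhancer | none
    evidence: list[tuple[str, bool]] = field(default_factory=list)


@dataclass
class CtcfWindow:
    gene: str
    window: GenomicInterval
    upstream_peak: GenomicInterval
    downstream_peak: GenomicInterval


# ---------------------------------------------------------------------------
# Interval primitives (0-based half-open; validated against a per-base
# brute-force oracle in the test suite)
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: list[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals closer than ``gap`` bp, per chromosome."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start)):
        if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end + gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def covered_bases(target: GenomicInterval, intervals: list[GenomicInterval]) -> int:
    """Bases of ``target`` covered by the union of ``intervals``."""
    return sum(target.overlap(m) for m in merge_intervals(intervals))


def intersect_intervals(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Pairwise intersection of two merged interval lists."""
    a, b = merge_intervals(a), merge_intervals(b)
    out = []
    for iv in a:
        for jv in b:
            if iv.overlap(jv) > 0:
                out.append(
                    GenomicInterval(
                        iv.chrom, max(iv.start, jv.start), min(iv.end, jv.end)
                    )
                )
    return merge_intervals(out)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def filter_peaks_by_signal(peaks: PeakSet, min_signal: float = 50.0) -> PeakSet:
    """Keep peaks with signal strictly greater than ``min_signal``."""
    kept = [(iv, s) for iv, s in peaks.peaks if s > min_signal]
    return PeakSet(mark=peaks.mark, cell_line=peaks.cell_line, peaks=kept)


def overlap_dmr_marks(
    dmrs: list[DMR], marks: list[PeakSet], min_overlap: int = 50
) -> list[OverlapRecord]:
    """(DMR, mark) pairs whose summed overlap reaches ``min_overlap`` bp.

    Peaks of one mark are merged first, so several peaks over one DMR
    contribute a single record with summed coverage.
    """
    records = []
    for peakset in marks:
        merged = merge_intervals(peakset.intervals())
        for dmr in dmrs:
            bp = covered_bases(dmr.interval, merged)
            if bp >= min_overlap:
                records.append(OverlapRecord(dmr.id, peakset.mark, bp))
    log.info("overlap: %d (DMR, mark) pairs at >= %d bp", len(records), min_overlap)
    return records


def overlap_fraction_distribution(records: list[OverlapRecord]) -> OverlapDistribution:
    """Mark-wise percent shares of overlapping pairs, rounded half-up."""
    if not records:
        raise ValueError("no overlap records: distribution undefined")
    counts: dict[Mark, int] = {}
    for rec in records:
        counts[rec.mark] = counts.get(rec.mark, 0) + 1
    total = len(records)
    shares = {
        mark: int(math.floor(100.0 * c / total + 0.5)) for mark, c in counts.items()
    }
    return OverlapDistribution(shares=shares, total_pairs=total)


def classify_chromatin_state(
    gene_region: GenomicInterval,
    promoter: GenomicInterval,
    marks: dict[Mark, PeakSet],
    dmr_methylation: list[tuple[GenomicInterval, float]],
    gene: str = "",
    cell_line: str = "",
    broad_domain_bp: int = 5000,
    domain_merge_gap: int = 1000,
    meth_low: float = 20.0,
    meth_high: float = 60.0,
    bivalent_promoter_cov: float = 0.20,
) -> ChromatinStateCall:
    """Rule-based chromatin-state call over a gene region + promoter.

    Rules (priority super_enhancer > active_enhancer > bivalent > none):

    * bivalent — H3K27me3 covers >= 20% of the promoter, H3K4me1 or H3K4me3
      overlaps the promoter, and no H3K27ac lies in the region;
    * active_enhancer — the merged H3K4me3/H3K27ac co-covered span reaches
      ``broad_domain_bp`` (1-kb gap merge) and overlapping DMR methylation
      sits in the intermediate band [20, 60]%;
    * super_enhancer — the broad co-domain plus H3K4me1 over the domain and
      at least one BRD4, MED1 and DHS peak in it, with overlapping DMR
      methylation < 20%.

    ``dmr_methylation`` carries (interval, percent) for the relevant group;
    ``marks`` should be pre-filtered by signal. Evidence records every
    criterion's truth value.
    """
    if promoter.chrom != gene_region.chrom:
        raise ValueError("promoter and gene region must share a chromosome")
    region = GenomicInterval(
        gene_region.chrom,
        min(gene_region.start, promoter.start),
        max(gene_region.end, promoter.end),
    )

    def mark_ivs(mark: Mark) -> list[GenomicInterval]:
        ps = marks.get(mark)
        return ps.intervals() if ps is not None else []

    def in_region(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
        return [iv for iv in ivs if region.overlap(iv) > 0]

    # bivalent criteria
    k27me3_cov = covered_bases(promoter, mark_ivs(Mark.H3K27me3)) / len(promoter)
    biv_k27me3 = k27me3_cov >= bivalent_promoter_cov
    biv_k4 = any(
        promoter.overlap(iv) > 0
        for iv in mark_ivs(Mark.H3K4me1) + mark_ivs(Mark.H3K4me3)
    )
    no_k27ac = not in_region(mark_ivs(Mark.H3K27ac))

    # broad co-domain: H3K4me3 n H3K27ac, gap-merged, within the region
    co = intersect_intervals(in_region(mark_ivs(Mark.H3K4me3)),
                             in_region(mark_ivs(Mark.H3K27ac)))
    co = merge_intervals(co, gap=domain_merge_gap)
    domain = max(co, key=len, default=None)
    broad = domain is not None and len(domain) >= broad_domain_bp

    # methylation of DMRs overlapping the co-domain (region if no domain)
    target = domain if domain is not None else region
    meth_vals = [pct for iv, pct in dmr_methylation if target.overlap(iv) > 0]
    meth = float(np.median(meth_vals)) if meth_vals else float("nan")
    meth_intermediate = bool(meth_vals) and meth_low <= meth <= meth_high
    meth_depleted = bool(meth_vals) and meth < meth_low

    def any_in_domain(mark: Mark) -> bool:
        return domain is not None and any(
            domain.overlap(iv) > 0 for iv in mark_ivs(mark)
        )

    se_k4me1 = any_in_domain(Mark.H3K4me1)
    se_brd4 = any_in_domain(Mark.BRD4)
    se_med1 = any_in_domain(Mark.MED1)
    se_dhs = any_in_domain(Mark.DHS)

    evidence = [
        ("h3k27me3_promoter_cov_ge_20pct", biv_k27me3),
        ("h3k4_at_promoter", biv_k4),
        ("no_h3k27ac_in_region", no_k27ac),
        ("broad_k4me3_k27ac_codomain", broad),
        ("dmr_methylation_intermediate", meth_intermediate),
        ("dmr_methylation_depleted", meth_depleted),
        ("h3k4me1_in_domain", se_k4me1),
        ("brd4_in_domain", se_brd4),
        ("med1_in_domain", se_med1),
        ("dhs_in_domain", se_dhs),
        ("h3k36me3_in_domain", any_in_domain(Mark.H3K36me3)),  # descriptive only
        ("maf_site_near_promoter",  # descriptive only
         any(promoter.overlap(iv) > 0 for iv in mark_ivs(Mark.MAF))),
    ]

    if broad and se_k4me1 and se_brd4 and se_med1 and se_dhs and meth_depleted:
        state = "super_enhancer"
    elif broad and meth_intermediate:
        state = "active_enhancer"
    elif biv_k27me3 and biv_k4 and no_k27ac:
        state = "bivalent"
    else:
        state = "none"
    return ChromatinStateCall(gene=gene, cell_line=cell_line, state=state,
                              evidence=evidence)


def detect_ctcf_window(
    gene: str,
    gene_model: GenomicInterval,
    ctcf: PeakSet,
    max_flank: int = 50_000,
) -> CtcfWindow | None:
    """Nearest CTCF peaks flanking a gene, as an insulated-window candidate.

    Requires one peak ending at or before the TSS and one starting at or
    after the 3' end, each within ``max_flank`` bp; the window spans from the
    upstream peak start to the downstream peak end. Returns None when either
    flank is missing.
    """
    tss, end3 = gene_model.start, gene_model.end
    upstream = [
        iv for iv in ctcf.intervals()
        if iv.chrom == gene_model.chrom and iv.end <= tss and tss - iv.end <= max_flank
    ]
    downstream = [
        iv for iv in ctcf.intervals()
        if iv.chrom == gene_model.chrom and iv.start >= end3
        and iv.start - end3 <= max_flank
    ]
    if not upstream or not downstream:
        return None
    up = max(upstream, key=lambda iv: iv.end)
    down = min(downstream, key=lambda iv: iv.start)
    window = GenomicInterval(gene_model.chrom, up.start, down.end)
    return CtcfWindow(gene=gene, window=window, upstream_peak=up, downstream_peak=down)
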