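"""Chromatin integration: overlap engine, pie shares, state rules, CTCF."""

import numpy as np
import pytest

from conftest import brute_force_overlap
from ren.core_io import DMR, GenomicInterval, Mark, PeakSet
from ren.chromatin import (
    classify_chromatin_state,
    detect_ctcf_window,
    filter_peaks_by_signal,
    merge_intervals,
    overlap_dmr_marks,
    overlap_fraction_distribution,
)
from ren import synthetic


def _peakset(mark, intervals, signal=60.0, cell_line="MM1S"):
    return PeakSet(mark=mark, cell_line=cell_line,
                   peaks=[(GenomicInterval("chr1", s, e), signal) for s, e in intervals])


def _dmr(dmr_id, start, end):
    return DMR(id=dmr_id, interval=GenomicInterval("chr1", start, end), gene="g")


def test_filter_peaks_strictly_greater():
    ps = PeakSet(mark=Mark.H3K27ac, cell_line="x",
                 peaks=[(GenomicInterval("chr1", 0, 10), 60.0),
                        (GenomicInterval("chr1", 20, 30), 50.0)])
    kept = filter_peaks_by_signal(ps, 50.0)
    assert [s for _, s in kept.peaks] == [60.0]
    assert filter_peaks_by_signal(_peakset(Mark.BRD4, []), 50.0).peaks == []


def test_overlap_threshold_boundary():
    marks = [_peakset(Mark.H3K4me1, [(150, 260)])]
    kept = overlap_dmr_marks([_dmr("a", 100, 200)], marks, min_overlap=50)
    assert kept[0].overlap_bp == 50
    dropped = overlap_dmr_marks([_dmr("b", 100, 149)], [_peakset(Mark.H3K4me1, [(120, 300)])])
    assert dropped == []


def test_overlap_merges_same_mark_peaks_into_one_record():
    marks = [_peakset(Mark.H3K27ac, [(100, 140), (160, 220)])]
    (rec,) = overlap_dmr_marks([_dmr("a", 100, 200)], marks, min_overlap=50)
    assert rec.overlap_bp == 40 + 40


def test_overlap_engine_matches_per_base_brute_force():
    """Sweep engine == per-base counting on random small instances."""
    rng = np.random.default_rng(4)
    for _ in range(300):
        dmr_start = int(rng.integers(0, 9_000))
        dmr_end = dmr_start + int(rng.integers(50, 1_000))
        peaks = []
        for _ in range(rng.integers(1, 8)):
            s = int(rng.integers(0, 9_500))
            peaks.append((s, s + int(rng.integers(1, 1_000))))
        expected = brute_force_overlap(dmr_start, dmr_end, peaks)
        records = overlap_dmr_marks(
            [_dmr("d", dmr_start, dmr_end)], [_peakset(Mark.DHS, peaks)], min_overlap=1
        )
        got = records[0].overlap_bp if records else 0
        assert got == expected


def test_merge_intervals_gap():
    ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 15, 20)]
    assert len(merge_intervals(ivs)) == 2
    assert len(merge_intervals(ivs, gap=5)) == 1


def test_pie_shares_equal_thirds():
    """Two DMRs each overlapping three marks: 33% per mark."""
    records = overlap_dmr_marks(
        [_dmr("d1", 0, 200), _dmr("d2", 1000, 1200)],
        [_peakset(m, [(0, 200), (1000, 1200)])
         for m in (Mark.H3K4me1, Mark.H3K4me3, Mark.H3K27ac)],
    )
    dist = overlap_fraction_distribution(records)
    assert dist.total_pairs == 6
    assert set(dist.shares.values()) == {33}


def test_pie_shares_13_29_pattern():
    """3 DMRs with H3K4me1 plus 7 DMRs x 3 marks: 13% / 29% / 29% / 29%."""
    k4me1_dmrs = [_dmr(f"a{i}", i * 1000, i * 1000 + 200) for i in range(3)]
    triple_dmrs = [_dmr(f"b{i}", 10_000 + i * 1000, 10_000 + i * 1000 + 200)
                   for i in range(7)]
    marks = [_peakset(Mark.H3K4me1, [(d.interval.start, d.interval.end) for d in k4me1_dmrs])]
    marks += [
        _peakset(m, [(d.interval.start, d.interval.end) for d in triple_dmrs])
        for m in (Mark.H3K4me3, Mark.H3K27ac, Mark.H3K36me3)
    ]
    dist = overlap_fraction_distribution(
        overlap_dmr_marks(k4me1_dmrs + triple_dmrs, marks)
    )
    assert dist.total_pairs == 24
    assert dist.shares[Mark.H3K4me1] == 13
    assert all(dist.shares[m] == 29
               for m in (Mark.H3K4me3, Mark.H3K27ac, Mark.H3K36me3))


def test_pie_single_record_and_empty():
    (rec,) = overlap_dmr_marks([_dmr("d", 0, 200)], [_peakset(Mark.BRD4, [(0, 200)])])
    dist = overlap_fraction_distribution([rec])
    assert dist.shares[Mark.BRD4] == 100
    with pytest.raises(ValueError):
        overlap_fraction_distribution([])


def test_pie_shares_sum_to_100_pm_1():
    rng = np.random.default_rng(9)
    for _ in range(50):
        n_marks = int(rng.integers(1, 6))
        marks = list(Mark)[:n_marks]
        records = []
        for i in range(int(rng.integers(1, 30))):
            from ren.chromatin import OverlapRecord

            records.append(OverlapRecord(f"d{i}", marks[int(rng.integers(n_marks))], 60))
        dist = overlap_fraction_distribution(records)
        assert abs(sum(dist.shares.values()) - 100) <= 1


# --- state classification ---------------------------------------------------

GENE = GenomicInterval("chr1", 100_000, 114_000)
PROMOTER = GenomicInterval("chr1", 98_000, 100_500)


def _marks(**by_name):
    return {Mark[k]: _peakset(Mark[k], ivs) for k, ivs in by_name.items()}


def _ae_marks(extra=()):
    base = dict(
        H3K4me3=[(101_000, 113_000)],
        H3K27ac=[(101_000, 113_000)],
    )
    for name in extra:
        base[name] = [(101_000, 113_000)] if name == "H3K4me1" else [(104_000, 106_000)]
    return _marks(**base)


DMR_METH_40 = [(GenomicInterval("chr1", 105_000, 105_200), 40.0)]
DMR_METH_5 = [(GenomicInterval("chr1", 105_000, 105_200), 5.0)]


def test_bivalent_pattern():
    marks = _marks(H3K27me3=[(98_500, 100_400)], H3K4me1=[(99_100, 100_100)])
    call = classify_chromatin_state(GENE, PROMOTER, marks, [])
    assert call.state == "bivalent"


def test_active_enhancer_broad_codomain_intermediate_methylation():
    call = classify_chromatin_state(GENE, PROMOTER, _ae_marks(), DMR_METH_40)
    assert call.state == "active_enhancer"


def test_super_enhancer_full_pattern():
    marks = _ae_marks(extra=("H3K4me1", "BRD4", "MED1", "DHS"))
    call = classify_chromatin_state(GENE, PROMOTER, marks, DMR_METH_5)
    assert call.state == "super_enhancer"
    assert dict(call.evidence)["brd4_in_domain"]


def test_no_marks_is_none():
    call = classify_chromatin_state(GENE, PROMOTER, {}, [])
    assert call.state == "none"


@pytest.mark.parametrize("dropped", ["H3K4me1", "BRD4", "MED1", "DHS"])
def test_removing_any_single_se_criterion_demotes(dropped):
    extras = [m for m in ("H3K4me1", "BRD4", "MED1", "DHS") if m != dropped]
    call = classify_chromatin_state(GENE, PROMOTER, _ae_marks(extra=extras), DMR_METH_5)
    assert call.state != "super_enhancer"


def test_adding_se_peaks_never_demotes_active_enhancer():
    """Classification is monotone: SE evidence on top of an AE never lowers it."""
    base = classify_chromatin_state(GENE, PROMOTER, _ae_marks(), DMR_METH_40)
    richer = classify_chromatin_state(
        GENE, PROMOTER, _ae_marks(extra=("H3K4me1", "BRD4", "MED1", "DHS")), DMR_METH_40
    )
    order = {"none": 0, "bivalent": 1, "active_enhancer": 2, "super_enhancer": 3}
    assert order[richer.state] >= order[base.state]


def test_planted_states_recovered_with_boundary_jitter(truth):
    """>= 95% of planted state calls survive +-200 bp peak-boundary jitter."""
    group_of = {cl: sg for cl, sg in synthetic.CELL_LINES.items()}
    model = truth.gene_models["ITGB7"]
    promoter = GenomicInterval(model.chrom, model.start - 2000, model.start + 500)
    hits = total = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        for cell_line, planted in truth.planted_states["ITGB7"].items():
            peaksets = synthetic.simulate_chromatin_peaks(
                truth, cell_line, jitter_sd=200.0, rng=rng
            )
            marks = {ps.mark: ps for ps in peaksets}
            group = group_of[cell_line].value
            meth = [
                (d.interval, d.median_methylation[group])
                for d in truth.planted_dmrs if d.gene == "ITGB7"
            ]
            call = classify_chromatin_state(model, promoter, marks, meth)
            hits += call.state == planted
            total += 1
    assert hits / total >= 0.95


def test_ctcf_23kb_window(truth):
    """CTCF at TSS-6 kb and 3'-end+3 kb around a 14-kb gene: 23-kb window."""
    peaksets = {ps.mark: ps for ps in synthetic.simulate_chromatin_peaks(truth, "MM1S")}
    model = truth.gene_models["ITGB7"]
    window = detect_ctcf_window("ITGB7", model, peaksets[Mark.CTCF])
    assert window is not None
    assert len(window.window) == 23_000
    assert window.window.start <= model.start and window.window.end >= model.end


def test_ctcf_requires_both_flanks():
    model = GenomicInterval("chr1", 100_000, 114_000)
    down_only = PeakSet(mark=Mark.CTCF, cell_line="x",
                        peaks=[(GenomicInterval("chr1", 116_800, 117_000), 60.0)])
    assert detect_ctcf_window("g", model, down_only) is None
    far = PeakSet(mark=Mark.CTCF, cell_line="x",
                  peaks=[(GenomicInterval("chr1", 10_000, 10_200), 60.0),
                         (GenomicInterval("chr1", 116_800, 117_000), 60.0)])
    assert detect_ctcf_window("g", model, far, max_flank=50_000) is None
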