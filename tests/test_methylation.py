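"""Methylation stage: segmentation, DMR summaries, DM calls, correlation."""

import numpy as np
import pytest

from ren.core_io import CpGSite, DMR, GenomicInterval
from ren.methylation import (
    annotate_region,
    call_dmrs,
    differential_methylation,
    methylation_expression_correlation,
    summarize_dmr,
)


def _cpg(start, meth=None, chrom="chr1"):
    return CpGSite(GenomicInterval(chrom, start, start + 2), meth or {})


class TestCallDmrs:
    def test_cluster_within_gap(self):
        cpgs = [_cpg(p) for p in (100, 150, 220, 300)]
        (dmr,) = call_dmrs(cpgs)
        assert (dmr.start, dmr.end) == (100, 302)

    def test_too_few_cpgs_no_dmr(self):
        assert call_dmrs([_cpg(100), _cpg(150)]) == []

    def test_large_gap_splits_clusters(self):
        cpgs = [_cpg(p) for p in (100, 150, 200, 700, 750, 800)]
        dmrs = call_dmrs(cpgs)
        assert len(dmrs) == 2
        assert dmrs[0].end <= 700 <= dmrs[1].start

    def test_chromosome_change_splits(self):
        cpgs = [_cpg(p) for p in (100, 150, 200)] + [
            _cpg(p, chrom="chr2") for p in (100, 150, 200)
        ]
        assert len(call_dmrs(cpgs)) == 2


class TestSummarizeDmr:
    def test_median_of_member_fractions(self):
        cpgs = [
            _cpg(s, {"T4_14": f}) for s, f in ((100, 0.80), (120, 0.84), (140, 0.88))
        ]
        dmr = summarize_dmr(GenomicInterval("chr1", 90, 150), cpgs)
        assert dmr.median_methylation["T4_14"] == pytest.approx(84.0)

    def test_single_cpg(self):
        dmr = summarize_dmr(GenomicInterval("chr1", 90, 150), [_cpg(100, {"g": 0.5})])
        assert dmr.median_methylation["g"] == pytest.approx(50.0)

    def test_order_invariance(self):
        cpgs = [_cpg(s, {"g": f}) for s, f in ((100, 0.2), (120, 0.6), (140, 0.9))]
        iv = GenomicInterval("chr1", 90, 150)
        a = summarize_dmr(iv, cpgs)
        b = summarize_dmr(iv, list(reversed(cpgs)))
        assert a.median_methylation == b.median_methylation

    def test_empty_dmr_errors(self):
        with pytest.raises(ValueError, match="no CpG"):
            summarize_dmr(GenomicInterval("chr1", 0, 10), [_cpg(100, {"g": 0.5})])


@pytest.mark.parametrize(
    "subgroup_pct,control_pct,expected_dm,expected_flag",
    [(55.0, 40.0, 15.0, "hyper"), (45.0, 40.0, 5.0, "unchanged"),
     (20.0, 45.0, -25.0, "hypo")],
)
def test_differential_methylation_flags(subgroup_pct, control_pct, expected_dm,
                                        expected_flag):
    dmr = DMR(id="d", interval=GenomicInterval("chr1", 0, 100), gene="g",
              median_methylation={"T4_14": subgroup_pct, "CONTROL": control_pct})
    annotated, flags = differential_methylation(dmr, threshold=10.0)
    assert annotated.dm_vs_control["T4_14"] == pytest.approx(expected_dm)
    assert flags["T4_14"] == expected_flag


def test_dm_antisymmetry_under_control_swap():
    """Choosing the other group as control negates every DM value."""
    iv = GenomicInterval("chr1", 0, 100)
    meth = {"A": 70.0, "B": 30.0}
    da, _ = differential_methylation(
        DMR(id="d", interval=iv, gene="g", median_methylation=dict(meth)),
        control="B",
    )
    db, _ = differential_methylation(
        DMR(id="d", interval=iv, gene="g", median_methylation=dict(meth)),
        control="A",
    )
    assert da.dm_vs_control["A"] == -db.dm_vs_control["B"] == 40.0


class TestAnnotateRegion:
    model = GenomicInterval("chr1", 50_000, 64_000, "+")

    def test_promoter(self):
        assert annotate_region(GenomicInterval("chr1", 48_900, 49_100), self.model) == "promoter"

    def test_body(self):
        assert annotate_region(GenomicInterval("chr1", 57_000, 57_200), self.model) == "body"

    def test_intergenic(self):
        assert annotate_region(GenomicInterval("chr1", 74_000, 74_200), self.model) == "intergenic"

    def test_promoter_wins_on_double_overlap(self):
        assert annotate_region(GenomicInterval("chr1", 50_400, 51_000), self.model) == "promoter"

    def test_minus_strand_promoter_at_end(self):
        minus = GenomicInterval("chr1", 50_000, 64_000, "-")
        assert annotate_region(GenomicInterval("chr1", 64_500, 64_700), minus) == "promoter"
        assert annotate_region(GenomicInterval("chr1", 51_000, 51_200), minus) == "body"


def _corr_dmrs(meth_by_group, gene="g", region_class="body"):
    return [
        DMR(id="d1", interval=GenomicInterval("chr1", 0, 100), gene=gene,
            region_class=region_class, median_methylation=dict(meth_by_group))
    ]


def test_correlation_perfect_linear():
    groups = ["A", "B", "C", "D"]
    meth = {g: 10.0 * i for i, g in enumerate(groups)}
    expr = {g: 5.0 + 0.3 * i for i, g in enumerate(groups)}
    corr = methylation_expression_correlation("g", _corr_dmrs(meth), expr, "body")
    assert corr.r_squared == pytest.approx(1.0)
    assert corr.passes_cutoff


def test_correlation_constant_methylation_undefined():
    groups = ["A", "B", "C"]
    meth = {g: 40.0 for g in groups}
    expr = {g: 5.0 + i for i, g in enumerate(groups)}
    corr = methylation_expression_correlation("g", _corr_dmrs(meth), expr, "body")
    assert corr.undefined
    assert not corr.passes_cutoff
    assert np.isnan(corr.r_squared)


def test_correlation_affine_invariance():
    """Rescaling either vector (percent vs fraction) leaves R^2 unchanged."""
    rng = np.random.default_rng(8)
    groups = [f"g{i}" for i in range(7)]
    meth = {g: float(v) for g, v in zip(groups, rng.uniform(5, 95, 7))}
    expr = {g: float(v) for g, v in zip(groups, rng.normal(8, 2, 7))}
    base = methylation_expression_correlation("g", _corr_dmrs(meth), expr, "body")
    scaled = methylation_expression_correlation(
        "g", _corr_dmrs({g: v / 100 * 3 + 1 for g, v in meth.items()}), expr, "body"
    )
    assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-12)


def test_correlation_needs_three_groups():
    with pytest.raises(ValueError, match=">= 3 groups"):
        methylation_expression_correlation(
            "g", _corr_dmrs({"A": 1.0, "B": 2.0}), {"A": 1.0, "B": 2.0}, "body"
        )


def test_noise_free_planted_coupling_r2_is_one(truth, noisefree_landscape):
    """DSG2-like planted methylation is collinear with expression: R^2 = 1."""
    cpgs, dmr_intervals = noisefree_landscape
    dmrs = [summarize_dmr(d, cpgs) for d in dmr_intervals]
    expr = {g: truth.baselines["DSG2"] for g in
            ["T4_14", "T11_14", "T14_16", "T14_20", "D1", "D2", "CONTROL"]}
    expr["T4_14"] += 1.8
    corr = methylation_expression_correlation("DSG2", dmrs, expr, "body")
    assert corr.r_squared == pytest.approx(1.0)


def test_noise_free_dm_flags_match_planted(truth, noisefree_landscape):
    cpgs, dmr_intervals = noisefree_landscape
    for planted in truth.planted_dmrs:
        summary = summarize_dmr(planted, cpgs)
        _, flags = differential_methylation(summary, threshold=10.0)
        ctrl = planted.median_methylation["CONTROL"]
        for group, flag in flags.items():
            dm = planted.median_methylation[group] - ctrl
            expected = "hyper" if dm > 10 else "hypo" if dm < -10 else "unchanged"
            assert flag == expected, (planted.id, group)
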