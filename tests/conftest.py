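"""Shared fixtures: planted-truth cohorts and independent oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from ren import synthetic


@pytest.fixture(scope="session")
def truth():
    return synthetic.default_truth(seed=0)


@pytest.fixture(scope="session")
def noisefree_cohort(truth):
    """Expression cohort with zero noise: planted effects recover exactly."""
    rng = np.random.default_rng(0)
    return synthetic.simulate_cohort_expression(
        10, list(truth.baselines), truth, noise_sd=0.0, rng=rng
    )


@pytest.fixture(scope="session")
def noisefree_landscape(truth):
    cpgs, dmrs = synthetic.simulate_methylation_landscape(
        truth, cpg_noise_sd=0.0, rng=np.random.default_rng(0)
    )
    return cpgs, dmrs


def mann_whitney_exact_oracle(x, y) -> float:
    """Two-tailed Mann-Whitney p by full enumeration of rank assignments.

    Independent of the implementation under test: enumerates every way of
    assigning the pooled ranks to the first sample and counts U statistics at
    least as extreme as the observed one.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == n1 + n2, "oracle requires no ties"
    ranks = pooled.argsort().argsort() + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_obs = min(u_obs, n1 * n2 - u_obs)  # two-tailed: distance from either tail
    count = total = 0
    for subset in combinations(range(n1 + n2), n1):
        r = sum(subset) + n1  # ranks are 1-based: sum of chosen positions + n1
        u = r - n1 * (n1 + 1) / 2
        u = min(u, n1 * n2 - u)
        if u <= u_obs:
            count += 1
        total += 1
    return count / total


def brute_force_overlap(dmr_start, dmr_end, peak_intervals) -> int:
    """Per-base overlap count between one interval and a union of intervals."""
    covered = np.zeros(dmr_end - dmr_start, dtype=bool)
    for s, e in peak_intervals:
        lo, hi = max(s, dmr_start), min(e, dmr_end)
        if hi > lo:
            covered[lo - dmr_start : hi - dmr_start] = True
    return int(covered.sum())
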