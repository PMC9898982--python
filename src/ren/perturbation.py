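"""Quantitative perturbation readouts: pyrosequencing per-CpG deltas with a
two-way ANOVA, ddCt qPCR fold change, and 4-parameter log-logistic IC50 fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, stats

from .core_io import Assay, PerturbationTable, log
from .expression import mann_whitney_p


@dataclass
class PyroResult:
    cpg_index: int
    mean_control: float
    mean_treated: float
    delta: float  # percentage points, treated - control
    p_value: float = float("nan")
    significant: bool = False


@dataclass
class QpcrFoldChange:
    target: str
    reference: str
    ddct: float  # cycles
    fold: float  # 2^-ddct
    p_value: float


@dataclass
class DoseResponseFit:
    time_point: float  # hours
    ic50: float  # uM
    hill: float
    top: float
    bottom: float
    rss: float
    extrapolated: bool = False


def _pyro_means(
    table: PerturbationTable, condition: str
) -> dict[int, np.ndarray]:
    sub = table.data[table.data["condition"] == condition]
    return {
        int(cpg): grp["value"].to_numpy()
        for cpg, grp in sub.groupby("key")
    }


def pyro_deltas(
    table: PerturbationTable, control: str, treated: str
) -> list[PyroResult]:
    """Per-CpG mean methylation difference (points) between two conditions."""
    if table.assay != Assay.PYRO:
        raise ValueError("expected a PYRO table")
    ctrl, trt = _pyro_means(table, control), _pyro_means(table, treated)
    missing = sorted(set(ctrl) ^ set(trt))
    if missing:
        raise ValueError(f"CpG(s) missing in one condition: {missing}")
    results = []
    for cpg in sorted(ctrl):
        if min(ctrl[cpg].size, trt[cpg].size) < 3:
            raise ValueError(f"CpG {cpg}: need >= 3 replicates per condition")
        mc, mt = float(ctrl[cpg].mean()), float(trt[cpg].mean())
        results.append(
            PyroResult(cpg_index=cpg, mean_control=mc, mean_treated=mt, delta=mt - mc)
        )
    return results


def pyro_anova(
    table: PerturbationTable,
    control: str,
    treated: str,
    alpha: float = 0.001,
) -> tuple[list[PyroResult], pd.DataFrame]:
    """Two-way ANOVA (condition x CpG with interaction) on pyro methylation.

    Per-CpG significance comes from the condition contrast within that CpG,
    tested against the full-model residual mean square. Returns the per-CpG
    results and the ANOVA table.
    """
    results = pyro_deltas(table, control, treated)
    df = table.data[table.data["condition"].isin([control, treated])].copy()
    counts = df.groupby(["condition", "key"])["value"].count()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per (condition, CpG) cell")
    model = smf.ols("value ~ C(condition) * C(key)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    dof = int(model.df_resid)
    for res in results:
        sub = df[df["key"] == str(res.cpg_index)]
        n1 = (sub["condition"] == control).sum()
        n2 = (sub["condition"] == treated).sum()
        se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
        if se == 0:  # degenerate zero-variance limit
            res.p_value = 0.0 if res.delta != 0 else 1.0
        else:
            t = res.delta / se
            res.p_value = float(2.0 * stats.t.sf(abs(t), dof))
        res.significant = res.p_value < alpha
    log.info(
        "pyro ANOVA: %d/%d CpGs significant at alpha=%g",
        sum(r.significant for r in results), len(results), alpha,
    )
    return results, anova


def ddct_fold_change(
    table: PerturbationTable,
    target: str,
    reference: str,
    control: str,
    treated: str,
) -> QpcrFoldChange:
    """Relative qPCR quantification: fold = 2^-ddCt against a reference gene.

    dCt = mean Ct(target) - mean Ct(reference) per condition; ddCt is the
    treated-minus-control difference. The p-value is a two-tailed
    Mann-Whitney test on the per-replicate dCt values.
    """
    if table.assay != Assay.QPCR:
        raise ValueError("expected a QPCR table")
    cts: dict[tuple[str, str], np.ndarray] = {}
    for cond in (control, treated):
        for gene in (target, reference):
            sub = table.data[
                (table.data["condition"] == cond) & (table.data["key"] == gene)
            ].sort_values("replicate")
            if len(sub) < 3:
                raise ValueError(
                    f"missing or underpowered Ct set: condition={cond!r} gene={gene!r}"
                )
            cts[(cond, gene)] = sub["value"].to_numpy()

    def dct(cond: str) -> np.ndarray:
        # per-replicate dCt, paired by replicate index
        return cts[(cond, target)] - cts[(cond, reference)]

    dct_c, dct_t = dct(control), dct(treated)
    ddct = float(dct_t.mean() - dct_c.mean())
    fold = float(2.0 ** (-ddct))
    p = mann_whitney_p(dct_t, dct_c)
    return QpcrFoldChange(target=target, reference=reference, ddct=ddct, fold=fold,
                          p_value=p)


def _four_pl(c, bottom, top, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_ic50(
    table: PerturbationTable, time_point: float, top_tolerance: float = 0.05
) -> DoseResponseFit:
    """Least-squares 4-parameter log-logistic fit of viability vs dose.

    Viability must be normalized to untreated = 1; because of that anchor the
    top plateau is constrained to 1 +- ``top_tolerance`` (the tested doses
    rarely sample the plateau itself, which would otherwise leave top, and
    with it the IC50, poorly identified). The condition column is matched as
    ``*_<time_point>h``. A mean response that increases with dose (or is
    flat) refuses the fit. An IC50 outside the tested concentration range is
    flagged extrapolated.
    """
    if table.assay != Assay.VIABILITY:
        raise ValueError("expected a VIABILITY table")
    cond = f"{int(time_point)}h"
    sub = table.data[table.data["condition"].str.endswith(cond)].copy()
    if sub.empty:
        raise ValueError(f"no viability rows for time point {time_point} h")
    sub["conc"] = sub["key"].astype(float)
    if sub["conc"].nunique() < 5:
        raise ValueError("need >= 5 distinct concentrations")
    means = sub.groupby("conc")["value"].mean().sort_index()
    conc = means.index.to_numpy()
    slope = np.polyfit(np.log(conc), means.to_numpy(), 1)[0]
    if slope >= 0:
        raise ValueError(
            "mean response does not decrease with dose; dose-response fit refused"
        )
    c = sub["conc"].to_numpy()
    v = sub["value"].to_numpy()
    top_lo, top_hi = 1.0 - top_tolerance, 1.0 + top_tolerance
    top0 = float(np.clip(means.max(), top_lo + 1e-9, top_hi - 1e-9))
    bottom0 = float(means.min())
    half = (top0 + bottom0) / 2.0
    ic50_0 = float(conc[np.argmin(np.abs(means.to_numpy() - half))])
    p0 = [bottom0, top0, ic50_0, 1.0]
    bounds = ([0.0, top_lo, 1e-9, 0.1], [np.inf, top_hi, np.inf, 10.0])
    popt, _ = optimize.curve_fit(_four_pl, c, v, p0=p0, bounds=bounds, maxfev=10000)
    bottom, top, ic50, hill = (float(x) for x in popt)
    rss = float(np.sum((v - _four_pl(c, *popt)) ** 2))
    extrapolated = not (conc.min() <= ic50 <= conc.max())
    if extrapolated:
        log.warning("IC50 %.3g uM lies outside the tested range; extrapolated", ic50)
    return DoseResponseFit(time_point=time_point, ic50=ic50, hill=hill, top=top,
                           bottom=bottom, rss=rss, extrapolated=extrapolated)
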