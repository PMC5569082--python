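"""Statistical machinery for the PT-OCT experiments.

Exact two-tailed Mann-Whitney U (full enumeration of group labelings at the
study's small sample sizes, normal approximation with tie and continuity
corrections otherwise), through-origin linear regression with R² and a 95%
confidence interval on the slope, and the experiment-level comparisons
(pigmented vs albino, gold-nanorod vs control lesions, power-series
detection limits, FWHM invariance across powers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "TestResult",
    "FitResult",
    "mann_whitney_exact",
    "linear_fit_origin",
    "compare_groups",
    "power_series_analysis",
]

EXACT_MAX_N = 8  # enumeration cost capped at C(16, 8) = 12 870 labelings


@dataclass
class TestResult:
    U: float
    p_two_tailed: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approx"

    def __post_init__(self) -> None:
        assert 0 < self.p_two_tailed <= 1.0 + 1e-12


@dataclass
class FitResult:
    slope: float
    r_squared: float
    ci95: tuple
    n_points: int
    stderr: float = float("nan")
    r2_defined: bool = True


# ---------------------------------------------------------------------------
def mann_whitney_exact(group_a, group_b) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    U is computed from rank sums (midranks for ties). With both group sizes
    at most 8 and no ties, the p-value is exact: the smaller tail
    probability over all C(n1+n2, n1) equally likely labelings, doubled and
    clipped at 1. Otherwise the normal approximation with continuity and
    tie corrections is used.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ParameterError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if max(n1, n2) <= EXACT_MAX_N and not has_ties:
        u_obs = min(u1, u2)
        total = comb(n1 + n2, n1)
        count = 0
        all_ranks = range(1, n1 + n2 + 1)
        base = n1 * (n1 + 1) / 2.0
        for chosen in combinations(all_ranks, n1):
            u = sum(chosen) - base
            if min(u, n1 * n2 - u) <= u_obs:
                count += 1
        # each labeling contributes to exactly one tail unless centered;
        # min-tail counting already covers both tails symmetrically
        p = min(1.0, count / total)
        return TestResult(float(u1), p, n1, n2, "exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(float(u1), 1.0, n1, n2, "normal_approx")
    z = max(abs(u1 - mu) - 0.5, 0.0) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(float(u1), float(p), n1, n2, "normal_approx")


# ---------------------------------------------------------------------------
def linear_fit_origin(x, y, centered_r2: bool = True, weights=None) -> FitResult:
    """Least-squares line through the origin: slope = Σxy/Σx².

    With ``weights`` (∝ 1/variance per point) the weighted analogue
    Σwxy/Σwx² is used, with the standard error computed from the weighted
    residuals — appropriate when the scatter grows with x, as it does for
    photothermal signal vs laser power. R² is computed against the centered
    total sum of squares by default (the convention matching ordinary
    regression reports); the uncentered alternative is available with a
    warning since it typically inflates R² for through-origin fits. The 95%
    CI is slope ± t(0.975, n−1)·se.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ParameterError("need >= 2 paired points")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float).ravel()
    if w.shape != x.shape or np.any(w <= 0):
        raise ParameterError("weights must be positive, one per point")
    sxx = float(np.sum(w * x * x))
    if sxx == 0:
        raise ParameterError("all x are zero: slope through origin undefined")
    slope = float(np.sum(w * x * y) / sxx)
    resid = y - slope * x
    ss_res = float(np.sum(resid**2))
    ss_res_w = float(np.sum(w * resid**2))
    if centered_r2:
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        warnings.warn("uncentered R² inflates goodness-of-fit for through-origin models")
        ss_tot = float(np.sum(y**2))
    if ss_tot > 0:
        r2, r2_def = 1.0 - ss_res / ss_tot, True
    else:
        r2, r2_def = 0.0, False
    df = x.size - 1
    se = float(np.sqrt(ss_res_w / df / sxx)) if df > 0 else float("nan")
    tcrit = float(sps.t.ppf(0.975, df)) if df > 0 else float("nan")
    ci = (slope - tcrit * se, slope + tcrit * se)
    return FitResult(slope, float(r2), ci, x.size, se, r2_def)


# ---------------------------------------------------------------------------
DEFAULT_PAIRS = (("pigmented", "albino"), ("gnr", "control"))


def compare_groups(
    table: pd.DataFrame,
    pairs=DEFAULT_PAIRS,
    value_col: str = "value_nm",
    group_col: str = "group",
) -> dict:
    """Exact MWU for each pre-registered group pair of a per-eye table.

    No multiple-testing correction is applied (the comparisons are few and
    pre-registered); the result records how many were run. Returns
    ``{(a, b): TestResult}`` plus significance flags at 0.05 and 0.01.
    """
    labels = set(table[group_col].unique())
    results: dict = {}
    for ga, gb in pairs:
        if ga not in labels or gb not in labels:
            raise ParameterError(f"unknown group label in pair ({ga!r}, {gb!r})")
        va = table.loc[table[group_col] == ga, value_col].to_numpy()
        vb = table.loc[table[group_col] == gb, value_col].to_numpy()
        results[(ga, gb)] = mann_whitney_exact(va, vb)
    results["n_comparisons"] = len(pairs)
    results["flags"] = {
        pair: {"p<0.05": r.p_two_tailed < 0.05, "p<0.01": r.p_two_tailed < 0.01}
        for pair, r in results.items()
        if isinstance(r, TestResult)
    }
    return results


def power_series_analysis(
    table: pd.DataFrame,
    power_col: str = "power_mw",
    value_col: str = "value_nm",
) -> dict:
    """Through-origin fit of mean signal vs photothermal power.

    Expects one row per (eye, power). The fit runs on the per-power means
    over the nonzero powers, weighted by 1/P²: between-eye scatter in
    photothermal signal grows in proportion to the power (the signal is
    multiplicative in absorber content), so proportional-variance weighting
    keeps the nominal CI honest. Also returns a descriptive table
    (mean/std/n per power) and — when a 0 mW group is present — per-power
    exact-MWU detection flags marking powers whose signals do not differ
    from the laser-off group (the detection limit).
    """
    powers = np.sort(table[power_col].unique())
    if powers.size < 2:
        raise ParameterError("need at least two power levels")
    desc = (
        table.groupby(power_col)[value_col]
        .agg(mean="mean", std="std", n="count")
        .reset_index()
    )
    nz = desc[power_col] > 0
    if nz.sum() < 2:
        raise ParameterError("need at least two nonzero power levels for the fit")
    x = desc.loc[nz, power_col].to_numpy(dtype=float)
    y = desc.loc[nz, "mean"].to_numpy(dtype=float)
    fit = linear_fit_origin(x, y, weights=1.0 / x**2)

    detection = {}
    if 0.0 in powers:
        zero_vals = table.loc[table[power_col] == 0.0, value_col].to_numpy()
        for p in powers:
            if p == 0.0:
                continue
            vals = table.loc[table[power_col] == p, value_col].to_numpy()
            try:
                res = mann_whitney_exact(vals, zero_vals)
                detection[float(p)] = {
                    "p": res.p_two_tailed,
                    "detected": res.p_two_tailed < 0.05,
                }
            except ParameterError:
                continue
    return {"fit": fit, "per_power": desc, "detection": detection}
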