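"""Two-group descriptive and inferential comparison of extracted measures.

Continuous measures are compared with Welch's unequal-variance t-test or the
Mann-Whitney U-test, both two-sided.  Which test applies is governed by a
policy: a Shapiro-Wilk normality gate (default), a fixed per-measure map
(rank tests for input resistance and delay-to-first-spike, Welch elsewhere),
or forcing one test.  Binary per-cell measures (firing at the minimal step,
resting below -80 mV) are summarised descriptively as k/n and percent.

No multiple-comparison correction is applied by default — each measure is
reported on its own — but Holm adjustment across measures is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, DesignError

POLICIES = ("shapiro_gate", "force_welch", "force_mwu", "per_measure_map")

#: Measures the rank test is pinned to under the per-measure-map policy.
DEFAULT_MEASURE_MAP: dict[str, str] = {
    "r_in_MOhm": "mann_whitney_u",
    "delay_first_ap_s": "mann_whitney_u",
    "delay_100_s": "mann_whitney_u",
}


@dataclass
class StatResult:
    measure: str
    test: str
    statistic: float
    df: float | None
    p_two_sided: float
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    sem_x: float
    sem_y: float
    median_x: float
    median_y: float
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t: statistic, Satterthwaite df, two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise DesignError("Welch t needs >= 2 values per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise DegenerateDataError("both groups have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (reported as min(U_x, U_y)) and two-sided p.

    Exact p by enumeration of rank configurations when the pooled sample is
    small (n_x + n_y <= 20) and tie-free; otherwise the normal approximation
    with midrank tie correction and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 1 or y.size < 1:
        raise DesignError("Mann-Whitney needs >= 1 value per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    u_x = float(res.statistic)
    u = min(u_x, x.size * y.size - u_x)
    return u, float(res.pvalue)


def choose_test(x, y, policy: str = "shapiro_gate", measure: str = "",
                measure_map: dict[str, str] | None = None,
                alpha: float = 0.05) -> str:
    """Select 'welch_t' or 'mann_whitney_u' for one comparison."""
    if policy not in POLICIES:
        raise DesignError(f"unknown test policy {policy!r}; choose from {POLICIES}")
    if policy == "force_welch":
        return "welch_t"
    if policy == "force_mwu":
        return "mann_whitney_u"
    if policy == "per_measure_map":
        mapping = DEFAULT_MEASURE_MAP if measure_map is None else measure_map
        return mapping.get(measure, "welch_t")
    # shapiro_gate: rank test iff either group rejects normality
    for g in (np.asarray(x, float), np.asarray(y, float)):
        g = g[~np.isnan(g)]
        if g.size >= 3 and np.ptp(g) > 0 and sps.shapiro(g).pvalue < alpha:
            return "mann_whitney_u"
    return "welch_t"


def _sem(g: np.ndarray) -> float:
    return float(g.std(ddof=1) / math.sqrt(g.size)) if g.size >= 2 else math.nan


def compare_measure(x, y, measure: str, policy: str = "shapiro_gate",
                    measure_map: dict[str, str] | None = None) -> StatResult:
    """One two-group comparison with pairwise NaN dropping."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        return StatResult(measure, "none", math.nan, None, math.nan,
                          int(x.size), int(y.size),
                          float(np.mean(x)) if x.size else math.nan,
                          float(np.mean(y)) if y.size else math.nan,
                          _sem(x), _sem(y),
                          float(np.median(x)) if x.size else math.nan,
                          float(np.median(y)) if y.size else math.nan,
                          note="fewer than 2 values per group after dropping missing")
    test = choose_test(x, y, policy, measure, measure_map)
    note = ""
    if test == "welch_t":
        try:
            stat, df, p = welch_t(x, y)
        except DegenerateDataError:
            stat, df, p = math.nan, math.nan, math.nan
            note = "degenerate: zero variance in both groups"
    else:
        stat, p = mann_whitney_u(x, y)
        df = None
    return StatResult(measure, test, stat, df, p, int(x.size), int(y.size),
                      float(np.mean(x)), float(np.mean(y)), _sem(x), _sem(y),
                      float(np.median(x)), float(np.median(y)), note)


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, float)
    ok = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    ps = p[ok]
    order = np.argsort(ps)
    m = ps.size
    running = 0.0
    out = np.empty(m)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        out[idx] = min(1.0, running)
    adj[ok] = out
    return adj.tolist()


def compare_groups(
    features: pd.DataFrame,
    measures: list[str] | None = None,
    group_col: str = "group_label",
    groups: tuple[str, str] | None = None,
    policy: str = "shapiro_gate",
    measure_map: dict[str, str] | None = None,
    fraction_measures: list[str] | None = None,
    holm: bool = False,
) -> dict:
    """Compare every measure between two groups of a feature table.

    Returns ``{"comparisons": [StatResult dicts], "fractions": {...}}``.
    ``fraction_measures`` (binary 0/1 columns) are tallied as k/n and percent
    per group instead of being tested.
    """
    if group_col not in features.columns:
        raise DesignError(f"feature table has no {group_col!r} column")
    labels = list(pd.unique(features[group_col])) if groups is None else list(groups)
    if len(labels) != 2:
        raise DesignError(f"exactly two groups required, found {labels}")
    gx = features[features[group_col] == labels[0]]
    gy = features[features[group_col] == labels[1]]
    for lbl, g in zip(labels, (gx, gy)):
        if len(g) < 2:
            raise DesignError(f"group {lbl!r} has {len(g)} cells; need >= 2")

    if measures is None:
        skip = {group_col, "cell_id"}
        fm = set(fraction_measures or [])
        measures = [c for c in features.columns
                    if c not in skip and c not in fm
                    and pd.api.types.is_numeric_dtype(features[c])]

    comparisons = [
        compare_measure(gx[m].to_numpy(float), gy[m].to_numpy(float), m,
                        policy, measure_map)
        for m in measures
    ]
    if holm:
        adj = holm_adjust([c.p_two_sided for c in comparisons])
        for c, a in zip(comparisons, adj):
            c.note = (c.note + "; " if c.note else "") + f"holm_p={a:.4g}"

    fractions = {}
    for m in fraction_measures or []:
        fractions[m] = {}
        for lbl, g in ((labels[0], gx), (labels[1], gy)):
            vals = g[m].to_numpy(float)
            vals = vals[~np.isnan(vals)]
            k, n = int(vals.sum()), int(vals.size)
            fractions[m][lbl] = {
                "k": k, "n": n,
                "percent": 100.0 * k / n if n else math.nan,
            }

    return {
        "groups": labels,
        "comparisons": [c.to_dict() for c in comparisons],
        "fractions": fractions,
    }
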