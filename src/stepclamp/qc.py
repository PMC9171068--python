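"""Cell-inclusion and outlier-removal rules.

Three rules operate at different levels:

* series-resistance drift excludes a whole cell when |Rs_end - Rs_start|
  changes by >= 20% (inclusive boundary) of the starting value;
* a minimum-spike rule gates entry into the accommodation analyses — more
  than 5 spikes at +100 pA, and at >= +200 pA enough spikes both for cell
  health (17) and to cover the late interval range being collapsed;
* a two-sided single-iteration Grubbs test flags at most one outlier per
  measure at alpha = 0.05.

Excluded cells are flagged, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import MetadataError
from .trace_io import CellRecording


@dataclass(frozen=True)
class RsCheck:
    """Series-resistance drift check result for one cell."""

    passed: bool
    assessed: bool
    change_fraction: float | None


@dataclass
class QCReport:
    """Per-cell rule outcomes plus per-measure outlier flags."""

    rs_checks: dict[str, RsCheck] = field(default_factory=dict)
    accommodation_included: dict[str, dict[float, bool]] = field(default_factory=dict)
    outliers: dict[str, list[dict]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "series_resistance": {
                cid: {"passed": c.passed, "assessed": c.assessed,
                      "change_fraction": c.change_fraction}
                for cid, c in self.rs_checks.items()
            },
            "accommodation_included": {
                cid: {f"{amp:g}": ok for amp, ok in d.items()}
                for cid, d in self.accommodation_included.items()
            },
            "outliers": self.outliers,
        }


def series_resistance_filter(rec: CellRecording, max_change: float = 0.20) -> RsCheck:
    """Fail iff |Rs_end - Rs_start| / Rs_start >= max_change (inclusive).

    Synthetic cells without Rs metadata pass with ``assessed=False``.
    """
    rs0, rs1 = rec.rs_start_MOhm, rec.rs_end_MOhm
    if rs0 is None or rs1 is None:
        return RsCheck(passed=True, assessed=False, change_fraction=None)
    if rs0 <= 0 or rs1 <= 0:
        raise MetadataError(
            f"cell {rec.cell_id}: series resistance must be > 0 (got {rs0}, {rs1})"
        )
    change = abs(rs1 - rs0) / rs0
    return RsCheck(passed=change < max_change, assessed=True, change_fraction=change)


#: Minimum-spike rules per amplitude threshold: at +100 pA strictly more than
#: 5 spikes; at >= +200 pA at least 17 spikes (both reported variants of the
#: health rule are encoded; the interval-coverage requirement is added by
#: :func:`min_spike_filter`).
DEFAULT_MIN_SPIKE_RULES: dict[float, tuple[str, int]] = {
    100.0: (">", 5),
    200.0: (">=", 17),
}


def min_spike_filter(
    spike_count: float,
    amplitude_pA: float,
    late_range: tuple[int, int] | None = None,
    rules: dict[float, tuple[str, int]] | None = None,
) -> bool:
    """Is a cell eligible for the accommodation analysis at one amplitude?

    Applies the per-amplitude health rule (the entry at the largest rule
    amplitude <= the step amplitude) and, when a late interval range is to
    be collapsed, additionally requires enough spikes to cover it
    (``late_range[1] + 1`` peaks give ``late_range[1]`` intervals).
    """
    rules = DEFAULT_MIN_SPIKE_RULES if rules is None else rules
    applicable = [a for a in rules if a <= amplitude_pA]
    ok = True
    if applicable:
        op, k = rules[max(applicable)]
        ok = spike_count > k if op == ">" else spike_count >= k
    if late_range is not None:
        ok = ok and spike_count >= late_range[1] + 1
    return bool(ok)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G* for sample size n."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier(values, alpha: float = 0.05) -> list[int]:
    """Indices of points flagged by a single-iteration two-sided Grubbs test.

    G = max|x - mean| / sd (sample sd) compared against the t-derived
    critical value; at most one point (the most extreme) can be flagged.
    Zero-variance input yields no outlier.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3 non-missing values")
    sd = x.std(ddof=1)
    if sd == 0:
        return []
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    G = dev[i] / sd
    return [i] if G > grubbs_critical(n, alpha) else []


def grubbs_report(values, alpha: float = 0.05) -> dict:
    """Grubbs decision with the statistic and critical value, for the audit trail."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    sd = x.std(ddof=1)
    if sd == 0:
        return {"outlier_index": None, "G": 0.0,
                "G_critical": grubbs_critical(x.size, alpha), "alpha": alpha}
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    G = float(dev[i] / sd)
    crit = grubbs_critical(x.size, alpha)
    return {"outlier_index": i if G > crit else None, "G": G,
            "G_critical": crit, "alpha": alpha, "value": float(x[i]) if G > crit else None}
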