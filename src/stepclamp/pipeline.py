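"""Orchestration: simulate -> extract -> QC -> compare, from one config.

The feature table has one row per cell with a documented column schema:

== ====================== =====================================================
group   column             meaning
== ====================== =====================================================
id      cell_id            unique cell identifier
id      group_label        experimental group
qc      rs_assessed        1 if series resistance was monitored
qc      rs_pass            1 if |Rs change| < 20% (1 when not assessed)
passive rmp_mV             resting membrane potential (100 ms baseline)
passive rmp_below_80       1 iff RMP < -80 mV
passive r_in_MOhm          input resistance at -100 pA
passive v_resp_<amp>       |steady state - baseline| at each amplitude (mV)
passive tau67_<amp>        67% settling time at hyperpolarizing steps (ms)
passive sag_mV             sag amplitude at -400 pA
passive sag_norm           sag / voltage response at -400 pA
active  rheobase_pA        mean of per-trial minimal firing amplitudes
active  rheobase_step_pA   smallest protocol amplitude with >= 1 spike
active  ap_threshold_mV    threshold of first AP at rheobase
active  ap_threshold_rel_mV  threshold - RMP
active  ap_count_<amp>     trial-averaged spike count per depolarizing step
active  fired_at_100       1 iff the cell fired at the minimal (+100 pA) step
active  delay_first_ap_s   onset-to-first-peak delay at the rheobase step
active  delay_100_s        same at +100 pA (NaN when silent there)
active  ap_amplitude_mV / ap_halfwidth_ms / ap_ahp_mV / ap_rise_ms /
        ap_decay_ms        first-AP waveform at rheobase
accom   accom_f1/f2/f3_<amp>  instantaneous frequency at intervals 1-3
accom   accom_late_<amp>   collapsed late-interval mean (NaN when the cell
                           fails the minimum-spike rule for that amplitude)
accom   accom_included_<amp>  1 iff the minimum-spike rule admitted the cell
misc    non_firing         1 iff no spike at any amplitude
== ====================== =====================================================

Negative amplitudes appear in column names with an ``m`` prefix
(``v_resp_m400`` is the response at -400 pA).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from . import stats as stats_mod
from .errors import SpecError, StepClampError
from .passive import extract_passive
from .spikes import ACCOM_LATE_RANGES, DetectorConfig, extract_active
from .synthetic import default_cohort_spec, generate_cohort
from .trace_io import CellRecording, StepProtocol, read_sweep_bundle, write_sweep_bundle

log = logging.getLogger("stepclamp")

#: Binary per-cell columns summarised as k/n fractions, not tested.
FRACTION_MEASURES = ["fired_at_100", "rmp_below_80"]

#: Columns never entered into the group comparisons.
NON_MEASURE_COLUMNS = {"cell_id", "group_label", "rs_assessed", "rs_pass",
                       "non_firing"} | set(FRACTION_MEASURES)


def _amp_col(prefix: str, amp: float) -> str:
    a = int(round(amp))
    return f"{prefix}_m{-a}" if a < 0 else f"{prefix}_{a}"


@dataclass
class PipelineConfig:
    """One config drives all stages; exactly one of cohort/bundle is set."""

    cohort_n_cells: int | None = None
    bundle: str | None = None
    seed: int | None = None
    protocol: StepProtocol = field(default_factory=StepProtocol)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    stats_policy: str = "shapiro_gate"
    grubbs: bool = True
    grubbs_alpha: float = 0.05
    outdir: str = "stepclamp_out"

    def __post_init__(self) -> None:
        if (self.cohort_n_cells is None) == (self.bundle is None):
            raise SpecError("exactly one of cohort_n_cells / bundle must be set")
        if self.cohort_n_cells is not None and self.seed is None:
            raise SpecError("a seed is required when simulating a cohort")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        kw: dict = {}
        cohort = raw.get("cohort") or {}
        if "n_cells" in cohort:
            kw["cohort_n_cells"] = int(cohort["n_cells"])
        if "seed" in cohort:
            kw["seed"] = int(cohort["seed"])
        if "bundle" in raw:
            kw["bundle"] = raw["bundle"]
        if "protocol" in raw:
            kw["protocol"] = StepProtocol(**raw["protocol"])
        if "detector" in raw:
            kw["detector"] = DetectorConfig(**raw["detector"])
        st = raw.get("stats") or {}
        if "policy" in st:
            kw["stats_policy"] = st["policy"]
        if "grubbs" in st:
            kw["grubbs"] = bool(st["grubbs"])
        if "grubbs_alpha" in st:
            kw["grubbs_alpha"] = float(st["grubbs_alpha"])
        if "outdir" in raw:
            kw["outdir"] = raw["outdir"]
        kw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kw)


def run_simulate(config: PipelineConfig) -> tuple[Path, Path]:
    """Generate the configured cohort; write the sweep bundle + ground truth."""
    if config.cohort_n_cells is None:
        raise SpecError("run_simulate needs a cohort spec, not an input bundle")
    spec = default_cohort_spec(n_cells=config.cohort_n_cells, seed=config.seed,
                               protocol=config.protocol)
    recs, truth = generate_cohort(spec)
    out = Path(config.outdir)
    bundle = write_sweep_bundle(recs, out / "bundle")
    gt_path = out / "ground_truth.csv"
    truth.to_csv(gt_path, index=False)
    log.info("simulated %d cells into %s", len(recs), bundle)
    return bundle, gt_path


def extract_features(
    rec: CellRecording,
    detector: DetectorConfig | None = None,
    late_ranges: dict[float, tuple[int, int]] | None = None,
) -> dict:
    """One cell's full feature-record row (see module docstring for schema)."""
    detector = detector or DetectorConfig()
    late_ranges = ACCOM_LATE_RANGES if late_ranges is None else late_ranges
    row: dict = {"cell_id": rec.cell_id, "group_label": rec.group_label}

    rs = qc_mod.series_resistance_filter(rec)
    row["rs_assessed"] = int(rs.assessed)
    row["rs_pass"] = int(rs.passed)

    pf = extract_passive(rec, detector)
    row["rmp_mV"] = pf.rmp_mV
    row["rmp_below_80"] = pf.rmp_below_80
    row["r_in_MOhm"] = pf.r_in_MOhm
    for amp, v in pf.v_response_mV.items():
        row[_amp_col("v_resp", amp)] = v
    for amp, v in pf.tau67_ms.items():
        row[_amp_col("tau67", amp)] = v
    row["sag_mV"] = pf.sag_mV
    row["sag_norm"] = pf.sag_norm

    af = extract_active(rec, pf.rmp_mV, detector, late_ranges)
    row["rheobase_pA"] = af.rheobase_pA
    row["rheobase_step_pA"] = af.rheobase_step_pA
    row["ap_threshold_mV"] = af.ap_threshold_mV
    row["ap_threshold_rel_mV"] = af.ap_threshold_rel_mV
    for amp, c in af.ap_count.items():
        row[_amp_col("ap_count", amp)] = c
    row["fired_at_100"] = af.fired_at_min_step
    row["delay_first_ap_s"] = af.delay_first_ap_s
    row["delay_100_s"] = af.delay_s.get(100.0, math.nan)
    wf = af.waveform
    row["ap_amplitude_mV"] = wf.amplitude_mV if wf else math.nan
    row["ap_halfwidth_ms"] = wf.halfwidth_ms if wf else math.nan
    row["ap_ahp_mV"] = wf.ahp_mV if wf else math.nan
    row["ap_rise_ms"] = wf.rise_ms if wf else math.nan
    row["ap_decay_ms"] = wf.decay_ms if wf else math.nan
    row["non_firing"] = int(af.non_firing)

    for amp, rng in late_ranges.items():
        summ = af.accommodation.get(amp)
        count = af.ap_count.get(amp, 0.0)
        included = qc_mod.min_spike_filter(count, amp, late_range=rng)
        row[_amp_col("accom_included", amp)] = int(included)
        row[_amp_col("accom_f1", amp)] = summ.f1_Hz if summ else math.nan
        row[_amp_col("accom_f2", amp)] = summ.f2_Hz if summ else math.nan
        row[_amp_col("accom_f3", amp)] = summ.f3_Hz if summ else math.nan
        late = summ.late_mean_Hz if summ else math.nan
        row[_amp_col("accom_late", amp)] = late if included else math.nan
    return row


def run_extract(
    recordings: list[CellRecording] | str | Path,
    detector: DetectorConfig | None = None,
    late_ranges: dict[float, tuple[int, int]] | None = None,
) -> tuple[pd.DataFrame, qc_mod.QCReport]:
    """Feature table + QC report for a bundle path or in-memory recordings.

    Per-cell extraction failures are logged and recorded as missing values;
    the cohort never aborts, and no cell is silently dropped.
    """
    if isinstance(recordings, (str, Path)):
        recordings = read_sweep_bundle(recordings)
    detector = detector or DetectorConfig()
    report = qc_mod.QCReport()
    rows = []
    for rec in recordings:
        try:
            row = extract_features(rec, detector, late_ranges)
        except StepClampError as e:
            log.warning("cell %s: extraction failed (%s); keeping row with "
                        "missing values", rec.cell_id, e)
            row = {"cell_id": rec.cell_id, "group_label": rec.group_label}
        rows.append(row)
        report.rs_checks[rec.cell_id] = qc_mod.series_resistance_filter(rec)
        report.accommodation_included[rec.cell_id] = {
            amp: bool(row.get(_amp_col("accom_included", amp), False))
            for amp in (late_ranges or ACCOM_LATE_RANGES)
        }
    return pd.DataFrame(rows), report


def run_compare(
    features: pd.DataFrame,
    policy: str = "shapiro_gate",
    grubbs: bool = True,
    grubbs_alpha: float = 0.05,
    groups: tuple[str, str] | None = None,
    measures: list[str] | None = None,
    qc_report: qc_mod.QCReport | None = None,
) -> dict:
    """Group comparison over the feature table, with optional outlier removal.

    Grubbs outliers are detected per measure per group and masked (with an
    audit entry naming the cell and value) before testing.
    """
    feats = features.copy()
    if measures is None:
        measures = [c for c in feats.columns
                    if c not in NON_MEASURE_COLUMNS
                    and not c.startswith("accom_included")
                    and pd.api.types.is_numeric_dtype(feats[c])]
    labels = groups or tuple(pd.unique(feats["group_label"]))

    outlier_log: dict[str, list[dict]] = {}
    if grubbs:
        for m in measures:
            for lbl in labels:
                mask = feats["group_label"] == lbl
                vals = feats.loc[mask, m].to_numpy(float)
                ok = ~np.isnan(vals)
                if ok.sum() < 3:
                    continue
                rep = qc_mod.grubbs_report(vals[ok], grubbs_alpha)
                if rep["outlier_index"] is not None:
                    idx_local = np.nonzero(ok)[0][rep["outlier_index"]]
                    row_idx = feats.index[mask][idx_local]
                    cid = feats.loc[row_idx, "cell_id"] if "cell_id" in feats else str(row_idx)
                    outlier_log.setdefault(m, []).append(
                        {"group": str(lbl), "cell_id": str(cid),
                         "value": rep["value"], "G": rep["G"],
                         "G_critical": rep["G_critical"]})
                    log.info("outlier removed: measure=%s group=%s cell=%s "
                             "value=%.4g (G=%.3f > G*=%.3f)", m, lbl, cid,
                             rep["value"], rep["G"], rep["G_critical"])
                    feats.loc[row_idx, m] = np.nan
    if qc_report is not None:
        qc_report.outliers = outlier_log

    out = stats_mod.compare_groups(
        feats, measures=measures, groups=groups, policy=policy,
        fraction_measures=[m for m in FRACTION_MEASURES if m in feats.columns],
    )
    out["outliers_removed"] = outlier_log
    return out


def _stats_text(result: dict) -> str:
    lines = [f"groups: {result['groups'][0]} vs {result['groups'][1]}", ""]
    hdr = (f"{'measure':<22}{'test':<16}{'stat':>9}{'df':>8}{'p':>10}"
           f"{'n':>8}{'mean_x':>10}{'mean_y':>10}{'mdn_x':>9}{'mdn_y':>9}")
    lines.append(hdr)
    lines.append("-" * len(hdr))
    for c in result["comparisons"]:
        df = f"{c['df']:.2f}" if c.get("df") is not None and not math.isnan(c["df"] or math.nan) else "-"
        lines.append(
            f"{c['measure']:<22}{c['test']:<16}{c['statistic']:>9.3f}{df:>8}"
            f"{c['p_two_sided']:>10.4f}{c['n_x']:>4}/{c['n_y']:<3}"
            f"{c['mean_x']:>10.3f}{c['mean_y']:>10.3f}"
            f"{c['median_x']:>9.3f}{c['median_y']:>9.3f}"
        )
    for m, groups in result.get("fractions", {}).items():
        for lbl, f in groups.items():
            lines.append(f"{m} [{lbl}]: {f['k']}/{f['n']} = {f['percent']:.1f}%")
    return "\n".join(lines) + "\n"


def run_all(config: PipelineConfig) -> dict:
    """Full pipeline; writes features.csv, qc_report.json, stats.json, stats.txt."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.cohort_n_cells is not None:
        bundle, _ = run_simulate(config)
        recordings: list[CellRecording] | Path = bundle
    else:
        recordings = Path(config.bundle)
    features, report = run_extract(recordings, config.detector)
    result = run_compare(features, config.stats_policy, config.grubbs,
                         config.grubbs_alpha, qc_report=report)
    features.to_csv(out / "features.csv", index=False)
    (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    (out / "stats.json").write_text(json.dumps(result, indent=1))
    (out / "stats.txt").write_text(_stats_text(result))
    log.info("pipeline outputs written to %s", out)
    return result
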