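"""Action-potential detection and active membrane properties.

The detector finds spike peaks as local maxima above a peak floor that are
preceded, within a short look-back window, by a depolarization rate of at
least ``dvdt_thresh_mV_per_ms``.  The threshold point of each spike is the
last sample before the peak at which dV/dt first sustainedly exceeds that
rate — i.e. the sample after the final sub-threshold-slope sample.  These
criteria (20 mV/ms, peak floor -10 mV, 1 ms minimum separation) follow
common current-clamp practice and are fully configurable.

Active measures built on the detector: rheobase, first-AP threshold and
waveform morphometrics (amplitude, half-width, 10-90% rise / 90-10% decay,
AHP relative to threshold), AP counts per step (f-I), firing probability at
the minimal depolarizing step, delay to first spike, instantaneous firing
frequency per spike interval, and accommodation summaries (early intervals
verbatim plus the collapsed mean of a late interval range).

Spike features are computed per trial and aggregated afterwards — counts and
delays by the mean, rheobase by the mean of per-trial minima — because
pointwise trial averaging would destroy AP waveforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .trace_io import CellRecording, Sweep

#: Late-interval ranges (inclusive, 1-based spike-interval indices) whose
#: collapsed mean summarises steady-state accommodation, per amplitude.
ACCOM_LATE_RANGES: dict[float, tuple[int, int]] = {200.0: (15, 20), 300.0: (19, 25)}


@dataclass(frozen=True)
class DetectorConfig:
    """Spike-detector settings (all voltages mV, rates mV/ms, times ms)."""

    dvdt_thresh_mV_per_ms: float = 20.0
    peak_floor_mV: float | None = -10.0
    min_isi_ms: float = 1.0
    search_back_ms: float = 5.0
    ahp_window_ms: float = 50.0


@dataclass(frozen=True)
class Spike:
    peak_time_s: float
    peak_mV: float
    threshold_time_s: float
    threshold_mV: float
    peak_index: int
    threshold_index: int


@dataclass
class SpikeTrain:
    """Detected spikes of one sweep, in time order."""

    spikes: list[Spike]
    amplitude_pA: float | None = None
    trial: int | None = None

    def __len__(self) -> int:
        return len(self.spikes)

    def peak_times(self) -> np.ndarray:
        return np.array([s.peak_time_s for s in self.spikes])


@dataclass
class APWaveform:
    """First-AP morphometrics; AHP is positive when the post-spike minimum
    falls below threshold."""

    threshold_mV: float
    amplitude_mV: float
    halfwidth_ms: float
    ahp_mV: float
    rise_ms: float
    decay_ms: float


@dataclass
class AccommodationSummary:
    """Early instantaneous frequencies (intervals 1-3) and collapsed late mean."""

    f1_Hz: float
    f2_Hz: float
    f3_Hz: float
    late_mean_Hz: float
    late_range: tuple[int, int]
    n_spikes: float


@dataclass
class ActiveFeatures:
    rheobase_pA: float
    rheobase_step_pA: float
    ap_threshold_mV: float
    ap_threshold_rel_mV: float
    ap_count: dict[float, float]
    fired_at_min_step: int
    delay_s: dict[float, float]
    delay_first_ap_s: float
    waveform: APWaveform | None
    inst_freq_Hz: dict[float, np.ndarray]
    accommodation: dict[float, AccommodationSummary]
    non_firing: bool = False


# ---------------------------------------------------------------------------
# Detection


def detect_spikes(
    voltage_mV: np.ndarray | Sweep,
    sampling_rate_hz: float | None = None,
    config: DetectorConfig | None = None,
) -> SpikeTrain:
    """Detect spikes on one uniformly sampled voltage trace.

    Accepts either a :class:`Sweep` or a raw array plus its sampling rate.
    An empty train is a valid result.
    """
    config = config or DetectorConfig()
    amp = trial = None
    if isinstance(voltage_mV, Sweep):
        sw = voltage_mV
        v = sw.voltage_mV
        fs = 1.0 / (sw.time_s[1] - sw.time_s[0]) if sw.time_s.size > 1 else 0.0
        amp, trial = sw.amplitude_pA, sw.trial
    else:
        v = np.asarray(voltage_mV, dtype=float)
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz is required for raw arrays")
        fs = float(sampling_rate_hz)
    if v.size < 3:
        return SpikeTrain([], amp, trial)

    dt_ms = 1000.0 / fs
    dvdt = np.diff(v) / dt_ms  # dvdt[i]: slope from sample i to i+1
    distance = max(1, int(round(config.min_isi_ms / dt_ms)))
    peaks, _ = find_peaks(v, height=config.peak_floor_mV, distance=distance)
    back = max(1, int(round(config.search_back_ms / dt_ms)))

    spikes: list[Spike] = []
    for p in peaks:
        lo = max(0, p - back)
        window = dvdt[lo:p]
        if window.size == 0 or window.max() < config.dvdt_thresh_mV_per_ms:
            continue
        # last sub-threshold-slope sample before the peak; threshold is the
        # sample after it (where dV/dt first sustainedly exceeds the rate)
        below = np.nonzero(window < config.dvdt_thresh_mV_per_ms)[0]
        th = lo + (below[-1] + 1 if below.size else 0)
        if th >= p:
            th = p - 1
        spikes.append(
            Spike(
                peak_time_s=p / fs,
                peak_mV=float(v[p]),
                threshold_time_s=th / fs,
                threshold_mV=float(v[th]),
                peak_index=int(p),
                threshold_index=int(th),
            )
        )
    return SpikeTrain(spikes, amp, trial)


def clip_spikes(voltage_mV: np.ndarray, sampling_rate_hz: float,
                config: DetectorConfig | None = None) -> np.ndarray:
    """Replace each detected spike by a threshold-to-threshold linear bridge.

    Used before steady-state averaging of spiking sweeps.  The bridge runs
    from the spike's threshold sample to the first later sample at/below the
    threshold voltage (bounded by the next spike's threshold).
    """
    config = config or DetectorConfig()
    train = detect_spikes(voltage_mV, sampling_rate_hz, config)
    if not train.spikes:
        return np.asarray(voltage_mV, dtype=float)
    v = np.asarray(voltage_mV, dtype=float).copy()
    n = v.size
    for k, sp in enumerate(train.spikes):
        i0 = sp.threshold_index
        stop = train.spikes[k + 1].threshold_index if k + 1 < len(train.spikes) else n
        i1 = stop
        for j in range(sp.peak_index + 1, stop):
            if v[j] <= sp.threshold_mV:
                i1 = j
                break
        i1 = min(i1, n - 1)
        if i1 > i0:
            v[i0:i1 + 1] = np.linspace(v[i0], v[i1], i1 - i0 + 1)
    return v


# ---------------------------------------------------------------------------
# Waveform morphometrics


def _cross_time(v: np.ndarray, i_from: int, i_to: int, level: float,
                rising: bool, fs: float) -> float:
    """Linearly interpolated time (s) of the first crossing of ``level``
    between samples ``i_from`` and ``i_to`` (exclusive upper bound)."""
    step = 1 if i_to >= i_from else -1
    rng = range(i_from, i_to, step)
    for i in rng:
        a, b = v[i], v[i + 1]
        hit = (a < level <= b) if rising else (a > level >= b)
        if hit or a == level:
            if a == level:
                return i / fs
            frac = (level - a) / (b - a)
            return (i + frac) / fs
    return math.nan


def measure_waveform(v: np.ndarray, fs: float, spike: Spike,
                     next_threshold_index: int | None = None,
                     config: DetectorConfig | None = None) -> APWaveform:
    """Morphometrics of a single AP on its source trace.

    Crossing points at 50% (half-width) and 10/90% (rise/decay) of the
    threshold-to-peak amplitude are located by linear interpolation.  The
    AHP minimum is searched from the peak to the next spike's threshold or
    ``ahp_window_ms``, whichever comes first.
    """
    config = config or DetectorConfig()
    thr, peak = spike.threshold_mV, spike.peak_mV
    amp = peak - thr
    i_th, i_pk = spike.threshold_index, spike.peak_index
    n = v.size

    lvl50 = thr + 0.5 * amp
    lvl10 = thr + 0.1 * amp
    lvl90 = thr + 0.9 * amp
    fall_stop = min(n - 1, i_pk + int(round(config.ahp_window_ms * fs / 1000.0)))

    t50r = _cross_time(v, i_th, i_pk, lvl50, True, fs)
    t50f = _cross_time(v, i_pk, fall_stop, lvl50, False, fs)
    t10r = _cross_time(v, i_th, i_pk, lvl10, True, fs)
    t90r = _cross_time(v, i_th, i_pk, lvl90, True, fs)
    t90f = _cross_time(v, i_pk, fall_stop, lvl90, False, fs)
    t10f = _cross_time(v, i_pk, fall_stop, lvl10, False, fs)

    ahp_stop = fall_stop if next_threshold_index is None else min(fall_stop, next_threshold_index)
    if ahp_stop > i_pk + 1:
        ahp = thr - float(np.min(v[i_pk + 1:ahp_stop + 1]))
    else:
        ahp = math.nan

    return APWaveform(
        threshold_mV=thr,
        amplitude_mV=amp,
        halfwidth_ms=(t50f - t50r) * 1000.0,
        ahp_mV=ahp,
        rise_ms=(t90r - t10r) * 1000.0,
        decay_ms=(t10f - t90f) * 1000.0,
    )


# ---------------------------------------------------------------------------
# Per-recording measures


def _trains_by_amp(rec: CellRecording, config: DetectorConfig | None,
                   depolarizing_only: bool = True) -> dict[float, list[SpikeTrain]]:
    out: dict[float, list[SpikeTrain]] = {}
    for amp in rec.amplitudes():
        if depolarizing_only and amp <= 0:
            continue
        out[amp] = [detect_spikes(s, config=config) for s in rec.sweeps_at(amp)]
    return out


def measure_rheobase(rec: CellRecording, config: DetectorConfig | None = None,
                     trains: dict[float, list[SpikeTrain]] | None = None) -> float:
    """Minimum depolarizing amplitude evoking >= 1 spike, per trial, averaged.

    Each trial contributes its own minimal firing amplitude; the cell's
    rheobase is the mean over trials that fired anywhere.  NaN for a cell
    that never fires (the non-firing flag is carried by the caller).
    """
    trains = trains if trains is not None else _trains_by_amp(rec, config)
    n_trials = rec.protocol.n_trials
    per_trial: list[float] = []
    for t_idx in range(n_trials):
        mins = [amp for amp, ts in sorted(trains.items())
                if t_idx < len(ts) and len(ts[t_idx]) > 0]
        if mins:
            per_trial.append(min(mins))
    return float(np.mean(per_trial)) if per_trial else math.nan


def _first_firing(trains: dict[float, list[SpikeTrain]]):
    """(amplitude, trial index, train) of the first spike-bearing sweep, in
    (ascending amplitude, ascending trial) order; None if the cell is silent."""
    for amp in sorted(trains):
        for t_idx, tr in enumerate(trains[amp]):
            if len(tr) > 0:
                return amp, t_idx, tr
    return None


def ap_threshold(rec: CellRecording, rmp_mV: float,
                 config: DetectorConfig | None = None,
                 trains: dict[float, list[SpikeTrain]] | None = None
                 ) -> tuple[float, float]:
    """Threshold of the first AP at the rheobase step, absolute and RMP-relative."""
    trains = trains if trains is not None else _trains_by_amp(rec, config)
    hit = _first_firing(trains)
    if hit is None:
        return math.nan, math.nan
    thr = hit[2].spikes[0].threshold_mV
    return thr, thr - rmp_mV


def ap_waveform(rec: CellRecording, config: DetectorConfig | None = None,
                trains: dict[float, list[SpikeTrain]] | None = None
                ) -> APWaveform | None:
    """Waveform of the first AP fired at the rheobase step (None if silent)."""
    config = config or DetectorConfig()
    trains = trains if trains is not None else _trains_by_amp(rec, config)
    hit = _first_firing(trains)
    if hit is None:
        return None
    amp, t_idx, train = hit
    sweep = rec.sweeps_at(amp)[t_idx]
    nxt = train.spikes[1].threshold_index if len(train) > 1 else None
    return measure_waveform(sweep.voltage_mV, rec.protocol.sampling_rate_hz,
                            train.spikes[0], nxt, config)


def count_aps(rec: CellRecording, config: DetectorConfig | None = None,
              trains: dict[float, list[SpikeTrain]] | None = None
              ) -> dict[float, float]:
    """f-I table: trial-averaged spike count per depolarizing amplitude."""
    trains = trains if trains is not None else _trains_by_amp(rec, config)
    return {amp: float(np.mean([len(t) for t in ts])) for amp, ts in sorted(trains.items())}


def firing_indicator(rec: CellRecording, amplitude_pA: float = 100.0,
                     config: DetectorConfig | None = None,
                     rule: str = "majority",
                     trains: dict[float, list[SpikeTrain]] | None = None) -> int:
    """1 iff the cell fired >= 1 AP at the given amplitude.

    ``rule='majority'`` (default) requires firing in more than half of the
    trials; ``rule='any'`` requires a single firing trial.
    """
    if trains is not None and amplitude_pA in trains:
        ts = trains[amplitude_pA]
    else:
        sw = rec.sweeps_at(amplitude_pA)
        if not sw:
            raise KeyError(f"no sweeps at {amplitude_pA:g} pA")
        ts = [detect_spikes(s, config=config) for s in sw]
    fired = [len(t) > 0 for t in ts]
    if rule == "majority":
        return int(sum(fired) > len(fired) / 2)
    if rule == "any":
        return int(any(fired))
    raise ValueError(f"unknown firing rule {rule!r}")


def firing_probability(recs: list[CellRecording], amplitude_pA: float = 100.0,
                       config: DetectorConfig | None = None,
                       rule: str = "majority") -> tuple[list[int], float]:
    """Per-cell firing indicators at one amplitude and their group fraction."""
    ind = [firing_indicator(r, amplitude_pA, config, rule) for r in recs]
    return ind, float(np.mean(ind)) if ind else math.nan


def fraction_summary(indicators: list[int] | np.ndarray) -> tuple[int, int, float]:
    """Descriptive k/n tally and percentage for a binary per-cell measure."""
    ind = np.asarray(indicators, dtype=float)
    k = int(np.nansum(ind))
    n = int(np.sum(~np.isnan(ind)))
    return k, n, 100.0 * k / n if n else math.nan


def delay_to_first_spike(rec: CellRecording, amplitude_pA: float,
                         config: DetectorConfig | None = None,
                         trains: dict[float, list[SpikeTrain]] | None = None) -> float:
    """Step onset to first-AP *peak* (s), averaged over firing trials; NaN if silent."""
    if trains is not None and amplitude_pA in trains:
        ts = trains[amplitude_pA]
    else:
        ts = [detect_spikes(s, config=config) for s in rec.sweeps_at(amplitude_pA)]
    onset = rec.protocol.pre_step_s
    delays = [t.spikes[0].peak_time_s - onset for t in ts if len(t) > 0]
    return float(np.mean(delays)) if delays else math.nan


def instantaneous_frequencies(train: SpikeTrain | np.ndarray) -> np.ndarray:
    """f_i = 1/(t_{i+1} - t_i) in Hz, i = 1..n-1, from spike peak times."""
    t = train.peak_times() if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if t.size < 2:
        return np.empty(0)
    return 1.0 / np.diff(t)


def accommodation_summary(freqs: np.ndarray,
                          late_range: tuple[int, int] = (15, 20),
                          n_spikes: float = math.nan) -> AccommodationSummary:
    """Early intervals 1-3 verbatim plus the collapsed late-interval mean.

    ``late_range`` is an inclusive 1-based index range; a train too short to
    cover it yields NaN (the cell drops out of that comparison).
    """
    f = np.asarray(freqs, dtype=float)
    lo, hi = late_range
    def pick(i: int) -> float:
        return float(f[i - 1]) if f.size >= i else math.nan
    late = float(np.mean(f[lo - 1:hi])) if f.size >= hi else math.nan
    return AccommodationSummary(pick(1), pick(2), pick(3), late, late_range, n_spikes)


def extract_active(rec: CellRecording, rmp_mV: float,
                   config: DetectorConfig | None = None,
                   late_ranges: dict[float, tuple[int, int]] | None = None
                   ) -> ActiveFeatures:
    """All detector-based features for one cell."""
    config = config or DetectorConfig()
    late_ranges = ACCOM_LATE_RANGES if late_ranges is None else late_ranges
    trains = _trains_by_amp(rec, config)

    counts = count_aps(rec, config, trains=trains)
    rheo = measure_rheobase(rec, config, trains=trains)
    non_firing = math.isnan(rheo)
    step_amps = sorted(trains)
    firing_amps = [a for a in step_amps if any(len(t) for t in trains[a])]
    rheo_step = firing_amps[0] if firing_amps else math.nan

    thr, thr_rel = ap_threshold(rec, rmp_mV, config, trains=trains)
    wf = ap_waveform(rec, config, trains=trains)

    delays = {amp: delay_to_first_spike(rec, amp, config, trains=trains)
              for amp in firing_amps}
    min_step = step_amps[0] if step_amps else math.nan
    fired_min = firing_indicator(rec, min_step, config, trains=trains) if step_amps else 0

    inst: dict[float, np.ndarray] = {}
    for amp in firing_amps:
        per_trial = [instantaneous_frequencies(t) for t in trains[amp] if len(t) >= 2]
        if not per_trial:
            inst[amp] = np.empty(0)
            continue
        width = max(len(f) for f in per_trial)
        grid = np.full((len(per_trial), width), np.nan)
        for i, f in enumerate(per_trial):
            grid[i, :len(f)] = f
        inst[amp] = np.nanmean(grid, axis=0)

    accom: dict[float, AccommodationSummary] = {}
    for amp, rng in late_ranges.items():
        if amp in inst:
            accom[amp] = accommodation_summary(inst[amp], rng, counts.get(amp, math.nan))

    return ActiveFeatures(
        rheobase_pA=rheo,
        rheobase_step_pA=rheo_step,
        ap_threshold_mV=thr,
        ap_threshold_rel_mV=thr_rel,
        ap_count=counts,
        fired_at_min_step=int(fired_min),
        delay_s=delays,
        delay_first_ap_s=delays.get(rheo_step, math.nan) if firing_amps else math.nan,
        waveform=wf,
        inst_freq_Hz=inst,
        accommodation=accom,
        non_firing=non_firing,
    )


# ---------------------------------------------------------------------------
# Parametric AP fixtures


def parametric_ap_trace(
    peak_times_s: list[float],
    fs_hz: float = 10_000.0,
    dur_s: float = 0.5,
    baseline_mV: float = -70.0,
    threshold_mV: float = -45.0,
    peak_mV: float = 35.0,
    rise_ms: float = 0.5,
    decay_ms: float = 1.0,
    trough_mV: float | None = None,
    trough_ms: float = 2.0,
    approach_ms: float = 5.0,
    recover_ms: float = 5.0,
) -> np.ndarray:
    """Piecewise-linear trace with analytically known AP shapes.

    Each AP: slow ramp from baseline to threshold over ``approach_ms``
    (sub-detector slope), linear rise to the peak over ``rise_ms``, linear
    decay back to threshold over ``decay_ms``, optional linear excursion to
    ``trough_mV`` over ``trough_ms``, then recovery to baseline.  Choosing
    durations that are multiples of the sample period makes every closed-form
    crossing land exactly on the sampled polyline.
    """
    pts: list[tuple[float, float]] = [(0.0, baseline_mV)]
    for tp in sorted(peak_times_s):
        t_th = tp - rise_ms / 1000.0
        pts.append((t_th - approach_ms / 1000.0, baseline_mV))
        pts.append((t_th, threshold_mV))
        pts.append((tp, peak_mV))
        t_back = tp + decay_ms / 1000.0
        pts.append((t_back, threshold_mV))
        if trough_mV is not None:
            t_tr = t_back + trough_ms / 1000.0
            pts.append((t_tr, trough_mV))
            pts.append((t_tr + recover_ms / 1000.0, baseline_mV))
        else:
            pts.append((t_back + recover_ms / 1000.0, baseline_mV))
    pts.append((dur_s, baseline_mV))
    ts = np.array([p[0] for p in pts])
    vs = np.array([p[1] for p in pts])
    if np.any(np.diff(ts) < 0):
        raise ValueError("AP shapes overlap: space peak_times_s further apart")
    grid = np.arange(int(round(dur_s * fs_hz)) + 1) / fs_hz
    return np.interp(grid, ts, vs)
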