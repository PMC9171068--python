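"""Passive membrane properties from step-protocol recordings.

Operational definitions follow the standard current-clamp conventions used
for dentate granule cells:

* **RMP** — mean voltage over the final 100 ms before step onset.
* **Voltage response** — |steady state - baseline|, with steady state taken
  as the mean over the final 160 ms of the step after spike clipping.
* **Input resistance** — steady-state deflection at the -100 pA step, where
  H-current (sag) contamination is negligible, converted to MOhm.
* **Membrane time constant** — time to reach 67% of the steady-state
  deflection on a hyperpolarizing step (threshold crossing, not a fit).
* **Sag** — difference between the peak hyperpolarization and the steady
  state at -400 pA; "normalized sag" divides by the voltage response there.

All passive measures are computed on the pointwise trial-averaged trace;
spiking depolarizing sweeps are spike-clipped per trial *before* averaging,
since averaging across trials with jittered spike times would corrupt the
steady-state estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientBaselineError,
    NonSettlingError,
    ProtocolError,
    UndefinedResponseError,
)
from .spikes import DetectorConfig, clip_spikes
from .trace_io import CellRecording

#: Baseline window before step onset used for RMP and per-sweep baselines (s).
BASELINE_WINDOW_S = 0.100

#: Steady-state window: the final 160 ms of the step, used consistently for
#: every steady-state measurement (the sag definition fixes it at -400 pA and
#: the same convention is applied to all other amplitudes).
STEADY_WINDOW_S = 0.160

#: Resting-level category boundary (mV) for the "rests below -80" tally.
RMP_CATEGORY_MV = -80.0


@dataclass
class PassiveFeatures:
    """Per-cell passive feature vector."""

    rmp_mV: float
    rmp_below_80: int
    r_in_MOhm: float
    v_response_mV: dict[float, float]
    tau67_ms: dict[float, float]
    sag_mV: float
    sag_response_mV: float
    sag_norm: float
    anomalies: list[str] = field(default_factory=list)


def _clipped_mean_trace(rec: CellRecording, amplitude_pA: float,
                        detector: DetectorConfig | None) -> np.ndarray:
    """Trial-averaged voltage at one amplitude, spike-clipped per trial."""
    sw = rec.sweeps_at(amplitude_pA)
    if not sw:
        raise ProtocolError(f"cell {rec.cell_id}: no sweep at {amplitude_pA:g} pA")
    detector = detector or DetectorConfig()
    fs = rec.protocol.sampling_rate_hz
    traces = []
    for s in sw:
        v = s.voltage_mV
        if amplitude_pA > 0:
            v = clip_spikes(v, fs, detector)
        traces.append(v)
    return np.mean(traces, axis=0)


def _baseline(rec: CellRecording, trace: np.ndarray) -> float:
    proto = rec.protocol
    n_base = int(round(BASELINE_WINDOW_S * proto.sampling_rate_hz))
    if proto.onset_index < n_base:
        raise InsufficientBaselineError(
            f"pre-step epoch {proto.pre_step_s*1000:.0f} ms < "
            f"{BASELINE_WINDOW_S*1000:.0f} ms baseline window"
        )
    return float(np.mean(trace[proto.onset_index - n_base:proto.onset_index]))


def _steady_state(rec: CellRecording, trace: np.ndarray) -> float:
    proto = rec.protocol
    n_ss = int(round(STEADY_WINDOW_S * proto.sampling_rate_hz))
    window = trace[proto.offset_index - n_ss:proto.offset_index]
    if np.isnan(window).all():
        raise UndefinedResponseError("steady-state window entirely consumed by spikes")
    return float(np.nanmean(window))


def measure_rmp(rec: CellRecording, all_sweeps: bool = False) -> tuple[float, int]:
    """Resting membrane potential: mean over the 100 ms before step onset.

    By default the baseline of the first sweep recorded (the lowest
    amplitude), averaged across its trials; ``all_sweeps=True`` averages the
    baselines of every sweep instead.  Also returns the indicator for the
    resting-level tally (1 iff RMP < -80 mV).
    """
    proto = rec.protocol
    n_base = int(round(BASELINE_WINDOW_S * proto.sampling_rate_hz))
    if proto.onset_index < n_base:
        raise InsufficientBaselineError(
            f"pre-step epoch {proto.pre_step_s*1000:.0f} ms < "
            f"{BASELINE_WINDOW_S*1000:.0f} ms baseline window"
        )
    if all_sweeps:
        sweeps = list(rec.sweeps)
    else:
        amps = rec.amplitudes()
        if not amps:
            raise ProtocolError(f"cell {rec.cell_id}: no sweeps")
        sweeps = rec.sweeps_at(amps[0])
    vals = [np.mean(s.voltage_mV[proto.onset_index - n_base:proto.onset_index])
            for s in sweeps]
    rmp = float(np.mean(vals))
    return rmp, int(rmp < RMP_CATEGORY_MV)


def measure_voltage_response(rec: CellRecording, amplitude_pA: float,
                             detector: DetectorConfig | None = None) -> float:
    """|steady-state - baseline| deflection magnitude at one amplitude (mV)."""
    trace = _clipped_mean_trace(rec, amplitude_pA, detector)
    return abs(_steady_state(rec, trace) - _baseline(rec, trace))


def measure_input_resistance(rec: CellRecording) -> float:
    """Input resistance (MOhm) from the -100 pA steady-state deflection."""
    if -100.0 not in rec.protocol.amplitudes_pA or not rec.sweeps_at(-100.0):
        raise ProtocolError(f"cell {rec.cell_id}: no -100 pA sweep for input resistance")
    deflection = measure_voltage_response(rec, -100.0)
    return deflection / 100.0 * 1000.0


def measure_time_constant(rec: CellRecording, amplitude_pA: float) -> float:
    """67% settling time (ms) on a hyperpolarizing step, linearly interpolated.

    The first time after step onset at which the trial-averaged voltage
    crosses baseline + 0.67 * (steady state - baseline).
    """
    if amplitude_pA >= 0:
        raise ValueError("membrane time constant is defined on hyperpolarizing steps")
    trace = _clipped_mean_trace(rec, amplitude_pA, None)
    proto = rec.protocol
    base = _baseline(rec, trace)
    ss = _steady_state(rec, trace)
    target = base + 0.67 * (ss - base)
    seg = trace[proto.onset_index:proto.offset_index]
    crossed = np.nonzero(seg <= target)[0] if ss < base else np.nonzero(seg >= target)[0]
    if len(crossed) == 0:
        raise NonSettlingError(
            f"cell {rec.cell_id}: no 67% crossing within the {amplitude_pA:g} pA step"
        )
    i = int(crossed[0])
    dt_ms = 1000.0 / proto.sampling_rate_hz
    if i == 0:
        return 0.0
    frac = (target - seg[i - 1]) / (seg[i] - seg[i - 1])
    return (i - 1 + float(frac)) * dt_ms


def measure_sag(rec: CellRecording, amplitude_pA: float = -400.0) -> tuple[float, float, float]:
    """Sag amplitude, voltage response, and normalized sag at -400 pA.

    ``sag_mV`` is steady-state voltage minus the minimum voltage during the
    step (positive when the membrane relaxes back toward baseline);
    ``sag_norm = sag_mV / response_mV``.  A negative sag (steady state below
    the peak) is returned as-is for QC flagging, never clamped.
    """
    if not rec.sweeps_at(amplitude_pA):
        raise ProtocolError(f"cell {rec.cell_id}: no {amplitude_pA:g} pA sweep for sag")
    trace = _clipped_mean_trace(rec, amplitude_pA, None)
    proto = rec.protocol
    ss = _steady_state(rec, trace)
    peak = float(np.min(trace[proto.onset_index:proto.offset_index]))
    sag = ss - peak
    response = abs(ss - _baseline(rec, trace))
    if response == 0:
        raise UndefinedResponseError("zero voltage response: normalized sag undefined")
    return sag, response, sag / response


def extract_passive(rec: CellRecording,
                    detector: DetectorConfig | None = None) -> PassiveFeatures:
    """All passive features for one cell."""
    rmp, below = measure_rmp(rec)
    anomalies: list[str] = []

    v_resp: dict[float, float] = {}
    for amp in rec.protocol.amplitudes_pA:
        if not rec.sweeps_at(amp):
            continue
        try:
            v_resp[amp] = measure_voltage_response(rec, amp, detector)
        except UndefinedResponseError:
            v_resp[amp] = float("nan")
            anomalies.append(f"voltage response undefined at {amp:g} pA")

    tau: dict[float, float] = {}
    for amp in rec.protocol.amplitudes_pA:
        if amp >= 0 or not rec.sweeps_at(amp):
            continue
        try:
            tau[amp] = measure_time_constant(rec, amp)
        except NonSettlingError:
            tau[amp] = float("nan")
            anomalies.append(f"no 67% crossing at {amp:g} pA")

    r_in = measure_input_resistance(rec)
    sag, sag_resp, sag_norm = measure_sag(rec)
    if sag < 0:
        anomalies.append(f"negative sag ({sag:.3f} mV): peak above steady state")

    return PassiveFeatures(
        rmp_mV=rmp,
        rmp_below_80=below,
        r_in_MOhm=r_in,
        v_response_mV=v_resp,
        tau67_ms=tau,
        sag_mV=sag,
        sag_response_mV=sag_resp,
        sag_norm=sag_norm,
        anomalies=anomalies,
    )
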