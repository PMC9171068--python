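"""Shared fixtures: hand-built recordings and simulated cohorts.

The expensive simulated cohorts (parameter-recovery and two-group
directional cohorts) are session-scoped so the feature extraction runs once
for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stepclamp.synthetic import (
    CohortSpec,
    NeuronParams,
    ParamDist,
    default_cohort_spec,
    generate_cohort,
)
from stepclamp.pipeline import run_extract
from stepclamp.trace_io import CellRecording, StepProtocol, Sweep
from stepclamp.validation import recovery_cohort_spec


@pytest.fixture
def small_protocol() -> StepProtocol:
    """Tiny protocol for I/O tests: short epochs, minimal sample counts."""
    return StepProtocol(amplitudes_pA=(-100.0, 100.0), pre_step_s=0.01,
                        step_dur_s=0.04, post_step_s=0.01, n_trials=2,
                        sampling_rate_hz=5000.0)


def build_recording(
    protocol: StepProtocol,
    trace_fn,
    cell_id: str = "cell",
    group_label: str = "grp",
    **meta,
) -> CellRecording:
    """Recording whose voltage at (amplitude, trial) is given by ``trace_fn``."""
    t = protocol.times()
    sweeps = [
        Sweep(trial=trial, amplitude_pA=amp, time_s=t,
              voltage_mV=np.asarray(trace_fn(amp, trial), dtype=float))
        for amp in protocol.amplitudes_pA
        for trial in range(1, protocol.n_trials + 1)
    ]
    return CellRecording(cell_id=cell_id, group_label=group_label,
                         protocol=protocol, sweeps=sweeps, **meta)


def step_trace(protocol: StepProtocol, baseline: float, delta: float,
               tau_ms: float | None = None, sag_to: float | None = None,
               sag_tau_ms: float = 30.0) -> np.ndarray:
    """Analytic step response: instant or RC, optionally with a sag relaxation.

    With ``tau_ms`` the step epoch follows baseline + delta(1 - exp(-t/tau)).
    With ``sag_to`` the step relaxes from its extreme toward ``sag_to``.
    """
    v = np.full(protocol.n_samples, baseline)
    on, off = protocol.onset_index, protocol.offset_index
    tt = (np.arange(off - on)) / protocol.sampling_rate_hz * 1000.0  # ms
    if tau_ms is None:
        seg = np.full(off - on, baseline + delta)
    else:
        seg = baseline + delta * (1.0 - np.exp(-tt / tau_ms))
    if sag_to is not None:
        target = np.full_like(seg, sag_to)
        lam = 1.0 - np.exp(-tt / sag_tau_ms)
        seg = seg + (target - seg) * lam
    v[on:off] = seg
    return v


# ---------------------------------------------------------------------------
# Simulated cohorts (session-scoped; reused by unit + acceptance tests)

RECOVERY_SEED = 123


@pytest.fixture(scope="session")
def recovery_cohort():
    """Noise-free recovery cohort (10 sag-free + 10 sag cells) with truth."""
    recs, truth = generate_cohort(recovery_cohort_spec(RECOVERY_SEED),
                                  with_rheobase=True)
    features, _ = run_extract(recs)
    return recs, truth, features


@pytest.fixture(scope="session")
def directional_cohort():
    """Default two-regime cohort at the pinned comparison seed."""
    spec = default_cohort_spec(n_cells=20, seed=42)
    recs, truth = generate_cohort(spec, with_rheobase=False)
    features, _ = run_extract(recs)
    return recs, truth, features


@pytest.fixture(scope="session")
def wt_cell_with_events():
    """One default-parameter cell on the full protocol, with the simulator's
    spike event log."""
    from stepclamp.synthetic import simulate_cell

    rec, events = simulate_cell(NeuronParams(), StepProtocol(), seed=7,
                                with_events=True)
    return rec, events
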