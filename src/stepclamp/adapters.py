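"""Optional adapters from standard electrophysiology containers.

These are contracts, not hard dependencies: each function maps one container
file to :class:`~stepclamp.trace_io.CellRecording` objects and imports its
reader lazily, so the core pipeline works without pyabf/pynwb installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .trace_io import CellRecording, StepProtocol, Sweep


def _build_recording(
    cell_id: str,
    group_label: str,
    protocol: StepProtocol,
    traces: list[tuple[int, float, np.ndarray]],
) -> CellRecording:
    sweeps = [
        Sweep(trial=trial, amplitude_pA=amp, time_s=protocol.times(), voltage_mV=v)
        for trial, amp, v in traces
    ]
    return CellRecording(cell_id=cell_id, group_label=group_label,
                         protocol=protocol, sweeps=sweeps, partial=True)


def read_abf(path: str | Path, protocol: StepProtocol, group_label: str = "") -> CellRecording:
    """Map an Axon Binary Format file onto one CellRecording.

    Sweeps are matched to protocol amplitudes in acquisition order, cycling
    trials within each amplitude.  Requires the ``pyabf`` package.
    """
    try:
        import pyabf  # type: ignore
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("reading ABF files requires the optional 'pyabf' package") from e

    abf = pyabf.ABF(str(path))  # pragma: no cover
    traces = []
    for i in range(abf.sweepCount):
        abf.setSweep(i)
        amp = protocol.amplitudes_pA[i % len(protocol.amplitudes_pA)]
        trial = i // len(protocol.amplitudes_pA) + 1
        traces.append((trial, amp, np.asarray(abf.sweepY, dtype=float)))
    return _build_recording(Path(path).stem, group_label, protocol, traces)


def read_nwb(path: str | Path, protocol: StepProtocol, group_label: str = "") -> CellRecording:
    """Map an NWB intracellular-ephys file onto one CellRecording.

    Reads every CurrentClampSeries acquisition in object order.  Requires the
    ``pynwb`` package.
    """
    try:
        from pynwb import NWBHDF5IO  # type: ignore
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("reading NWB files requires the optional 'pynwb' package") from e

    traces = []  # pragma: no cover
    with NWBHDF5IO(str(path), "r") as io:
        nwb = io.read()
        i = 0
        for obj in nwb.acquisition.values():
            if type(obj).__name__ != "CurrentClampSeries":
                continue
            amp = protocol.amplitudes_pA[i % len(protocol.amplitudes_pA)]
            trial = i // len(protocol.amplitudes_pA) + 1
            traces.append((trial, amp, np.asarray(obj.data[:], dtype=float) * 1000.0))
            i += 1
    return _build_recording(Path(path).stem, group_label, protocol, traces)
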