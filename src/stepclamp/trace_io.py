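"""Data model and on-disk format for current-clamp step-protocol recordings.

A *sweep bundle* is a directory holding ``manifest.json`` (protocol and
per-cell metadata) plus ``sweeps.csv`` (one long table with columns
``cell_id,trial,amplitude_pA,time_s,voltage_mV``).  The long-CSV layout keeps
fixtures diffable and streamable at the cost of some redundancy.

Fixed unit convention throughout the package: voltage in mV, current in pA,
conductance in nS, capacitance in pF, resistance in MOhm, time in seconds on
trace grids and milliseconds for membrane time constants.  These choices make
ground-truth arithmetic exact (pF/nS = ms, nS*mV = pA, 1000/nS = MOhm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BundleCorruptionError,
    BundleFormatError,
    UnsupportedVersionError,
)

FORMAT_VERSION = "1"

#: Grid-spacing tolerance when checking time axes, in seconds.
GRID_TOL_S = 1e-9

# Serialisation precision: 4 decimals on mV bounds round-trip error at 5e-5 mV
# (and gives >= 6 significant digits for any |V| >= 10 mV); 9 decimals on
# seconds keeps grid spacing reconstruction within GRID_TOL_S.
_VOLT_FMT = "%.4f"
_TIME_FMT = "%.9f"


@dataclass(frozen=True)
class StepProtocol:
    """Square-pulse stimulus schedule for a serial current-step protocol.

    The default instance is the 14-step schedule used throughout this
    package: -400 to +900 pA in 100 pA increments, 800 ms step duration,
    three trials per amplitude, sampled at 10 kHz.  Pre/post epoch durations
    are not part of that schedule and default to 100 ms of baseline (enough
    for the 100 ms resting-potential window) and 200 ms of tail.
    """

    amplitudes_pA: tuple[float, ...] = tuple(range(-400, 901, 100))
    pre_step_s: float = 0.1
    step_dur_s: float = 0.8
    post_step_s: float = 0.2
    n_trials: int = 3
    sampling_rate_hz: float = 10_000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes_pA", tuple(float(a) for a in self.amplitudes_pA))
        if not self.amplitudes_pA:
            raise ValueError("protocol needs at least one amplitude")
        diffs = np.diff(self.amplitudes_pA)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("amplitudes_pA must be strictly increasing")
        for name in ("pre_step_s", "step_dur_s", "post_step_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sampling_rate_hz < 5000:
            raise ValueError("sampling_rate_hz must be >= 5000")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def total_s(self) -> float:
        return self.pre_step_s + self.step_dur_s + self.post_step_s

    @property
    def n_samples(self) -> int:
        """Samples per sweep, inclusive of both endpoints of the time grid."""
        return int(round(self.total_s * self.sampling_rate_hz)) + 1

    @property
    def onset_index(self) -> int:
        """Index of the first sample at/after step onset."""
        return int(round(self.pre_step_s * self.sampling_rate_hz))

    @property
    def offset_index(self) -> int:
        """Index of the first sample at/after step offset."""
        return int(round((self.pre_step_s + self.step_dur_s) * self.sampling_rate_hz))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_s

    def to_dict(self) -> dict:
        return {
            "amplitudes_pA": list(self.amplitudes_pA),
            "pre_step_s": self.pre_step_s,
            "step_dur_s": self.step_dur_s,
            "post_step_s": self.post_step_s,
            "n_trials": self.n_trials,
            "sampling_rate_hz": self.sampling_rate_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StepProtocol":
        return cls(
            amplitudes_pA=tuple(d["amplitudes_pA"]),
            pre_step_s=d["pre_step_s"],
            step_dur_s=d["step_dur_s"],
            post_step_s=d["post_step_s"],
            n_trials=int(d["n_trials"]),
            sampling_rate_hz=d["sampling_rate_hz"],
        )


@dataclass
class Sweep:
    """One voltage trace: a single trial at a single command amplitude."""

    trial: int
    amplitude_pA: float
    time_s: np.ndarray
    voltage_mV: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)


@dataclass
class CellRecording:
    """One cell's complete sweep set plus recording metadata.

    ``rs_start_MOhm``/``rs_end_MOhm`` hold the pipette series resistance
    monitored at the beginning and end of the trial block; they may be absent
    for simulated cells, in which case the series-resistance QC rule reports
    "not assessed" rather than pass/fail.
    """

    cell_id: str
    group_label: str
    protocol: StepProtocol
    sweeps: list[Sweep] = field(default_factory=list)
    rs_start_MOhm: float | None = None
    rs_end_MOhm: float | None = None
    notes: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        if "," in self.cell_id or "\n" in self.cell_id:
            raise ValueError("cell_id must not contain commas or newlines")
        self._sort()

    def _sort(self) -> None:
        self.sweeps.sort(key=lambda s: (s.amplitude_pA, s.trial))

    def __iter__(self) -> Iterator[Sweep]:
        """Iterate sweeps in (ascending amplitude, ascending trial) order."""
        return iter(self.sweeps)

    def amplitudes(self) -> list[float]:
        return sorted({s.amplitude_pA for s in self.sweeps})

    def sweeps_at(self, amplitude_pA: float) -> list[Sweep]:
        out = [s for s in self.sweeps if s.amplitude_pA == float(amplitude_pA)]
        return sorted(out, key=lambda s: s.trial)

    def mean_voltage(self, amplitude_pA: float) -> np.ndarray:
        """Pointwise trial average of the raw traces at one amplitude."""
        sw = self.sweeps_at(amplitude_pA)
        if not sw:
            raise KeyError(f"no sweeps at {amplitude_pA} pA for cell {self.cell_id}")
        return np.mean([s.voltage_mV for s in sw], axis=0)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_recording`."""

    field: str
    cell_id: str
    sweep: tuple[float, int] | None
    message: str


def validate_recording(rec: CellRecording) -> list[Violation]:
    """Check a recording against the data-model invariants.

    Returns an empty list iff everything holds.  Never raises: a recording
    that is structurally broken simply yields violations naming the offending
    field and sweep.
    """
    out: list[Violation] = []
    proto = rec.protocol

    for name, val in (("rs_start_MOhm", rec.rs_start_MOhm), ("rs_end_MOhm", rec.rs_end_MOhm)):
        if val is not None and val <= 0:
            out.append(Violation(name, rec.cell_id, None, f"{name} must be > 0, got {val}"))

    expected = {(a, t) for a in proto.amplitudes_pA for t in range(1, proto.n_trials + 1)}
    present = {(s.amplitude_pA, s.trial) for s in rec.sweeps}
    if len(present) != len(rec.sweeps):
        out.append(Violation("sweeps", rec.cell_id, None, "duplicate (amplitude, trial) sweeps"))
    if present != expected and not rec.partial:
        missing = sorted(expected - present)
        extra = sorted(present - expected)
        msg = "partial sweep set"
        if missing:
            msg += f"; missing {missing[:5]}{'...' if len(missing) > 5 else ''}"
        if extra:
            msg += f"; unexpected {extra[:5]}{'...' if len(extra) > 5 else ''}"
        out.append(Violation("sweeps", rec.cell_id, None, msg))

    dt = proto.dt_s
    for s in rec.sweeps:
        key = (s.amplitude_pA, s.trial)
        if s.trial < 1:
            out.append(Violation("trial", rec.cell_id, key, "trial index must be >= 1"))
        if s.time_s.shape != s.voltage_mV.shape:
            out.append(
                Violation("voltage_mV", rec.cell_id, key,
                          f"time ({s.time_s.size}) and voltage ({s.voltage_mV.size}) lengths differ")
            )
            continue
        if s.time_s.size != proto.n_samples:
            out.append(
                Violation("time_s", rec.cell_id, key,
                          f"sweep has {s.time_s.size} samples, protocol epochs need {proto.n_samples}")
            )
        if s.time_s.size >= 2:
            spacing = np.diff(s.time_s)
            if np.any(np.abs(spacing - dt) > GRID_TOL_S):
                out.append(
                    Violation("time_s", rec.cell_id, key,
                              "grid spacing deviates from 1/sampling_rate_hz by more than 1e-9 s")
                )
        if not np.all(np.isfinite(s.voltage_mV)):
            out.append(Violation("voltage_mV", rec.cell_id, key, "non-finite voltage samples"))
    return out


def write_sweep_bundle(recordings: Sequence[CellRecording], path: str | Path) -> Path:
    """Write recordings as a manifest + long-CSV sweep bundle.

    Voltages are serialised with 0.1 uV resolution so a write/read round trip
    reproduces every sample to better than 1e-4 mV.  All recordings must share
    one protocol (the bundle stores a single schedule).
    """
    path = Path(path)
    recordings = list(recordings)
    if recordings:
        proto = recordings[0].protocol
        for r in recordings[1:]:
            if r.protocol != proto:
                raise ValueError("all recordings in a bundle must share one protocol")
    else:
        proto = StepProtocol()

    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "protocol": proto.to_dict(),
        "cells": [
            {
                "cell_id": r.cell_id,
                "group_label": r.group_label,
                "rs_start_MOhm": r.rs_start_MOhm,
                "rs_end_MOhm": r.rs_end_MOhm,
                "notes": r.notes,
                "partial": r.partial,
            }
            for r in recordings
        ],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    with open(path / "sweeps.csv", "w") as fh:
        fh.write("cell_id,trial,amplitude_pA,time_s,voltage_mV\n")
        for r in recordings:
            for s in r:  # (amplitude, trial) order
                row_fmt = f"{r.cell_id},{s.trial},{s.amplitude_pA:g},{_TIME_FMT},{_VOLT_FMT}"
                np.savetxt(fh, np.column_stack([s.time_s, s.voltage_mV]), fmt=row_fmt)
    return path


def read_sweep_bundle(path: str | Path) -> list[CellRecording]:
    """Read a sweep bundle back into :class:`CellRecording` objects.

    Sample values are returned exactly as written (no resampling or
    smoothing).  Iteration order within each cell is (ascending amplitude,
    ascending trial); cells come back in manifest order.
    """
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise BundleFormatError(f"no manifest.json in {path}")
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as e:
        raise BundleFormatError(f"unparseable manifest.json in {path}: {e}") from e
    version = str(manifest.get("format_version"))
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"bundle format version {version!r} not supported (expected {FORMAT_VERSION!r})"
        )
    if "protocol" not in manifest or "cells" not in manifest:
        raise BundleFormatError("manifest.json missing 'protocol' or 'cells'")
    proto = StepProtocol.from_dict(manifest["protocol"])

    spath = path / "sweeps.csv"
    if not spath.exists():
        raise BundleFormatError(f"no sweeps.csv in {path}")
    table = pd.read_csv(spath, dtype={"cell_id": str})
    required = ["cell_id", "trial", "amplitude_pA", "time_s", "voltage_mV"]
    if list(table.columns) != required:
        raise BundleFormatError(f"sweeps.csv columns {list(table.columns)} != {required}")

    grouped: dict[str, dict[tuple[float, int], pd.DataFrame]] = {}
    if len(table):
        for (cid, amp, trial), block in table.groupby(
            ["cell_id", "amplitude_pA", "trial"], sort=False
        ):
            grouped.setdefault(str(cid), {})[(float(amp), int(trial))] = block

    out: list[CellRecording] = []
    for entry in manifest["cells"]:
        cid = entry["cell_id"]
        blocks = grouped.pop(cid, {})
        sweeps = []
        for (amp, trial), block in sorted(blocks.items()):
            t = block["time_s"].to_numpy()
            v = block["voltage_mV"].to_numpy()
            if np.isnan(v).any() or np.isnan(t).any():
                raise BundleCorruptionError(
                    f"cell {cid}, sweep ({amp:g} pA, trial {trial}): "
                    "missing values in time/voltage columns"
                )
            if len(t) != proto.n_samples:
                raise BundleCorruptionError(
                    f"cell {cid}, sweep ({amp:g} pA, trial {trial}): "
                    f"{len(t)} rows, expected {proto.n_samples}"
                )
            sweeps.append(Sweep(trial=trial, amplitude_pA=amp, time_s=t, voltage_mV=v))
        out.append(
            CellRecording(
                cell_id=cid,
                group_label=entry.get("group_label", ""),
                protocol=proto,
                sweeps=sweeps,
                rs_start_MOhm=entry.get("rs_start_MOhm"),
                rs_end_MOhm=entry.get("rs_end_MOhm"),
                notes=entry.get("notes", ""),
                partial=bool(entry.get("partial", False)),
            )
        )
    if grouped:
        raise BundleCorruptionError(
            f"sweeps.csv contains cells absent from the manifest: {sorted(grouped)}"
        )
    return out
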