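"""Synthetic two-group cohorts of current-clamp recordings with known truth.

The generator stands in for patch-clamp recordings of dentate granule cells:
a single-compartment adaptive exponential integrate-and-fire (AdEx) neuron
augmented with a first-order H-type (sag) conductance, driven through the
serial square-step protocol.  It is the simplest model that produces every
phenomenon the extraction pipeline measures — ohmic input resistance, RC
charging, HCN-style sag and rebound, rheobase, spike-frequency accommodation
and delay-to-first-spike — while keeping closed-form ground truth available
for the passive properties.

Spikes on the output traces are stylised: a one-sample excursion to ``Vcut``
followed by the reset.  That exercises peak detection without pretending to
model Na+ kinetics; action-potential *waveform* metrics are validated against
parametric spike shapes instead (see :mod:`stepclamp.spikes`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from ._integrator import integrate_adex
from .errors import RheobaseUnboundedError, SimulationError, SpecError
from .trace_io import CellRecording, StepProtocol, Sweep

#: Default internal integration step (ms).  Output traces are recorded at the
#: protocol sampling rate; the integrator runs on an integer subdivision of
#: the output grid no coarser than this.
DEFAULT_DT_MS = 0.05

#: Settling time at I = 0 used to find the resting state before the first
#: sweep (long relative to every time constant in the model).
SETTLE_MS = 2000.0


@dataclass(frozen=True)
class NeuronParams:
    """AdEx + H-conductance parameter set (pF, nS, mV, pA, ms units)."""

    C_pF: float = 180.0
    gL_nS: float = 7.47
    EL_mV: float = -79.0
    VT_mV: float = -61.0
    DeltaT_mV: float = 2.0
    Vreset_mV: float = -68.0
    Vcut_mV: float = 0.0
    tref_ms: float = 2.0
    a_nS: float = 0.0
    b_pA: float = 4.0
    tauw_ms: float = 120.0
    gh_nS: float = 0.8
    Eh_mV: float = -30.0
    Vh_mV: float = -110.0
    kh_mV: float = 4.0
    tauh_ms: float = 80.0
    noise_sigma_pA: float = 0.0
    noise_tau_ms: float = 3.0

    def validate(self) -> None:
        if self.C_pF <= 0 or self.gL_nS <= 0:
            raise SpecError("C_pF and gL_nS must be > 0")
        if self.DeltaT_mV < 0:
            raise SpecError("DeltaT_mV must be >= 0")
        if self.tauw_ms <= 0 or self.tauh_ms <= 0 or self.kh_mV <= 0:
            raise SpecError("tauw_ms, tauh_ms and kh_mV must be > 0")
        if not (self.Vreset_mV < self.VT_mV < self.Vcut_mV):
            raise SpecError("need Vreset_mV < VT_mV < Vcut_mV")
        if self.noise_sigma_pA < 0 or self.a_nS < 0 or self.gh_nS < 0 or self.tref_ms < 0:
            raise SpecError("a_nS, gh_nS, tref_ms, noise_sigma_pA must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True properties of one parameter set, for recovery testing.

    ``Rin_MOhm`` and ``tau_ms`` are the passive (leak-only) limits
    ``1000/gL`` and ``C/gL``; an H-conductance perturbs the measured values
    only to the extent it activates in the measurement's voltage range.
    ``rheobase_pA`` is analytic, ``gL (VT - EL - DeltaT)``, when neither
    subthreshold adaptation nor the sag conductance interferes (a = gh = 0);
    otherwise it is found numerically by bisection.
    """

    Rin_MOhm: float
    tau_ms: float
    rheobase_pA: float
    has_sag: bool


def _args(p: NeuronParams) -> tuple:
    return (
        p.C_pF, p.gL_nS, p.EL_mV, p.VT_mV, p.DeltaT_mV, p.Vreset_mV, p.Vcut_mV,
        p.tref_ms, p.a_nS, p.b_pA, p.tauw_ms,
        p.gh_nS, p.Eh_mV, p.Vh_mV, p.kh_mV, p.tauh_ms,
    )


def _hinf(p: NeuronParams, V: float) -> float:
    return 1.0 / (1.0 + math.exp((V - p.Vh_mV) / p.kh_mV))


def _settle(p: NeuronParams, dt_ms: float) -> tuple[float, float, float]:
    """Resting state found by settling at I = 0 (noise off)."""
    n = int(round(SETTLE_MS / dt_ms))
    I = np.zeros(n)
    _, _, V, w, h = integrate_adex(
        I, dt_ms, n, *_args(p),
        p.EL_mV, 0.0, _hinf(p, p.EL_mV), False,
    )
    if not math.isfinite(V):
        raise SimulationError("settling diverged: non-finite resting state")
    return V, w, h


def _ou_noise(n: int, dt_ms: float, sigma: float, tau_ms: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck current noise via its exact AR(1) form."""
    rho = math.exp(-dt_ms / tau_ms)
    z = rng.standard_normal(n) * (sigma * math.sqrt(1.0 - rho * rho))
    x0 = rng.standard_normal() * sigma
    out, _ = signal.lfilter([1.0], [1.0, -rho], z, zi=[rho * x0])
    return out


def simulate_cell(
    params: NeuronParams,
    protocol: StepProtocol | None = None,
    seed: int = 0,
    cell_id: str = "sim",
    group_label: str = "sim",
    dt_ms: float = DEFAULT_DT_MS,
    with_events: bool = False,
):
    """Run the full step protocol on one model neuron.

    Each sweep starts from the settled resting state (the protocol's long
    inter-sweep rest period is idealised as complete recovery).  With noise
    off, trials at one amplitude are identical and the integration is shared.
    Deterministic given ``(params, protocol, seed)``.

    Returns the :class:`CellRecording`; with ``with_events=True``, also a
    dict mapping ``(amplitude_pA, trial)`` to the integrator's own spike
    times (seconds from sweep start) — the event-log oracle for detector
    tests.
    """
    params.validate()
    protocol = protocol or StepProtocol()
    out_dt_ms = 1000.0 / protocol.sampling_rate_hz
    n_sub = max(1, int(math.ceil(out_dt_ms / dt_ms - 1e-12)))
    dt = out_dt_ms / n_sub

    V0, w0, h0 = _settle(params, dt)

    n_out = protocol.n_samples
    n_int = (n_out - 1) * n_sub
    i_on = protocol.onset_index * n_sub
    i_off = protocol.offset_index * n_sub
    t_grid = protocol.times()

    sweeps: list[Sweep] = []
    events: dict[tuple[float, int], np.ndarray] = {}
    noisy = params.noise_sigma_pA > 0

    for ai, amp in enumerate(protocol.amplitudes_pA):
        base_I = np.zeros(n_int)
        base_I[i_on:i_off] = amp
        cached = None
        for trial in range(1, protocol.n_trials + 1):
            if cached is None or noisy:
                I = base_I
                if noisy:
                    rng = np.random.default_rng(
                        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, ai, trial])
                    )
                    I = base_I + _ou_noise(n_int, dt, params.noise_sigma_pA,
                                           params.noise_tau_ms, rng)
                V_out, sp_ms, V_end, _, _ = integrate_adex(
                    I, dt, n_sub, *_args(params), V0, w0, h0, True,
                )
                if not math.isfinite(V_end) or not np.all(np.isfinite(V_out)):
                    raise SimulationError(
                        f"integration diverged on sweep ({amp:g} pA, trial {trial}) "
                        f"of cell {cell_id}"
                    )
                cached = (V_out, sp_ms)
            V_out, sp_ms = cached
            sweeps.append(Sweep(trial=trial, amplitude_pA=amp,
                                time_s=t_grid, voltage_mV=V_out.copy()))
            events[(amp, trial)] = sp_ms / 1000.0

    rec = CellRecording(cell_id=cell_id, group_label=group_label,
                        protocol=protocol, sweeps=sweeps)
    return (rec, events) if with_events else rec


def numeric_rheobase(
    params: NeuronParams,
    step_dur_s: float = 0.8,
    tol_pA: float = 0.5,
    upper_pA: float = 2000.0,
    dt_ms: float = DEFAULT_DT_MS,
) -> float:
    """Minimum constant current eliciting >= 1 spike within the step, by bisection.

    Noise is switched off.  Returns the midpoint of the final bracket of
    width <= ``tol_pA``.  Raises :class:`RheobaseUnboundedError` when even
    ``upper_pA`` fails to elicit a spike.
    """
    if tol_pA <= 0:
        raise ValueError("tol_pA must be > 0")
    p = replace(params, noise_sigma_pA=0.0)
    p.validate()
    V0, w0, h0 = _settle(p, dt_ms)
    n = int(round(step_dur_s * 1000.0 / dt_ms))

    def fires(amp: float) -> bool:
        I = np.full(n, amp)
        _, sp, V_end, _, _ = integrate_adex(I, dt_ms, n, *_args(p), V0, w0, h0, False)
        if not math.isfinite(V_end):
            raise SimulationError(f"integration diverged at {amp:g} pA")
        return len(sp) > 0

    lo, hi = 0.0, float(upper_pA)
    if fires(lo):
        return 0.0
    if not fires(hi):
        raise RheobaseUnboundedError(
            f"no spike within {step_dur_s} s even at {upper_pA:g} pA"
        )
    while hi - lo > tol_pA:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def analytic_ground_truth(params: NeuronParams, step_dur_s: float = 0.8) -> GroundTruth:
    """Closed-form passive truth plus analytic or numeric rheobase."""
    rin = 1000.0 / params.gL_nS
    tau = params.C_pF / params.gL_nS
    if params.a_nS == 0 and params.gh_nS == 0:
        rheo = params.gL_nS * (params.VT_mV - params.EL_mV - params.DeltaT_mV)
    else:
        rheo = numeric_rheobase(params, step_dur_s=step_dur_s)
    return GroundTruth(Rin_MOhm=rin, tau_ms=tau, rheobase_pA=rheo,
                       has_sag=params.gh_nS > 0)


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class ParamDist:
    """Truncated normal over one neuron parameter; sd = 0 means a constant."""

    mean: float
    sd: float = 0.0
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise SpecError("sd must be >= 0")
        if not self.low < self.high:
            raise SpecError(f"empty truncation interval [{self.low}, {self.high}]")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            if not (self.low <= self.mean <= self.high):
                raise SpecError("constant value outside its truncation interval")
            return self.mean
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return float(stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                         random_state=rng))


@dataclass
class CohortSpec:
    """Two (or more) group regimes over NeuronParams, plus protocol and seed.

    Each group maps parameter names to :class:`ParamDist`; parameters not
    listed stay at ``base``.  Sampling is fully deterministic given ``seed``.
    """

    groups: dict[str, dict[str, ParamDist]]
    n_cells: int = 20
    seed: int = 0
    protocol: StepProtocol = field(default_factory=StepProtocol)
    base: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise SpecError("n_cells must be >= 1")
        if not self.groups:
            raise SpecError("at least one group regime is required")
        valid = {f.name for f in fields(NeuronParams)}
        for label, regime in self.groups.items():
            unknown = set(regime) - valid
            if unknown:
                raise SpecError(f"group {label!r}: unknown parameters {sorted(unknown)}")


#: Group regimes emulating the study conditions: a wild-type-like group
#: centred at an input resistance of ~134 MOhm, and a transgenic-like group
#: centred at ~168 MOhm with a depolarised resting level, a weaker sag
#: conductance (smaller normalised sag) and a stronger spike-triggered
#: adaptation increment (greater accommodation).  Calibrated to the reported
#: group medians and effect directions only — no claim of biophysical fit.
WT_LIKE: dict[str, ParamDist] = {
    "gL_nS": ParamDist(7.47, 0.70, 5.0, 10.5),
    "EL_mV": ParamDist(-79.0, 2.0, -85.0, -73.0),
    "VT_mV": ParamDist(-61.0, 1.5, -66.0, -56.0),
    "C_pF": ParamDist(180.0, 15.0, 140.0, 220.0),
    "b_pA": ParamDist(4.0, 1.0, 1.5, 8.0),
    "gh_nS": ParamDist(0.80, 0.15, 0.30, 1.40),
}

TG_LIKE: dict[str, ParamDist] = {
    "gL_nS": ParamDist(5.95, 0.60, 4.0, 8.5),
    "EL_mV": ParamDist(-76.5, 2.0, -83.0, -70.5),
    "VT_mV": ParamDist(-61.0, 1.5, -66.0, -56.0),
    "C_pF": ParamDist(180.0, 15.0, 140.0, 220.0),
    "b_pA": ParamDist(18.0, 3.0, 10.0, 28.0),
    "gh_nS": ParamDist(0.40, 0.10, 0.10, 0.80),
}


def default_cohort_spec(n_cells: int = 20, seed: int = 0,
                        protocol: StepProtocol | None = None) -> CohortSpec:
    return CohortSpec(
        groups={"Wt-like": dict(WT_LIKE), "Tg-like": dict(TG_LIKE)},
        n_cells=n_cells,
        seed=seed,
        protocol=protocol or StepProtocol(),
    )


def sample_params(spec: CohortSpec, group_label: str, cell_index: int) -> NeuronParams:
    """Draw one cell's parameter set; deterministic in (seed, group, index)."""
    g_idx = list(spec.groups).index(group_label)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, g_idx, cell_index])
    )
    draws = {name: dist.sample(rng) for name, dist in spec.groups[group_label].items()}
    p = replace(spec.base, **draws)
    try:
        p.validate()
    except SpecError as e:
        raise SpecError(
            f"group {group_label!r}, cell {cell_index}: sampled parameters invalid ({e})"
        ) from e
    return p


def generate_cohort(
    spec: CohortSpec,
    with_rheobase: bool = True,
) -> tuple[list[CellRecording], pd.DataFrame]:
    """Simulate ``n_cells`` per group and tabulate per-cell ground truth.

    Returns the recordings (group by group, ascending cell index) and a
    DataFrame with one row per cell: all sampled parameters plus
    ``Rin_MOhm``, ``tau_ms`` and ``rheobase_pA`` (numeric when the model has
    a sag or subthreshold-adaptation conductance).  ``with_rheobase=False``
    skips the bisection when true rheobase is not needed.
    """
    recs: list[CellRecording] = []
    rows: list[dict] = []
    for g_idx, label in enumerate(spec.groups):
        for i in range(spec.n_cells):
            p = sample_params(spec, label, i)
            sim_seed = int(
                np.random.SeedSequence(
                    [int(spec.seed) & 0x7FFFFFFF, g_idx, i, 7]
                ).generate_state(1)[0] & 0x7FFFFFFF
            )
            cid = f"{label}-{i:03d}"
            rec = simulate_cell(p, spec.protocol, seed=sim_seed,
                                cell_id=cid, group_label=label)
            recs.append(rec)
            row = {"cell_id": cid, "group_label": label}
            row.update({f.name: getattr(p, f.name) for f in fields(NeuronParams)})
            row["Rin_MOhm"] = 1000.0 / p.gL_nS
            row["tau_ms"] = p.C_pF / p.gL_nS
            if with_rheobase:
                gt = analytic_ground_truth(p, step_dur_s=spec.protocol.step_dur_s)
                row["rheobase_pA"] = gt.rheobase_pA
            rows.append(row)
    return recs, pd.DataFrame(rows)
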