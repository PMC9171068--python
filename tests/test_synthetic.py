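"""Simulator physics: closed-form passive behaviour, rheobase, sag, determinism."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from stepclamp.errors import RheobaseUnboundedError, SpecError
from stepclamp.passive import measure_sag
from stepclamp.synthetic import (
    CohortSpec,
    NeuronParams,
    ParamDist,
    analytic_ground_truth,
    default_cohort_spec,
    generate_cohort,
    numeric_rheobase,
    simulate_cell,
)
from stepclamp.trace_io import StepProtocol, write_sweep_bundle


def passive_params(**kw) -> NeuronParams:
    """Leak-only cell: spike initiation pushed far above the operating range."""
    base = dict(C_pF=200.0, gL_nS=10.0, EL_mV=-80.0, VT_mV=100.0, DeltaT_mV=2.0,
                Vreset_mV=-65.0, Vcut_mV=120.0, a_nS=0.0, b_pA=0.0, gh_nS=0.0,
                noise_sigma_pA=0.0)
    base.update(kw)
    return NeuronParams(**base)


class TestPassivePhysics:
    def test_ohmic_steady_state(self):
        """-100 pA into gL = 10 nS settles at EL - 10 mV."""
        proto = StepProtocol(amplitudes_pA=(-100.0,), n_trials=1)
        rec = simulate_cell(passive_params(), proto, seed=0)
        v = rec.sweeps[0].voltage_mV
        ss = v[proto.offset_index - 1600:proto.offset_index].mean()
        assert ss == pytest.approx(-90.0, abs=0.05)

    def test_rc_charging_time(self):
        """Time to 67% of the steady deflection is 1.109 tau = 22.2 ms."""
        proto = StepProtocol(amplitudes_pA=(-100.0,), n_trials=1)
        rec = simulate_cell(passive_params(), proto, seed=0)
        v = rec.sweeps[0].voltage_mV
        on, off = proto.onset_index, proto.offset_index
        base = v[:on].mean()
        ss = v[off - 1600:off].mean()
        target = base + 0.67 * (ss - base)
        t67_ms = np.argmax(v[on:] <= target) * 0.1
        assert t67_ms == pytest.approx(22.2, abs=0.3)

    def test_convergence_under_dt_halving(self):
        """Halving dt moves no subthreshold sample by 0.1 mV; spike count is
        unchanged, the first spike moves < 0.2 ms, and no interspike interval
        changes by 0.2 ms (late absolute spike times accumulate the per-spike
        reset quantization and are not compared directly)."""
        p = NeuronParams()
        proto = StepProtocol(amplitudes_pA=(-400.0, 300.0), n_trials=1)
        r1, e1 = simulate_cell(p, proto, seed=0, dt_ms=0.05, with_events=True)
        r2, e2 = simulate_cell(p, proto, seed=0, dt_ms=0.025, with_events=True)
        dv = np.abs(r1.sweeps_at(-400.0)[0].voltage_mV
                    - r2.sweeps_at(-400.0)[0].voltage_mV)
        assert dv.max() < 0.1
        t1, t2 = e1[(300.0, 1)], e2[(300.0, 1)]
        assert len(t1) == len(t2)
        assert abs(t1[0] - t2[0]) < 0.2e-3
        assert np.max(np.abs(np.diff(t1) - np.diff(t2))) < 0.2e-3


class TestRheobase:
    EIF = dict(C_pF=200.0, gL_nS=10.0, EL_mV=-80.0, VT_mV=-50.0, DeltaT_mV=2.0,
               Vreset_mV=-65.0, Vcut_mV=0.0, a_nS=0.0, b_pA=0.0, gh_nS=0.0)

    def test_analytic_truth_values(self):
        gt = analytic_ground_truth(NeuronParams(**self.EIF))
        assert gt.rheobase_pA == pytest.approx(280.0)
        assert gt.tau_ms == pytest.approx(20.0)
        gt2 = analytic_ground_truth(replace(NeuronParams(**self.EIF), gL_nS=7.474))
        assert gt2.Rin_MOhm == pytest.approx(133.8, abs=0.05)

    def test_protocol_brackets_analytic_rheobase(self):
        """280 pA rheobase: no spike in 800 ms at +200, >= 1 spike at +300."""
        proto = StepProtocol(amplitudes_pA=(200.0, 300.0), n_trials=1)
        _, ev = simulate_cell(NeuronParams(**self.EIF), proto, seed=0,
                              with_events=True)
        assert len(ev[(200.0, 1)]) == 0
        assert len(ev[(300.0, 1)]) >= 1

    def test_numeric_matches_analytic(self):
        num = numeric_rheobase(NeuronParams(**self.EIF), tol_pA=0.5)
        assert abs(num - 280.0) <= 5.0

    def test_subthreshold_adaptation_raises_rheobase(self):
        base = NeuronParams(**self.EIF)
        with_a = replace(base, a_nS=2.0)
        assert numeric_rheobase(with_a) > numeric_rheobase(base) + 10

    def test_sag_conductance_case_reproducible_across_tolerances(self):
        p = replace(NeuronParams(**self.EIF), gh_nS=1.0)
        r1 = numeric_rheobase(p, tol_pA=1.0)
        r2 = numeric_rheobase(p, tol_pA=0.1)
        assert math.isfinite(r1) and abs(r1 - r2) <= 1.0

    def test_unbounded_search_raises(self):
        p = passive_params(gL_nS=15.0, VT_mV=100.0, Vcut_mV=120.0)
        with pytest.raises(RheobaseUnboundedError):
            numeric_rheobase(p)


class TestSag:
    def test_no_mechanism_no_sag(self):
        proto = StepProtocol(amplitudes_pA=(-400.0,), n_trials=1)
        rec = simulate_cell(passive_params(), proto, seed=0)
        sag, resp, norm = measure_sag(rec)
        assert norm < 0.02

    def test_sag_monotone_in_gh(self):
        proto = StepProtocol(amplitudes_pA=(-400.0,), n_trials=1)
        sags = []
        for gh in (0.0, 0.5, 1.0, 2.0):
            p = replace(NeuronParams(), gh_nS=gh, b_pA=0.0)
            rec = simulate_cell(p, proto, seed=0)
            sags.append(measure_sag(rec)[0])
        assert all(b >= a for a, b in zip(sags, sags[1:]))
        assert sags[-1] > sags[0] + 1.0  # strictly grows over the range


class TestCohort:
    def test_same_seed_same_bundle_bytes(self, tmp_path):
        spec = default_cohort_spec(n_cells=1, seed=9)
        out = []
        for tag in ("a", "b"):
            recs, truth = generate_cohort(spec, with_rheobase=False)
            path = write_sweep_bundle(recs, tmp_path / tag)
            out.append(((path / "sweeps.csv").read_bytes(),
                        (path / "manifest.json").read_bytes(), truth))
        assert out[0][0] == out[1][0]
        assert out[0][1] == out[1][1]
        assert out[0][2].equals(out[1][2])

    def test_ground_truth_row_count(self):
        spec = default_cohort_spec(
            n_cells=2, seed=1,
            protocol=StepProtocol(amplitudes_pA=(-100.0,), n_trials=1))
        recs, truth = generate_cohort(spec, with_rheobase=False)
        assert len(recs) == 4 and len(truth) == 4
        assert set(truth["group_label"]) == {"Wt-like", "Tg-like"}

    def test_tg_like_has_higher_input_resistance_truth(self):
        spec = default_cohort_spec(
            n_cells=10, seed=4,
            protocol=StepProtocol(amplitudes_pA=(-100.0,), n_trials=1))
        _, truth = generate_cohort(spec, with_rheobase=False)
        med = truth.groupby("group_label")["Rin_MOhm"].median()
        assert med["Tg-like"] > med["Wt-like"]

    def test_unsatisfiable_truncation_is_spec_error(self):
        with pytest.raises(SpecError):
            ParamDist(1.0, 0.5, low=2.0, high=1.0)
        spec = CohortSpec(groups={"g": {"gL_nS": ParamDist(-5.0)}}, n_cells=1,
                          seed=0)
        with pytest.raises(SpecError):
            generate_cohort(spec, with_rheobase=False)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(SpecError):
            CohortSpec(groups={"g": {"nonsense": ParamDist(1.0)}}, n_cells=1, seed=0)


class TestNoise:
    def test_noise_is_seed_deterministic_and_nonzero(self):
        proto = StepProtocol(amplitudes_pA=(-100.0,), n_trials=2,
                             pre_step_s=0.05, step_dur_s=0.1, post_step_s=0.05)
        p = replace(passive_params(), noise_sigma_pA=20.0)
        r1 = simulate_cell(p, proto, seed=5)
        r2 = simulate_cell(p, proto, seed=5)
        r3 = simulate_cell(p, proto, seed=6)
        v1 = r1.sweeps_at(-100.0)[0].voltage_mV
        assert np.array_equal(v1, r2.sweeps_at(-100.0)[0].voltage_mV)
        assert not np.array_equal(v1, r3.sweeps_at(-100.0)[0].voltage_mV)
        # trials differ from each other under noise
        assert not np.array_equal(v1, r1.sweeps_at(-100.0)[1].voltage_mV)

    def test_invalid_params_rejected(self):
        with pytest.raises(SpecError):
            simulate_cell(replace(NeuronParams(), Vreset_mV=-40.0, VT_mV=-50.0))


class TestParameterRecovery:
    """Extractor-vs-truth closure on the noise-free recovery cohort."""

    def test_input_resistance_within_2_percent(self, recovery_cohort):
        _, truth, feats = recovery_cohort
        merged = feats.merge(truth, on="cell_id")
        rel = np.abs(merged["r_in_MOhm"] - merged["Rin_MOhm"]) / merged["Rin_MOhm"]
        assert (rel < 0.02).all()

    def test_t67_within_5_percent_without_sag(self, recovery_cohort):
        _, truth, feats = recovery_cohort
        merged = feats.merge(truth, on="cell_id")
        gh0 = merged[merged["gh_nS"] == 0.0]
        assert len(gh0) == 10
        rel = np.abs(gh0["tau67_m100"] - 1.109 * gh0["tau_ms"]) / (1.109 * gh0["tau_ms"])
        assert (rel < 0.05).all()

    def test_rheobase_step_matches_numeric_truth(self, recovery_cohort):
        from stepclamp.validation import rheobase_step_consistent

        recs, truth, feats = recovery_cohort
        amps = np.array(recs[0].protocol.amplitudes_pA)
        merged = feats.merge(truth, on="cell_id", suffixes=("", "_true"))
        for _, row in merged.iterrows():
            assert rheobase_step_consistent(
                row["rheobase_step_pA"], row["rheobase_pA_true"], amps
            ), row["cell_id"]
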