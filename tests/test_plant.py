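"""Flowsheet assembly, simulation physics and effluent-limit accounting."""

import numpy as np
import pytest

from sludgeopt.asm2d import IDX
from sludgeopt.influent import InfluentRecord, generate_synthetic_series
from sludgeopt.plant import (
    PlantConfig,
    PlantTrajectory,
    TankSpec,
    build_flowsheet,
    default_tanks,
    effluent_limits_check,
    replace_time,
    simulate,
    steady_state,
)


class TestFlowsheet:
    def test_default_volumes_sum(self):
        cfg = PlantConfig()
        assert cfg.total_volume == pytest.approx(18767.0)
        assert [t.volume for t in cfg.tanks] == [1113, 1825, 5518, 7461, 472, 1433, 945]

    def test_node_balances_close(self, default_model):
        bal = default_model.node_balances(Qin=35000.0)
        assert max(abs(v) for v in bal.values()) < 1e-10

    def test_once_through_chain(self):
        model = build_flowsheet(PlantConfig(Ql=0.0, Qs=0.0, Qw=0.0))
        assert np.allclose(model.flow_mult, 1.0)
        assert max(abs(v) for v in model.node_balances().values()) < 1e-10

    def test_recycle_multipliers(self, default_model):
        cfg = default_model.cfg
        # anoxic through deox tanks carry influent + RAS + internal recycle
        expected = [1 + cfg.Qs] * 2 + [1 + cfg.Qs + cfg.Ql] * 3 + [1 + cfg.Qs] * 2
        np.testing.assert_allclose(default_model.flow_mult, expected)

    def test_bad_draw_point_rejected(self):
        with pytest.raises(ValueError, match="draw"):
            PlantConfig(recycle_from="T9")

    def test_backwards_recycle_rejected(self):
        with pytest.raises(ValueError, match="upstream"):
            PlantConfig(recycle_from="T2", recycle_to="T4")

    def test_aeration_role_enforced(self):
        with pytest.raises(ValueError, match="aerated"):
            TankSpec("T1", "anaerobic", 1000.0, kla=50.0)

    def test_config_serialization_round_trip(self):
        cfg = PlantConfig(Ql=2.5, Qw=0.02)
        back = PlantConfig.from_dict(cfg.to_dict())
        assert back.Ql == 2.5 and back.Qw == 0.02
        assert [t.volume for t in back.tanks] == [t.volume for t in cfg.tanks]
        assert back.settler.area == cfg.settler.area

    def test_config_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PlantConfig.from_dict({"Qz": 1.0})


class TestSimulation:
    def test_states_remain_nonnegative(self, default_model):
        recs = generate_synthetic_series(days=1.0, seed=11)
        traj = simulate(default_model, recs, rtol=1e-5)
        assert np.all(traj.tank_states >= 0.0)
        assert np.all(traj.settler_X >= 0.0)

    def test_kernel_and_reference_rhs_agree(self, default_model, baseline_steady):
        from sludgeopt.plant import _influent_interpolator

        recs = generate_synthetic_series(days=1.0, seed=2)
        interp = _influent_interpolator(default_model, recs)
        y = baseline_steady + 0.5
        fast = default_model.rhs(0.3, y, interp)
        ref = default_model.rhs_reference(0.3, y, interp)
        np.testing.assert_allclose(fast, ref, rtol=1e-12, atol=1e-9)

    def test_tolerance_self_consistency(self, default_model, baseline_steady, constant_record):
        """Halving tolerances moves effluent COD by well under 0.1 %."""
        recs = generate_synthetic_series(days=2.0, seed=4)
        a = simulate(default_model, recs, init=baseline_steady, rtol=1e-5, atol=1e-7)
        b = simulate(default_model, recs, init=baseline_steady, rtol=5e-7, atol=5e-9)
        rel = abs(a.effluent["COD"][-1] - b.effluent["COD"][-1]) / b.effluent["COD"][-1]
        assert rel < 1e-3

    def test_decay_only_dynamics_without_substrate(self, default_model, baseline_steady):
        blank = InfluentRecord(time=0.0, flow=35000.0, COD=0.0, TN=0.0, TP=0.0, NH4N=0.0, SS=0.0)
        traj = simulate(default_model, [blank, replace_time(blank, 5.0)], init=baseline_steady, rtol=1e-5)
        xh = traj.tank_states[:, 3, IDX["XH"]]
        assert xh[-1] < xh[0]
        assert np.all(np.diff(xh) < 1e-6)


class TestSteadyState:
    def test_fixed_point_has_small_drift(self, default_model, baseline_steady, constant_record):
        recs = [replace_time(constant_record, 0.0), replace_time(constant_record, 10.0)]
        traj = simulate(default_model, recs, init=baseline_steady, rtol=1e-7, atol=1e-9)
        start = traj.tank_states[0]
        end = traj.tank_states[-1]
        denom = np.maximum(np.abs(start), 1.0)
        assert np.max(np.abs(end - start) / denom) < 1e-3

    def test_tracer_passes_through(self, default_model, baseline_steady, constant_record, params):
        """At steady state the non-reactive SI leaves at its influent level."""
        from sludgeopt.influent import fractionate

        si_in = fractionate(constant_record, default_model.scheme, params).SI
        eff = default_model.effluent_state(baseline_steady)
        assert eff[IDX["SI"]] == pytest.approx(si_in, rel=1e-3)

    def test_matches_long_horizon_integration(self, default_model, baseline_steady, constant_record):
        recs = [replace_time(constant_record, 0.0), replace_time(constant_record, 400.0)]
        traj = simulate(default_model, recs, init=baseline_steady, rtol=1e-7, atol=1e-9, n_out=3)
        end = traj.tank_states[-1].ravel()
        ref = default_model.unpack(baseline_steady)[0].ravel()
        denom = np.maximum(np.abs(ref), 1.0)
        assert np.max(np.abs(end - ref) / denom) < 1e-3


class TestDilutionInvariance:
    def test_scaling_volumes_and_flows_preserves_concentrations(self, constant_record):
        """Doubling every volume, area and flow leaves steady concentrations
        unchanged (dilution-rate invariance)."""
        base = build_flowsheet(PlantConfig())
        y1 = steady_state(base, constant_record)

        cfg = PlantConfig()
        scaled_tanks = [TankSpec(t.name, t.role, t.volume * 2.0, t.kla) for t in cfg.tanks]
        cfg2 = PlantConfig(tanks=scaled_tanks)
        cfg2.settler.area *= 2.0
        model2 = build_flowsheet(cfg2)
        rec2 = InfluentRecord(
            time=0.0, flow=constant_record.flow * 2.0, COD=constant_record.COD,
            TN=constant_record.TN, TP=constant_record.TP, NH4N=constant_record.NH4N,
            SS=constant_record.SS,
        )
        y2 = steady_state(model2, rec2)
        t1, _ = base.unpack(y1)
        t2, _ = model2.unpack(y2)
        denom = np.maximum(np.abs(t1), 0.5)
        assert np.max(np.abs(t1 - t2) / denom) < 1e-3


class TestEffluentLimits:
    def _traj(self, series):
        nt = len(series["COD"])
        return PlantTrajectory(
            t=np.linspace(0, 1, nt),
            tank_states=np.zeros((nt, 7, 19)),
            settler_X=np.zeros((nt, 10)),
            settler_solubles=np.zeros((nt, 10, 9)),
            effluent=series,
            effluent_states=np.zeros((nt, 19)),
        )

    def test_clean_effluent_feasible(self):
        z = np.zeros(5)
        traj = self._traj({"COD": z, "TN": z, "NH4N": z, "TP": z})
        out = effluent_limits_check(traj)
        assert out["feasible"] and all(v == 0.0 for v in out["violations"].values())

    def test_constant_violation_fraction_one(self):
        z = np.zeros(5)
        traj = self._traj({"COD": np.full(5, 60.0), "TN": z, "NH4N": z, "TP": z})
        out = effluent_limits_check(traj, {"COD": 50.0})
        assert out["violations"]["COD"] == 1.0 and not out["feasible"]

    def test_fraction_matches_counting_oracle(self, rng):
        cod = rng.uniform(30.0, 70.0, size=40)
        z = np.zeros(40)
        traj = self._traj({"COD": cod, "TN": z, "NH4N": z, "TP": z})
        out = effluent_limits_check(traj, {"COD": 50.0})
        brute = sum(1 for v in cod if v > 50.0) / 40.0
        assert out["violations"]["COD"] == pytest.approx(brute)
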