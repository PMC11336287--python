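"""ASM2d core: stoichiometric continuity, rate kinetics, composites."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sludgeopt.asm2d import (
    COMPONENTS,
    IDX,
    Asm2dParams,
    Asm2dState,
    composite_variables,
    continuity_residuals,
    process_rates,
    reactor_derivatives,
    stoichiometric_matrix,
)


class TestStoichiometry:
    def test_continuity_closes(self, stoich, params):
        res = continuity_residuals(stoich, params)
        for name, vec in res.items():
            assert np.abs(vec).max() < 1e-8, f"{name} balance violated"

    def test_known_coefficients(self, stoich):
        M, i = stoich.matrix, IDX
        Y_H, Y_A = 0.625, 0.24
        assert M[3, i["SO2"]] == pytest.approx(-(1 - Y_H) / Y_H)
        assert M[5, i["SNO3"]] == pytest.approx(-(1 - Y_H) / Y_H / (40.0 / 14.0))
        assert M[5, i["SN2"]] == pytest.approx(-M[5, i["SNO3"]])
        assert M[17, i["SO2"]] == pytest.approx(1.0 - 64.0 / (14.0 * Y_A))
        assert M[15, i["SPO4"]] == pytest.approx(1.0)  # poly-P lysis releases P

    def test_si_is_nonreactive(self, stoich, params):
        # with the default zero inert production fraction, SI is a tracer
        assert params.f_SI == 0.0
        assert np.all(stoich.matrix[:, IDX["SI"]] == 0.0)


class TestProcessRates:
    def test_zero_state_gives_zero_rates(self, params):
        assert np.allclose(process_rates(np.zeros(19), params), 0.0)

    def test_no_electron_acceptor_stops_growth(self, params):
        st = Asm2dState(SF=100, SA=100, SNH4=20, SPO4=5, SALK=5, XH=1000, XAUT=100, XPAO=100, XPHA=50)
        r = process_rates(st, params)
        # aerobic growth (4,5,13,18) and anoxic growth (6,7,14) all need SO2 or SNO3
        for k in (3, 4, 5, 6, 12, 13, 17):
            assert r[k] == 0.0
        assert r[7] > 0.0  # fermentation proceeds anaerobically

    def test_saturated_growth_matches_scalar_monod_oracle(self, params):
        st = Asm2dState(SF=4000, SO2=200, SNH4=50, SPO4=50, SALK=50, XH=100)
        r = process_rates(st, params)
        k = lambda n: params.kinetic[n].value  # noqa: E731
        oracle = (
            k("mu_H")
            * (200 / (k("K_O2_H") + 200))
            * (4000 / (k("K_F") + 4000))
            * 1.0  # SF/(SF+SA) with SA=0
            * (50 / (k("K_NH4_H") + 50))
            * (50 / (k("K_P_H") + 50))
            * (50 / (k("K_ALK_H") + 50))
            * 100
        )
        assert r[3] == pytest.approx(oracle, rel=1e-12)
        assert r[3] == pytest.approx(k("mu_H") * 100, rel=0.06)  # ~ mu_H * XH

    def test_rates_finite_nonnegative_and_monod_monotone(self, params, rng):
        base = rng.uniform(0.0, 50.0, size=19)
        base[IDX["XH"]] = 800.0
        r0 = process_rates(base, params)
        assert np.all(np.isfinite(r0)) and np.all(r0 >= 0.0)
        # raising a substrate never lowers any rate consuming it
        for comp, procs in [("SF", [3, 5]), ("SA", [4, 6, 9]), ("SNH4", [17]), ("SO2", [0, 3, 4])]:
            up = base.copy()
            up[IDX[comp]] *= 1.5
            r1 = process_rates(up, params)
            assert np.all(r1[procs] >= r0[procs] - 1e-12)

    def test_negative_concentration_rejected(self, params):
        bad = np.zeros(19)
        bad[0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            process_rates(bad, params)

    def test_missing_parameter_named(self, params):
        incomplete = dict(params.kinetic)
        incomplete.pop("mu_H")
        with pytest.raises(KeyError):
            process_rates(np.zeros(19), params, kvals={k: v.value for k, v in incomplete.items()})


class TestReactorDerivatives:
    def test_equilibrium_inflow_zero_reaction(self, params):
        st = np.zeros(19)
        st[IDX["SI"]] = 30.0
        d = reactor_derivatives(st, st, Q_in=1000.0, V=500.0, KLa=0.0, params=params)
        assert np.allclose(d, 0.0)

    def test_aeration_term_hand_value(self, params):
        st = np.zeros(19)
        st[IDX["SO2"]] = 4.0
        d = reactor_derivatives(st, st, Q_in=0.0, V=100.0, KLa=100.0, SO_sat=8.0, params=params)
        assert d[IDX["SO2"]] == pytest.approx(400.0)

    def test_invalid_volume(self, params):
        with pytest.raises(ValueError):
            reactor_derivatives(np.zeros(19), np.zeros(19), Q_in=1.0, V=0.0, params=params)

    def test_closed_batch_conserves_cod_oxygen_equivalents(self, params, stoich):
        """A sealed, unaerated batch conserves total COD counting the
        electron-acceptor oxygen equivalents."""
        comp = params.composition()
        i_cod = comp["COD"]
        y0 = np.zeros(19)
        y0[IDX["SF"]] = 150.0
        y0[IDX["SA"]] = 50.0
        y0[IDX["SO2"]] = 6.0
        y0[IDX["SNO3"]] = 15.0
        y0[IDX["SNH4"]] = 20.0
        y0[IDX["SPO4"]] = 8.0
        y0[IDX["SALK"]] = 5.0
        y0[IDX["XS"]] = 100.0
        y0[IDX["XH"]] = 600.0
        y0[IDX["XAUT"]] = 40.0

        def rhs(t, y):
            r = process_rates(np.maximum(y, 0.0), params)
            return r @ stoich.matrix

        sol = solve_ivp(rhs, (0.0, 2.0), y0, method="BDF", rtol=1e-9, atol=1e-11)
        assert sol.success
        total0 = y0 @ i_cod
        total1 = sol.y[:, -1] @ i_cod
        assert total1 == pytest.approx(total0, rel=1e-6)


class TestCompositeVariables:
    def test_zero_state(self, params):
        cv = composite_variables(np.zeros(19), params)
        assert all(v == 0.0 for v in cv.values())

    def test_pure_ammonia(self, params):
        st = Asm2dState(SNH4=10.0)
        cv = composite_variables(st, params)
        assert cv["NH4N"] == 10.0 and cv["TN"] == 10.0 and cv["COD"] == 0.0

    def test_mixed_state_hand_sum(self, params):
        st = Asm2dState(SF=50.0, XS=100.0, SNH4=5.0)
        cv = composite_variables(st, params)
        expected_tn = 5.0 + params.i_N_XS * 100.0 + params.i_N_SF * 50.0
        assert cv["TN"] == pytest.approx(expected_tn)
        assert cv["COD"] == pytest.approx(150.0)


class TestParams:
    def test_exactly_42_kinetic_entries(self, params):
        assert len(params.kinetic) == 42

    def test_ranges_bracket_defaults(self, params):
        for name, par in params.kinetic.items():
            assert par.low <= par.value <= par.high, name

    def test_serialization_round_trip(self, params, tmp_path):
        path = tmp_path / "asm2d_params.tsv"
        modified = params.with_values(mu_H=4.2, K_NH4_AUT=0.7)
        modified.to_file(path)
        back = Asm2dParams.from_file(path)
        assert back.kinetic["mu_H"].value == 4.2
        assert back.kinetic["K_NH4_AUT"].value == 0.7
        assert back.kinetic["b_H"].value == params.kinetic["b_H"].value

    def test_temperature_correction_reference_point(self, params):
        assert params.k("mu_H", 20.0) == pytest.approx(6.0)
        assert params.k("mu_H", 10.0) == pytest.approx(3.0, rel=1e-9)
        assert params.k("K_F", 10.0) == params.k("K_F", 20.0)  # saturation constants fixed


class TestState:
    def test_component_count_and_flags(self):
        st = Asm2dState()
        assert len(st.values) == 19 == len(COMPONENTS)
        assert len(st.soluble_index) == 9

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="SNH4"):
            Asm2dState(SNH4=-1.0)

    def test_unknown_component_rejected(self):
        with pytest.raises(KeyError):
            Asm2dState(SBOGUS=1.0)
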