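import numpy as np
import pytest

from leafosc.biochem import Limitation, MeteoInputs, assimilation, kinetics_at
from leafosc.marginal_cost import CITRUS_LAMBDA_CO, GasExchangeRecord, lambda_point
from leafosc.oscm import (
    Form,
    LambdaSchedule,
    NoRoot,
    as_form,
    ci_compensation,
    forward,
    lambda_of_ci,
    simulate_dataset,
    solve_ci,
)


@pytest.fixture
def kin(moderate_meteo, params):
    return kinetics_at(moderate_meteo, params)


class TestLambdaOfCi:
    def test_diverges_near_ca(self, moderate_meteo, kin):
        lam = lambda_of_ci(moderate_meteo.ca - 0.01, moderate_meteo, kin, Limitation.VC)
        assert lam > 1e6

    def test_low_ci_limit(self, moderate_meteo, kin):
        comp = ci_compensation(Limitation.VC, kin)
        limit = 1.6 * moderate_meteo.D / (moderate_meteo.P * (moderate_meteo.ca - comp)) * 1e6
        lam = lambda_of_ci(comp * (1 + 1e-9), moderate_meteo, kin, Limitation.VC)
        assert lam == pytest.approx(limit, rel=1e-4)

    @pytest.mark.parametrize("branch", [Limitation.VC, Limitation.VJ])
    def test_strictly_increasing(self, moderate_meteo, kin, branch):
        comp = ci_compensation(branch, kin)
        grid = np.linspace(comp + 0.5, moderate_meteo.ca - 0.5, 200)
        lams = [lambda_of_ci(c, moderate_meteo, kin, branch) for c in grid]
        assert np.all(np.diff(lams) > 0)

    def test_domain_errors(self, moderate_meteo, kin):
        comp = ci_compensation(Limitation.VC, kin)
        with pytest.raises(ValueError):
            lambda_of_ci(comp - 1.0, moderate_meteo, kin, Limitation.VC)
        with pytest.raises(ValueError):
            lambda_of_ci(moderate_meteo.ca + 1.0, moderate_meteo, kin, Limitation.VC)


class TestCiCompensation:
    def test_zero_assimilation_at_compensation(self, kin):
        for branch in (Limitation.VC, Limitation.VJ):
            comp = ci_compensation(branch, kin)
            res = assimilation(comp, kin)
            a = res.Ac if branch is Limitation.VC else res.Aj
            assert a == pytest.approx(0.0, abs=1e-10)

    def test_dark_vj_has_none(self, params):
        kin = kinetics_at(MeteoInputs(Q=0.0, Ta=30.0, D=2.0, ca=400.0, P=95.0), params)
        assert ci_compensation(Limitation.VJ, kin) is None


class TestSolveCi:
    @pytest.mark.parametrize("branch", [Limitation.VC, Limitation.VJ])
    def test_self_inverse_on_grid(self, moderate_meteo, kin, branch):
        comp = ci_compensation(branch, kin)
        for c_star in np.linspace(comp + 2.0, moderate_meteo.ca - 2.0, 15):
            lam = lambda_of_ci(c_star, moderate_meteo, kin, branch)
            assert solve_ci(branch, lam, moderate_meteo, kin) == \
                pytest.approx(c_star, rel=1e-8)

    def test_result_inside_bracket(self, moderate_meteo, kin):
        ci = solve_ci(Limitation.VC, 2000.0, moderate_meteo, kin)
        assert kin.gamma_star < ci < moderate_meteo.ca

    def test_monotone_in_lambda(self, params):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = MeteoInputs(Q=float(rng.uniform(300, 2000)),
                            Ta=float(rng.uniform(15, 40)),
                            D=float(rng.uniform(0.5, 4)),
                            ca=float(rng.uniform(380, 420)),
                            P=float(rng.uniform(90, 100)))
            k = kinetics_at(m, params)
            c1 = solve_ci(Limitation.VC, 1200.0, m, k)
            c2 = solve_ci(Limitation.VC, 2400.0, m, k)
            assert c1 < c2

    def test_unattainable_lambda_raises_noroot(self, moderate_meteo, kin):
        with pytest.raises(NoRoot):
            solve_ci(Limitation.VC, 1e-6, moderate_meteo, kin)


class TestForward:
    def test_dark_floors_at_gmin(self, params):
        m = MeteoInputs(Q=0.0, Ta=30.0, D=2.0, ca=400.0, P=95.0)
        sol = forward("vj", CITRUS_LAMBDA_CO, m, params)
        assert sol.floored
        assert sol.gs == 0.01
        assert sol.converged
        # diffusion fixed point: A = gmin (ca - ci) / 1.6 with A = -Rd
        assert sol.A == pytest.approx(-params.Rd25, abs=1e-9)
        assert sol.ci == pytest.approx(m.ca + 1.6 * params.Rd25 / params.gmin, rel=1e-9)
        assert sol.E == pytest.approx(1e3 * 0.01 * m.D / m.P, rel=1e-12)

    def test_round_trip_master_invariant(self, params, moderate_meteo):
        for form in (Form.VC, Form.VJ, Form.COMBINED):
            sol = forward(form, CITRUS_LAMBDA_CO, moderate_meteo, params)
            assert sol.converged and not sol.floored
            rec = GasExchangeRecord(meteo=moderate_meteo, A=sol.A, E=sol.E,
                                    gs=sol.gs, ci=sol.ci)
            est = lambda_point(rec, params, branch=sol.branch)
            assert est.lam == pytest.approx(CITRUS_LAMBDA_CO, rel=1e-6)

    def test_fick_consistency(self, params, moderate_meteo):
        sol = forward("combined", 1500.0, moderate_meteo, params)
        assert sol.gs == pytest.approx(1.6 * sol.A / (moderate_meteo.ca - sol.ci), rel=1e-12)
        assert sol.E == pytest.approx(1e3 * sol.gs * moderate_meteo.D / moderate_meteo.P,
                                      rel=1e-12)

    def test_solution_bounds(self, params, moderate_meteo):
        kin = kinetics_at(moderate_meteo, params)
        sol = forward("combined", CITRUS_LAMBDA_CO, moderate_meteo, params)
        assert kin.gamma_star < sol.ci < moderate_meteo.ca
        assert sol.gs >= params.gmin

    def test_gs_and_ci_monotone_in_lambda(self, params, moderate_meteo):
        lams = [800.0, 1200.0, 1800.0, 2600.0, 4000.0]
        sols = [forward("combined", lam, moderate_meteo, params) for lam in lams]
        cis = [s.ci for s in sols]
        gss = [s.gs for s in sols]
        assert all(a < b for a, b in zip(cis, cis[1:]))
        assert all(a < b for a, b in zip(gss, gss[1:]))
        assert all(c < moderate_meteo.ca for c in cis)

    def test_combined_selects_limiting_branch(self, params):
        # high light: carboxylation limitation should prevail and match OSCvc
        m = MeteoInputs(Q=2200.0, Ta=30.0, D=2.0, ca=400.0, P=95.0)
        combined = forward("combined", CITRUS_LAMBDA_CO, m, params)
        kin = kinetics_at(m, params)
        assert assimilation(combined.ci, kin).limitation is combined.branch
        single = forward("vc" if combined.branch is Limitation.VC else "vj",
                         CITRUS_LAMBDA_CO, m, params)
        assert combined.ci == pytest.approx(single.ci, rel=1e-10)

    def test_combined_self_consistency_random(self, params):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(40):
            m = MeteoInputs(Q=float(rng.uniform(100, 2300)),
                            Ta=float(rng.uniform(10, 42)),
                            D=float(rng.uniform(0.3, 5)),
                            ca=float(rng.uniform(350, 600)),
                            P=float(rng.uniform(80, 102)))
            sol = forward("combined", float(rng.uniform(600, 4000)), m, params)
            if sol.floored or not sol.converged:
                continue
            rec = GasExchangeRecord(meteo=m, A=sol.A, E=sol.E, gs=sol.gs, ci=sol.ci)
            est = lambda_point(rec, params, branch=sol.branch)
            assert est.lam == pytest.approx(sol.lambda_used, rel=1e-6)
            checked += 1
        assert checked > 20

    def test_invalid_lambda_rejected(self, params, moderate_meteo):
        with pytest.raises(ValueError):
            forward("combined", -5.0, moderate_meteo, params)

    def test_form_aliases(self):
        assert as_form("vc") is Form.VC
        assert as_form("OSCvj") is Form.VJ
        assert as_form("combined") is Form.COMBINED
        with pytest.raises(ValueError):
            as_form("bogus")


class TestSimulateDataset:
    def _meteo(self, n, day="d1"):
        rng = np.random.default_rng(11)
        return [MeteoInputs(Q=float(rng.uniform(300, 2000)), Ta=25.0, D=2.0,
                            ca=400.0, P=95.0, day_id=day) for _ in range(n)]

    def test_long_term_equals_matching_daily(self, params):
        meteo = self._meteo(6)
        long = simulate_dataset(meteo, LambdaSchedule("long_term", 1500.0),
                                "combined", params)
        daily = simulate_dataset(meteo, LambdaSchedule("daily", {"d1": 1500.0}),
                                 "combined", params)
        assert [(s.ci, s.gs) for s in long] == [(s.ci, s.gs) for s in daily]

    def test_empty_input(self, params):
        out = simulate_dataset([], LambdaSchedule("long_term", 1500.0), "vc", params)
        assert out == []

    def test_missing_day_rejected_upfront(self, params):
        meteo = self._meteo(3, day="d1") + self._meteo(2, day="d2")
        with pytest.raises(KeyError, match="d2"):
            simulate_dataset(meteo, LambdaSchedule("daily", {"d1": 1500.0}),
                             "combined", params)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            LambdaSchedule("long_term", -1.0)
        with pytest.raises(ValueError):
            LambdaSchedule("daily", {})
        with pytest.raises(ValueError):
            LambdaSchedule("weekly", 1.0)
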