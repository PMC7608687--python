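"""Unit and property tests for the intracellular circuit model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoswitch.circuit_model import (
    CircuitState,
    ConfigurationError,
    ParamSet,
    SignalEnvironment,
    default_params,
    derivatives,
    effective_repressor,
    hill_act,
    hill_rep,
    integrate,
    integrate_many,
    rates_vec,
    single_pathway_steady_state,
)

pos = st.floats(min_value=1e-3, max_value=1e6)
hill_n = st.floats(min_value=1.0, max_value=4.0)


class TestHillAct:
    def test_zero_input(self):
        assert hill_act(0.0, 10.0, 2.0) == 0.0

    def test_half_saturation(self):
        assert hill_act(7.3, 7.3, 2.7) == pytest.approx(0.5)

    def test_hundredfold_k(self):
        # closed form: 1e4 / (1e4 + 1) = 0.99990001
        assert hill_act(100 * 5.0, 5.0, 2.0) == pytest.approx(0.9999, abs=5e-5)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hill_act(-1.0, 10.0, 2.0)
        with pytest.raises(ValueError):
            hill_act(np.nan, 10.0, 2.0)

    def test_bad_constants_rejected(self):
        with pytest.raises(ValueError):
            hill_act(1.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            hill_act(1.0, 1.0, 0.5)

    @given(s1=pos, s2=pos, K=pos, n=hill_n)
    def test_monotone_nondecreasing(self, s1, s2, K, n):
        lo, hi = sorted((s1, s2))
        assert hill_act(lo, K, n) <= hill_act(hi, K, n) + 1e-15

    @given(s=pos, K=pos, n=hill_n)
    def test_range(self, s, K, n):
        assert 0.0 <= hill_act(s, K, n) <= 1.0


class TestHillRep:
    def test_no_repressor(self):
        assert hill_rep(0.0, 3.0, 2.0) == 1.0

    def test_half_repression(self):
        assert hill_rep(3.0, 3.0, 2.0) == pytest.approx(0.5)

    def test_saturating_repression(self):
        assert hill_rep(1e300, 3.0, 2.0) == pytest.approx(0.0, abs=1e-12)

    @given(r1=pos, r2=pos, K=pos, n=hill_n)
    def test_monotone_nonincreasing(self, r1, r2, K, n):
        lo, hi = sorted((r1, r2))
        assert hill_rep(lo, K, n) >= hill_rep(hi, K, n) - 1e-15

    def test_complements_activation(self):
        assert hill_rep(4.0, 2.0, 3.0) + hill_act(4.0, 2.0, 3.0) == pytest.approx(1.0)


class TestEffectiveRepressor:
    def test_no_inducer(self):
        assert effective_repressor(5.0, 0.0, 100.0, 2.0) == 5.0

    def test_full_derepression(self):
        assert effective_repressor(5.0, np.inf, 100.0, 2.0) == 0.0

    def test_half_saturation(self):
        assert effective_repressor(5.0, 100.0, 100.0, 2.0) == pytest.approx(2.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            effective_repressor(-1.0, 0.0, 100.0, 2.0)
        with pytest.raises(ValueError):
            effective_repressor(1.0, -2.0, 100.0, 2.0)


class TestParamSet:
    def test_defaults_valid(self):
        ParamSet().validate()

    @pytest.mark.parametrize("field,value", [
        ("a_f", -1.0), ("K6", 0.0), ("n6", 0.5), ("g_r", 0.0),
        ("cross_lux_c12", 1.5), ("n_lac", 0.0),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            ParamSet(**{field: value})

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            ParamSet(circuit_variant="toggle")

    def test_json_roundtrip(self, tmp_path):
        p = ParamSet(K6=33.0, circuit_variant="receiver")
        path = tmp_path / "p.json"
        p.to_json(path)
        assert ParamSet.from_json(path) == p

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            ParamSet.from_dict({"K6": 10.0, "not_a_param": 1.0})


class TestSignalEnvironment:
    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            SignalEnvironment(c6=-1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            SignalEnvironment(c12=np.inf)


class TestDerivatives:
    def test_near_zero_synthesis_origin_absorbing(self):
        p = ParamSet(a_r=1e-12, b_r=0.0, a_f=1e-12, b_f=0.0)
        d = derivatives(CircuitState(), SignalEnvironment(c6=100.0), p)
        assert np.allclose(d.as_array(), 0.0, atol=1e-9)

    def test_pure_decay_without_activation(self, params):
        p = params.replace(b_f=0.0, b_r=0.0)
        state = CircuitState(cfp=4.0)
        d = derivatives(state, SignalEnvironment(), p)
        assert d.cfp == pytest.approx(-p.g_cfp * 4.0)

    def test_negative_state_rejected(self, params):
        with pytest.raises(ValueError):
            derivatives(CircuitState(cfp=-1.0), SignalEnvironment(), params)

    def test_single_pathway_analytic_vs_integration(self, params):
        env = SignalEnvironment(c6=500.0)
        analytic = single_pathway_steady_state(env, params, "c6")
        traj = integrate(np.zeros(6), env, params, 400.0, rtol=1e-9, atol=1e-11)
        assert np.allclose(traj.states[-1], analytic, rtol=1e-3)

    def test_zero_rate_at_analytic_steady_state(self, params):
        env = SignalEnvironment(c6=500.0)
        y = single_pathway_steady_state(env, params, "c6")
        d = rates_vec(y, env.c6, env.c12, env.iptg, env.atc, params)
        assert np.allclose(d, 0.0, atol=1e-6 * params.a_f)

    def test_krep_to_infinity_reduces_to_receiver(self, params, receiver_params):
        big = params.replace(K_lac=1e12, K_tet=1e12)
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.uniform(0, 100, 6)
            env = SignalEnvironment(c6=rng.uniform(0, 500), c12=rng.uniform(0, 500))
            d_big = rates_vec(y, env.c6, env.c12, 0.0, 0.0, big)
            d_rec = rates_vec(y, env.c6, env.c12, 0.0, 0.0, receiver_params)
            assert np.allclose(d_big, d_rec, rtol=1e-9, atol=1e-9)


class TestIntegrate:
    def test_monostable_cfp_high_terminal(self, params):
        traj = integrate(np.zeros(6), SignalEnvironment(c6=500.0), params, 40.0)
        end = traj.terminal
        assert end.cfp > 10 * end.yfp

    def test_fixed_point_stays_fixed(self, params):
        env = SignalEnvironment(c6=500.0)
        y_ss = single_pathway_steady_state(env, params, "c6")
        traj = integrate(y_ss, env, params, 20.0)
        assert np.allclose(traj.states, y_ss[None, :], rtol=1e-4)

    def test_tolerance_self_consistency(self, params):
        env = SignalEnvironment(c6=60.0, c12=900.0)
        loose = integrate(np.zeros(6), env, params, 10.0, rtol=1e-5, atol=1e-8)
        tight = integrate(np.zeros(6), env, params, 10.0, rtol=1e-9, atol=1e-12)
        diff = np.abs(loose.states[-1] - tight.states[-1])
        assert np.all(diff <= 10 * 1e-5 * (np.abs(tight.states[-1]) + 1.0))

    def test_invalid_t_end(self, params):
        with pytest.raises(ValueError):
            integrate(np.zeros(6), SignalEnvironment(), params, 0.0)

    def test_piecewise_schedule(self, params):
        sched = [(0.0, SignalEnvironment(c6=500.0)), (2.0, SignalEnvironment(c12=500.0))]
        traj = integrate(np.zeros(6), sched, params, 4.0)
        # conditioning built CFP; after the switch YFP production resumes
        assert traj.terminal.cfp > 0
        k = np.searchsorted(traj.times, 2.0)
        assert traj.states[-1, 5] > traj.states[k, 5]

    def test_schedule_must_start_at_zero(self, params):
        with pytest.raises(ValueError):
            integrate(np.zeros(6), [(1.0, SignalEnvironment())], params, 4.0)

    @settings(max_examples=20, deadline=None)
    @given(
        c6=st.floats(min_value=0, max_value=1e3),
        c12=st.floats(min_value=0, max_value=1e4),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_nonnegativity(self, c6, c12, seed):
        p = default_params()
        rng = np.random.default_rng(seed)
        y0 = rng.uniform(0, 50, 6)
        traj = integrate(y0, SignalEnvironment(c6=c6, c12=c12), p, 5.0)
        assert np.all(traj.states >= 0)
        assert np.all(np.diff(traj.times) > 0)


class TestExclusivity:
    """Sign structure of the dose-response grids."""

    def test_exclusive_single_signals(self, params):
        end6 = integrate(np.zeros(6), SignalEnvironment(c6=500.0), params, 24.0).terminal
        end12 = integrate(np.zeros(6), SignalEnvironment(c12=500.0), params, 24.0).terminal
        assert end6.cfp > 10 * end6.yfp
        assert end12.yfp > 10 * end12.cfp

    def test_receiver_coexpresses_both(self, params, receiver_params):
        both = SignalEnvironment(c6=500.0, c12=5000.0)
        rec_both = integrate(np.zeros(6), both, receiver_params, 24.0).terminal
        rec_c6 = integrate(np.zeros(6), SignalEnvironment(c6=500.0),
                           receiver_params, 24.0).terminal
        rec_c12 = integrate(np.zeros(6), SignalEnvironment(c12=5000.0),
                            receiver_params, 24.0).terminal
        assert rec_both.cfp > 0.5 * rec_c6.cfp
        assert rec_both.yfp > 0.5 * rec_c12.yfp

        exc_both = integrate(np.zeros(6), both, params, 24.0).terminal
        exc_c6 = integrate(np.zeros(6), SignalEnvironment(c6=500.0), params, 24.0).terminal
        exc_c12 = integrate(np.zeros(6), SignalEnvironment(c12=5000.0), params, 24.0).terminal
        minor = min(exc_both.cfp / exc_c6.cfp, exc_both.yfp / exc_c12.yfp)
        assert minor < 0.10


class TestIntegrateMany:
    def test_matches_solve_ivp(self, params):
        env = SignalEnvironment(c6=80.0, c12=700.0, iptg=10.0)
        y_rk = integrate_many(np.zeros((6, 1)), env.c6, env.c12, env.iptg,
                              env.atc, params, 7.0, dt=0.02)[:, 0]
        y_ivp = integrate(np.zeros(6), env, params, 7.0,
                          rtol=1e-10, atol=1e-12).states[-1]
        assert np.allclose(y_rk, y_ivp, rtol=1e-5, atol=1e-8)

    def test_vectorised_equals_loop(self, params):
        c6s = np.array([0.0, 50.0, 500.0])
        batch = integrate_many(np.zeros((6, 3)), c6s, 100.0, 0.0, 0.0, params, 3.0)
        for j, c6 in enumerate(c6s):
            single = integrate_many(np.zeros((6, 1)), c6, 100.0, 0.0, 0.0, params, 3.0)
            assert np.allclose(batch[:, j], single[:, 0])


class TestTrajectory:
    def test_to_dataframe(self, params):
        traj = integrate(np.zeros(6), SignalEnvironment(c6=100.0), params, 2.0)
        df = traj.to_dataframe()
        assert list(df.columns) == ["t", "luxR", "lasR", "lacI", "tetR", "cfp", "yfp"]
        assert len(df) == traj.times.size

    def test_csv_roundtrip(self, params, tmp_path):
        import pandas as pd

        traj = integrate(np.zeros(6), SignalEnvironment(c6=100.0), params, 2.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert np.allclose(df["cfp"], traj.states[:, 4])
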