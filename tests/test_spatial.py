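"""Reaction-diffusion simulator tests: ICs, conservation, homogenisation, relay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoswitch.bistability import find_equilibria
from morphoswitch.circuit_model import SignalEnvironment, integrate_many
from morphoswitch.spatial import (
    SpatialConfig,
    make_antiparallel_ic,
    make_central_source_ic,
    phase_trajectories,
    simulate_rd,
    simulate_relay,
)

FAST = SpatialConfig(L=4.0, n_x=41, t_end=2.0, output_every=0.5)


class TestSpatialConfig:
    def test_defaults_valid(self):
        SpatialConfig()

    @pytest.mark.parametrize("kw", [
        {"L": -1.0}, {"n_x": 2}, {"D_c6": 0.0}, {"t_end": 0.0},
        {"hsl_decay": -0.1}, {"dt_split": 0.0},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SpatialConfig(**kw)

    def test_grid_is_cell_centred(self):
        c = SpatialConfig(L=10.0, n_x=10)
        assert np.allclose(c.x, np.arange(0.5, 10.0, 1.0))


class TestAntiparallelIC:
    def test_four_x_amplitude(self):
        cfg = SpatialConfig(L=8.0, n_x=100)
        c6, c12 = make_antiparallel_ic(200.0, 2000.0, 0.25, cfg)
        assert c6.max() == pytest.approx(800.0)
        assert c12.max() == pytest.approx(8000.0)
        assert c6.mean() == pytest.approx(200.0)
        assert c12.mean() == pytest.approx(2000.0)

    def test_orientation(self):
        cfg = SpatialConfig(L=8.0, n_x=100)
        c6, c12 = make_antiparallel_ic(100.0, 100.0, 0.25, cfg)
        assert c12[0] > 0 and c12[-1] == 0       # C12 from the left
        assert c6[-1] > 0 and c6[0] == 0         # C6 from the right

    def test_zero_average_gives_zero_field(self):
        c6, c12 = make_antiparallel_ic(0.0, 0.0, 0.25, FAST)
        assert not c6.any() and not c12.any()

    @settings(max_examples=60, deadline=None)
    @given(
        avg6=st.floats(min_value=0.0, max_value=1e4),
        avg12=st.floats(min_value=0.0, max_value=1e4),
        frac=st.floats(min_value=0.01, max_value=0.5),
        n_x=st.integers(min_value=10, max_value=301),
    )
    def test_mean_exact_for_any_geometry(self, avg6, avg12, frac, n_x):
        cfg = SpatialConfig(L=8.0, n_x=n_x)
        c6, c12 = make_antiparallel_ic(avg6, avg12, frac, cfg)
        assert c6.mean() == pytest.approx(avg6, rel=1e-9, abs=1e-12)
        assert c12.mean() == pytest.approx(avg12, rel=1e-9, abs=1e-12)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            make_antiparallel_ic(1.0, 1.0, 0.6, FAST)
        with pytest.raises(ValueError):
            make_antiparallel_ic(-1.0, 1.0, 0.25, FAST)


class TestCentralSourceIC:
    def test_mean_is_conc_times_fraction(self):
        cfg = SpatialConfig(L=20.0, n_x=161)
        f = make_central_source_ic(40000.0, 0.1, cfg)
        assert f.mean() == pytest.approx(4000.0)
        assert f.max() == pytest.approx(40000.0)

    def test_zero_conc(self):
        assert not make_central_source_ic(0.0, 0.1, FAST).any()

    def test_window_centred(self):
        cfg = SpatialConfig(L=10.0, n_x=101)
        f = make_central_source_ic(100.0, 0.2, cfg)
        centroid = np.sum(f * cfg.x) / np.sum(f)
        assert abs(centroid - cfg.L / 2) <= 0.5 * cfg.dx

    @settings(max_examples=40, deadline=None)
    @given(conc=st.floats(min_value=0.0, max_value=1e5),
           frac=st.floats(min_value=0.02, max_value=0.5),
           n_x=st.integers(min_value=10, max_value=201))
    def test_mean_exact(self, conc, frac, n_x):
        cfg = SpatialConfig(L=20.0, n_x=n_x)
        f = make_central_source_ic(conc, frac, cfg)
        assert f.mean() == pytest.approx(conc * frac, rel=1e-9, abs=1e-12)


class TestSimulateRd:
    def test_mass_conservation(self, params):
        cfg = SpatialConfig(L=8.0, n_x=81, t_end=4.0, output_every=0.5)
        ic = make_antiparallel_ic(200.0, 2000.0, 0.25, cfg)
        f = simulate_rd(cfg, params, ic)
        for sig in ("c6", "c12"):
            m = f.mass(sig)
            assert np.all(np.abs(m - m[0]) <= 1e-6 * m[0])

    def test_uniform_ic_stays_constant(self, params):
        ic = (np.full(FAST.n_x, 50.0), np.full(FAST.n_x, 500.0))
        f = simulate_rd(FAST, params, ic)
        assert np.allclose(f.c6, 50.0, rtol=1e-9)
        assert np.allclose(f.c12, 500.0, rtol=1e-9)

    def test_homogenisation_limit(self, params):
        cfg = SpatialConfig(L=2.0, n_x=41, D_c6=0.36, D_c12=0.36,
                            t_end=60.0, output_every=5.0)
        ic = make_antiparallel_ic(100.0, 1000.0, 0.25, cfg)
        f = simulate_rd(cfg, params, ic)
        assert np.max(np.abs(f.c6[-1] - 100.0)) < 0.01 * 100.0
        assert np.max(np.abs(f.c12[-1] - 1000.0)) < 0.01 * 1000.0

    def test_fields_nonnegative(self, params):
        cfg = SpatialConfig(L=8.0, n_x=61, t_end=3.0)
        ic = make_antiparallel_ic(20.0, 2000.0, 0.25, cfg)
        f = simulate_rd(cfg, params, ic)
        assert np.all(f.c6 >= 0) and np.all(f.c12 >= 0)
        assert np.all(f.states >= 0)

    def test_decay_removes_mass(self, params):
        cfg = SpatialConfig(L=4.0, n_x=41, t_end=2.0, hsl_decay=0.5)
        ic = make_antiparallel_ic(100.0, 100.0, 0.25, cfg)
        f = simulate_rd(cfg, params, ic)
        expected = f.mass("c6")[0] * np.exp(-0.5 * f.times[-1])
        assert f.mass("c6")[-1] == pytest.approx(expected, rel=1e-2)

    def test_splitting_self_convergence(self, params):
        cfg1 = SpatialConfig(L=8.0, n_x=61, t_end=4.0, dt_split=0.02)
        cfg2 = SpatialConfig(L=8.0, n_x=61, t_end=4.0, dt_split=0.01)
        ic = make_antiparallel_ic(200.0, 2000.0, 0.25, cfg1)
        f1 = simulate_rd(cfg1, params, ic)
        f2 = simulate_rd(cfg2, params, ic)
        scale = np.abs(f2.states[-1]).max()
        assert np.max(np.abs(f1.states[-1] - f2.states[-1])) < 1e-2 * scale

    def test_ic_shape_mismatch(self, params):
        with pytest.raises(ValueError):
            simulate_rd(FAST, params, (np.zeros(5), np.zeros(FAST.n_x)))

    def test_dataframe_export(self, params):
        f = simulate_rd(FAST, params, make_antiparallel_ic(10.0, 10.0, 0.25, FAST))
        df = f.to_dataframe()
        assert {"t", "x", "c6", "c12", "cfp", "yfp"} <= set(df.columns)
        assert len(df) == f.times.size * FAST.n_x


RELAY_CFG = SpatialConfig(L=20.0, n_x=81, t_end=6.0, output_every=0.5)


class TestRelay:
    def test_zero_relay_equals_plain_rd(self, params):
        p = params.replace(circuit_variant="relay_c6_to_c12", k_relay=0.0)
        ic = (make_central_source_ic(40000.0, 0.1, RELAY_CFG), np.zeros(RELAY_CFG.n_x))
        fa = simulate_relay(RELAY_CFG, p, "C6")
        fb = simulate_rd(RELAY_CFG, p, ic)
        assert np.allclose(fa.c12, fb.c12)
        assert np.allclose(fa.states, fb.states)

    def test_secondary_mass_nondecreasing(self, params):
        p = params.replace(circuit_variant="relay_c6_to_c12")
        f = simulate_relay(RELAY_CFG, p, "C6")
        m12 = f.mass("c12")
        assert np.all(np.diff(m12) >= -1e-9)
        assert m12[-1] > m12[0]

    def test_primary_mass_constant(self, params):
        p = params.replace(circuit_variant="relay_c6_to_c12")
        f = simulate_relay(RELAY_CFG, p, "C6")
        m6 = f.mass("c6")
        assert np.all(np.abs(m6 - m6[0]) <= 1e-6 * m6[0])

    def test_variant_mismatch_rejected(self, params):
        p = params.replace(circuit_variant="relay_c12_to_c6")
        with pytest.raises(ValueError):
            simulate_relay(RELAY_CFG, p, "C6")

    def test_invalid_primary(self, params):
        with pytest.raises(ValueError):
            simulate_relay(RELAY_CFG, params, "C9")


class TestPhaseTrajectories:
    def test_mean_path_constant_without_relay(self, params):
        cfg = SpatialConfig(L=8.0, n_x=61, t_end=3.0)
        ic = make_antiparallel_ic(200.0, 2000.0, 0.25, cfg)
        f = simulate_rd(cfg, params, ic)
        ph = phase_trajectories(f)
        assert np.allclose(ph["mean_path"][:, 0], 200.0, rtol=1e-6)
        assert np.allclose(ph["mean_path"][:, 1], 2000.0, rtol=1e-6)

    def test_positions_converge_to_mean(self, params):
        cfg = SpatialConfig(L=2.0, n_x=41, t_end=40.0, output_every=5.0)
        ic = make_antiparallel_ic(100.0, 1000.0, 0.25, cfg)
        ph = phase_trajectories(simulate_rd(cfg, params, ic))
        final = ph["paths"][:, -1, :]
        mean_final = ph["mean_path"][-1]
        assert np.all(np.abs(final - mean_final) <= 0.01 * (mean_final + 1e-12))

    def test_relay_mean_c12_increases(self, params):
        p = params.replace(circuit_variant="relay_c6_to_c12")
        ph = phase_trajectories(simulate_relay(RELAY_CFG, p, "C6"))
        c12_mean = ph["mean_path"][:, 1]
        assert np.all(np.diff(c12_mean) >= -1e-12)
        assert c12_mean[-1] > c12_mean[0]


class TestHysteresisPatternLink:
    """Terminal states near each source match the respective conditioned state."""

    def test_ends_match_conditioned_equilibria(self, params):
        cfg = SpatialConfig(L=8.0, n_x=61, t_end=48.0, output_every=4.0)
        ic = make_antiparallel_ic(200.0, 2000.0, 0.25, cfg)
        f = simulate_rd(cfg, params, ic)

        env = SignalEnvironment(c6=200.0, c12=2000.0, iptg=10.0)
        eqs = [e for e in find_equilibria(env, params) if e.is_stable]
        assert len(eqs) == 2
        cfp_high = max(eqs, key=lambda e: e.state[4]).state
        yfp_high = max(eqs, key=lambda e: e.state[5]).state

        core = slice(0, 4)  # fast species: receptors + repressors
        right = f.states[-1, :, -3]   # near the C6 source
        left = f.states[-1, :, 2]     # near the C12 source
        rel = lambda a, b: np.max(np.abs(a - b) / (np.abs(b) + 1e-6))
        assert rel(right[core], cfp_high[core]) < 0.05
        assert rel(left[core], yfp_high[core]) < 0.05
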