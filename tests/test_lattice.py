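"""Lattice geometry, state initialization and synchronous-update tests."""

import numpy as np
import pytest

from neuroca.activation import ActivationParams, evaluate
from neuroca.lattice import (
    ConfigError,
    LatticeConfig,
    binary_state,
    build_neighbor_map,
    initialize_state,
    run,
    step,
    uniform_state,
)

from conftest import ALL_GEOMETRIES, brute_force_step


class TestNeighborMap:
    def test_toroidal_moore_counts(self):
        nm = build_neighbor_map(LatticeConfig(rows=5, cols=5))
        assert set(nm.counts) == {8}
        assert all(i not in nm.neighbors(i) for i in range(25))

    def test_outer_totalistic_includes_self(self):
        nm = build_neighbor_map(
            LatticeConfig(rows=5, cols=5, neighborhood="outer_totalistic")
        )
        assert set(nm.counts) == {9}
        assert all(i in nm.neighbors(i) for i in range(25))

    def test_spherical_pole_counts(self):
        nm = build_neighbor_map(LatticeConfig(rows=5, cols=5, boundary="spherical"))
        counts = nm.counts.reshape(5, 5)
        assert set(counts[0]) == {7} and set(counts[-1]) == {7}  # (cols-1)+3
        assert set(counts[1:-1].ravel()) == {8}

    def test_layered_counts(self):
        nm2 = build_neighbor_map(LatticeConfig(rows=3, cols=3, n_layers=2))
        nm4 = build_neighbor_map(LatticeConfig(rows=3, cols=3, n_layers=4))
        assert set(nm2.counts) == {9}  # 8 intra + 1 overlay
        assert set(nm4.counts) == {10}  # 8 intra + overlay above and below

    @pytest.mark.parametrize("boundary,neighborhood,n_layers", ALL_GEOMETRIES)
    def test_adjacency_symmetric(self, boundary, neighborhood, n_layers):
        cfg = LatticeConfig(
            rows=6, cols=5, n_layers=n_layers,
            boundary=boundary, neighborhood=neighborhood,
        )
        nm = build_neighbor_map(cfg)
        for i in range(cfg.n_cells):
            for j in nm.neighbors(i):
                assert i in nm.neighbors(int(j))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            LatticeConfig(rows=2, cols=5)
        with pytest.raises(ConfigError):
            LatticeConfig(boundary="kleinbottle")
        with pytest.raises(ConfigError):
            LatticeConfig(ext_fraction=1.5)


class TestInitialization:
    def test_seed_determinism(self):
        cfg = LatticeConfig(rows=10, cols=10, ext_fraction=0.1, seed=7)
        s1, s2 = initialize_state(cfg), initialize_state(cfg)
        assert np.array_equal(s1.a, s2.a)
        assert np.array_equal(s1.clamp_mask, s2.clamp_mask)

    def test_clamp_count_and_value(self):
        cfg = LatticeConfig(rows=10, cols=10, ext_fraction=0.05, seed=3)
        s = initialize_state(cfg)
        assert s.clamp_mask.sum() == 5  # round(0.05 * 100)
        assert np.all(s.a[s.clamp_mask] == 1.0)

    def test_no_clamps_by_default(self):
        s = initialize_state(LatticeConfig(rows=8, cols=8))
        assert s.clamp_mask.sum() == 0

    def test_binary_state_fraction(self):
        cfg = LatticeConfig(rows=10, cols=10, seed=5)
        s = binary_state(cfg, 0.25)
        assert np.sum(s.a == 1.0) == 25
        assert np.sum(s.a == 0.0) == 75


class TestStep:
    def test_homogeneous_lattice_follows_single_cell_map(self):
        """A spatially uniform lattice stays uniform: one update equals a
        single application of the activation map."""
        p = ActivationParams.linear(0.2, 0.6, 0.8)
        cfg = LatticeConfig(rows=8, cols=8)
        nm = build_neighbor_map(cfg)
        for v in (0.0, 0.3, 0.55, 0.9):
            s = uniform_state(cfg, v)
            step(s, nm, p)
            assert np.allclose(s.a, evaluate(v, p), atol=1e-12)

    def test_quiescence_absorbing_with_threshold(self):
        p = ActivationParams.linear(0.3, 0.8, 0.9)
        cfg = LatticeConfig(rows=8, cols=8)
        s = uniform_state(cfg, 0.0)
        step(s, build_neighbor_map(cfg), p)
        assert np.all(s.a == 0.0)

    @pytest.mark.parametrize("boundary,neighborhood,n_layers", ALL_GEOMETRIES)
    @pytest.mark.parametrize("order", ["linear", "nonlinear"])
    def test_update_matches_brute_force(self, boundary, neighborhood, n_layers, order):
        """The sparse-matrix update equals naive per-cell neighbor-list
        averaging on random 8x8 lattices, for every geometry and rule."""
        cfg = LatticeConfig(
            rows=8, cols=8, n_layers=n_layers,
            boundary=boundary, neighborhood=neighborhood, seed=11,
        )
        if order == "linear":
            p = ActivationParams.linear(0.2, 0.7, 0.9)
        else:
            p = ActivationParams.nonlinear(0.1, 0.8, 3.0)
        state = initialize_state(cfg)
        expected = brute_force_step(state.a.copy(), cfg, p)
        step(state, build_neighbor_map(cfg), p)
        assert np.max(np.abs(state.a - expected)) < 1e-12

    def test_clamped_cells_held_at_ext_value(self):
        cfg = LatticeConfig(rows=10, cols=10, ext_fraction=0.1, seed=2)
        p = ActivationParams.linear(0.2, 0.6, 0.8)
        s = initialize_state(cfg)
        nm = build_neighbor_map(cfg)
        for _ in range(5):
            step(s, nm, p)
            assert np.all(s.a[s.clamp_mask] == 1.0)


class TestRun:
    def test_series_length_and_bounds(self):
        cfg = LatticeConfig(rows=16, cols=16, timesteps=40)
        res = run(cfg, ActivationParams.linear(0.1, 0.5, 1.0))
        assert res.mean_activity.shape == (41,)
        assert 0.0 <= res.steady_state <= 1.0

    def test_zero_map_dies_immediately(self):
        cfg = LatticeConfig(rows=16, cols=16, timesteps=30)
        res = run(cfg, ActivationParams.linear(0.5, 0.5, 0.8))
        assert np.all(res.mean_activity[1:] == 0.0)

    def test_state_bounded_for_all_times(self):
        cfg = LatticeConfig(rows=16, cols=16, timesteps=50, ext_fraction=0.05)
        res = run(cfg, ActivationParams.nonlinear(0.1, 1.0, 3.0), record_all=True)
        for snap in res.snapshots.values():
            assert np.all(snap >= 0.0) and np.all(snap <= 1.0)

    def test_layer_indifference(self):
        """Starting every layer from the same field, each layer's mean series
        coincides with the whole-system mean at all times."""
        from neuroca.lattice import PatchState

        rng = np.random.default_rng(4)
        field = rng.uniform(0, 1, size=(32, 32))
        for n_layers in (2, 4):
            cfg = LatticeConfig(rows=32, cols=32, n_layers=n_layers, timesteps=30)
            init = PatchState(
                np.tile(field, (n_layers, 1, 1)),
                np.zeros((n_layers, 32, 32), dtype=bool),
            )
            res = run(cfg, ActivationParams.linear(0.1, 0.5, 1.0),
                      init_state=init, record_all=True)
            for t, snap in res.snapshots.items():
                layer_means = snap.mean(axis=(1, 2))
                assert np.allclose(layer_means, res.mean_activity[t], atol=1e-12)

    def test_steady_state_is_mean_of_last_ten(self):
        cfg = LatticeConfig(rows=16, cols=16, timesteps=60, seed=9)
        res = run(cfg, ActivationParams.linear(0.1, 0.4, 0.7))
        assert res.steady_state == pytest.approx(res.mean_activity[-10:].mean())
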