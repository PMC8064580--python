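import dataclasses

import numpy as np
import pytest
from scipy.stats import fisher_exact

from bindsteer.engine import (
    KB,
    EngineConfig,
    EngineError,
    PackingError,
    PotentialField,
    first_binding_time,
    place_ligands_uniform,
    run_simulation,
    step_update,
)
from bindsteer.biasing import FlatBottomConfig, SteeringConfig
from bindsteer.geometry import PeriodicBox

from conftest import small_run_config


class TestStepUpdate:
    def test_deterministic_drift_from_constant_force(self):
        """Overdamped displacement (D/kBT)·F·dt per axis with the noise zeroed."""
        cfg = EngineConfig(n_steps=1, dt=0.01, temperature=300.0, diffusion=0.6)
        kBT = KB * 300.0
        pos = np.array([[0.0, 0.0, 50.0]])
        F = np.array([[0.0, 0.0, -5.0]])
        new = step_update(pos, F, cfg, np.zeros((1, 3)))
        expected_dz = 0.6 / kBT * (-5.0) * 0.01
        assert kBT == pytest.approx(0.59616)
        assert new[0, 2] - 50.0 == pytest.approx(expected_dz, rel=1e-12)
        assert expected_dz == pytest.approx(-0.050322, abs=1e-6)

    def test_no_force_no_noise_is_a_fixed_point(self):
        cfg = EngineConfig(n_steps=1)
        pos = np.array([[1.0, 2.0, 3.0]])
        new = step_update(pos, np.zeros((1, 3)), cfg, np.zeros((1, 3)))
        assert np.allclose(new, pos)

    def test_membrane_wall_reflection(self):
        cfg = EngineConfig(n_steps=1, diffusion=0.6, dt=0.01)
        pos = np.array([[0.0, 0.0, 0.01]])
        # noise chosen so the raw z update would be 0.01 - 0.31 = -0.3
        xi = -0.31 / np.sqrt(2 * 0.6 * 0.01)
        new = step_update(pos, np.zeros((1, 3)), cfg, np.array([[0.0, 0.0, xi]]))
        assert new[0, 2] == pytest.approx(0.3, abs=1e-9)

    def test_periodic_wrap_in_xy(self):
        cfg = EngineConfig(n_steps=1)
        pos = np.array([[59.9, -59.9, 10.0]])
        xi = 0.5 / np.sqrt(2 * 0.6 * 0.01)
        new = step_update(pos, np.zeros((1, 3)), cfg, np.array([[xi, -xi, 0.0]]))
        assert new[0, 0] == pytest.approx(-59.6, abs=1e-9)
        assert new[0, 1] == pytest.approx(59.6, abs=1e-9)


class TestPlacement:
    def test_76_ligands_respect_separation_and_halfspace(self):
        box = PeriodicBox()
        pos = place_ligands_uniform(76, box, min_separation=6.0, seed=11)
        assert pos.shape == (76, 3)
        assert np.all(pos[:, 2] > 0)
        delta = box.minimum_image(pos[:, None, :] - pos[None, :, :])
        d = np.linalg.norm(delta, axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 6.0

    def test_single_ligand_inside_slab(self):
        pos = place_ligands_uniform(1, PeriodicBox(), seed=1)
        assert pos.shape == (1, 3) and 0 < pos[0, 2] < 100

    def test_reproducible_from_seed(self):
        a = place_ligands_uniform(10, PeriodicBox(), seed=5)
        b = place_ligands_uniform(10, PeriodicBox(), seed=5)
        assert np.array_equal(a, b)

    def test_impossible_packing_raises(self):
        with pytest.raises(PackingError, match="separation"):
            place_ligands_uniform(50, PeriodicBox((20, 20, 20), (True, True, False)),
                                  min_separation=15.0, seed=0)


class TestRunSimulation:
    def test_zero_steps_yields_initial_frame_only(self, structure, draft_config):
        cfg = dataclasses.replace(draft_config, n_steps=0)
        r = run_simulation(structure, cfg)
        assert r.trajectory.n_frames == 1
        assert r.distances[0, 0] == pytest.approx(cfg.initial_distance)

    def test_same_seed_bitwise_identical(self, structure, draft_config):
        cfg = small_run_config(draft_config)
        r1 = run_simulation(structure, cfg, SteeringConfig())
        r2 = run_simulation(structure, cfg, SteeringConfig())
        assert np.array_equal(r1.trajectory.coords, r2.trajectory.coords)
        assert np.array_equal(r1.trajectory.flags, r2.trajectory.flags)
        r3 = run_simulation(structure, dataclasses.replace(cfg, seed=cfg.seed + 1), SteeringConfig())
        assert not np.array_equal(r1.trajectory.coords, r3.trajectory.coords)

    def test_unresolvable_reference_fails_before_stepping(self, structure, draft_config):
        cfg = dataclasses.replace(draft_config, reference="GLU:42:CD", n_steps=10)
        with pytest.raises(Exception, match="no atom matches"):
            run_simulation(structure, cfg)

    def test_wall_never_penetrated_and_events_logged(self, structure, draft_config):
        cfg = small_run_config(draft_config, n_steps=5000, record_stride=10)
        r = run_simulation(structure, cfg, SteeringConfig())
        assert np.all(r.trajectory.coords[:, :, 2] >= 0)
        kinds = {e["event"] for e in r.events}
        assert "force_on" in kinds and "force_off" in kinds
        assert all(isinstance(e["step"], int) for e in r.events)

    def test_steering_acceleration_over_unbiased(self, structure, draft_config):
        """Steered replicates overwhelmingly reach the bound state within the
        step budget; identical unbiased replicates mostly do not."""
        cfg = small_run_config(draft_config, n_steps=50_000, n_ligands=20,
                               record_stride=100, seed=42)
        steered = run_simulation(structure, cfg, SteeringConfig())
        unbiased = run_simulation(structure, cfg, None)
        bound_steer = np.isfinite(steered.first_binding_times(threshold=7.0, dwell=5))
        bound_free = np.isfinite(unbiased.first_binding_times(threshold=7.0, dwell=5))
        assert bound_steer.mean() >= 0.9
        assert bound_free.mean() <= 0.3

    def test_well_occupancy_monotone_in_depth(self, structure, draft_config):
        """Equilibrium occupancy of the binding-well region grows with well
        depth (flat-bottom containment keeps the comparison bounded)."""
        occ = []
        for eps in (0.0, 2.0, 5.0):
            cfg = small_run_config(
                draft_config, n_steps=40_000, record_stride=10, seed=9,
                n_ligands=8, potential=PotentialField(well_depth=eps),
            )
            r = run_simulation(structure, cfg, FlatBottomConfig(cutoff=12.0))
            occ.append(float(np.mean(r.distances < 4.0)))
        assert occ[0] < occ[1] < occ[2]

    def test_high_concentration_accelerates_first_binding(self, structure, draft_config):
        """With 76 ligands the chance that at least one binds within the
        budget beats the single-ligand chance (binomial comparison)."""
        n_seeds = 30
        steps = 50_000
        hits76 = 0
        for seed in range(n_seeds):
            cfg = dataclasses.replace(
                draft_config, n_steps=steps, record_stride=100, seed=seed,
                n_ligands=76, initial_distance=None,
            )
            r = run_simulation(structure, cfg, None)
            hits76 += int(np.any(np.isfinite(r.first_binding_times(threshold=7.0, dwell=5))))
        cfg1 = dataclasses.replace(
            draft_config, n_steps=steps, record_stride=100, seed=123,
            n_ligands=n_seeds, initial_distance=None,
        )
        r1 = run_simulation(structure, cfg1, None)
        hits1 = int(np.sum(np.isfinite(r1.first_binding_times(threshold=7.0, dwell=5))))
        table = [[hits76, n_seeds - hits76], [hits1, n_seeds - hits1]]
        _, p = fisher_exact(table, alternative="greater")
        assert p < 0.05, f"76-ligand hits {hits76}/{n_seeds} vs single-ligand {hits1}/{n_seeds}"


class TestFirstBindingTime:
    def _result_from_series(self, series):
        class R:
            pass

        r = R()
        r.distances = np.asarray(series, dtype=float)[:, None]

        class T:
            pass

        r.trajectory = T()
        r.trajectory.times = np.arange(len(series), dtype=float)
        return r

    def test_hand_traced_dwell_rule(self):
        series = [10, 8, 6, 5, 5, 4, 4, 4]
        t = first_binding_time(self._result_from_series(series), threshold=7.0, dwell=2)
        assert t[0] == 2.0  # first frame of the first 2-long run below 7

    def test_never_bound_is_nan(self):
        t = first_binding_time(self._result_from_series([10, 9, 8]), threshold=7.0, dwell=1)
        assert np.isnan(t[0])

    def test_dwell_one_first_frame(self):
        t = first_binding_time(self._result_from_series([5, 9, 9]), threshold=7.0, dwell=1)
        assert t[0] == 0.0

    def test_invalid_parameters(self):
        r = self._result_from_series([5.0])
        with pytest.raises(ValueError):
            first_binding_time(r, threshold=-1)
        with pytest.raises(ValueError):
            first_binding_time(r, dwell=0)


def test_config_validation():
    with pytest.raises(ValueError):
        EngineConfig(n_steps=-1)
    with pytest.raises(ValueError):
        EngineConfig(n_steps=1, dt=0.0)
    with pytest.raises(ValueError):
        EngineConfig(n_steps=1, n_ligands=0)


def test_initial_distance_outside_box_rejected(structure, draft_config):
    cfg = dataclasses.replace(draft_config, n_steps=10, initial_distance=1e6)
    with pytest.raises(EngineError, match="outside the box"):
        run_simulation(structure, cfg)
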