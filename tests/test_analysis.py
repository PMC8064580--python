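import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bindsteer.analysis import (
    BindingEvent,
    bias_fraction,
    conformer_classify,
    detect_binding_events,
    distance_series,
    rdf,
)
from bindsteer.fixtures import synth_dihedral_trajectory
from bindsteer.geometry import PeriodicBox
from bindsteer.model_io import SelectionError, Trajectory


def _traj(coords, labels, times=None, box=None, flags=None):
    coords = np.asarray(coords, dtype=float)
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(times, coords, labels, flags, box=box)


class TestDistanceSeries:
    def test_three_four_five(self):
        t = _traj([[[3.0, 4.0, 0.0]]], ["LIG1:CA"])
        ds = distance_series(t, np.zeros(3), "LIG1:CA")
        assert ds.distances[0] == pytest.approx(5.0)

    def test_static_pair_is_constant(self, structure):
        t = _traj(np.random.default_rng(0).normal(size=(5, 1, 3)), ["LIG1:CA"])
        ds = distance_series(t, "ARG:397:CZ", "ARG:397:CG", structure)
        assert np.allclose(ds.distances, ds.distances[0])

    def test_crystal_gate_distance_on_fixture(self, structure):
        t = _traj([[[0.0, 0.0, 20.0]]], ["LIG1:CA"])
        ds = distance_series(t, "SER:277:CA", "PRO:356:CA", structure)
        assert ds.distances[0] == pytest.approx(5.6, abs=1e-9)

    def test_minimum_image_applied(self):
        box = PeriodicBox((10, 10, 10), (True, True, True))
        t = _traj([[[9.0, 0.0, 0.0]]], ["P"], box=box)
        ds = distance_series(t, np.array([1.0, 0.0, 0.0]), "P")
        assert ds.distances[0] == pytest.approx(2.0)

    def test_unresolvable_endpoint_fails_fast(self, structure):
        t = _traj([[[0.0, 0.0, 0.0]]], ["LIG1:CA"])
        with pytest.raises(SelectionError):
            distance_series(t, "GLN:1:CA", "LIG1:CA", structure)


class TestRDF:
    def test_single_fixed_ligand_occupies_one_bin(self):
        coords = np.tile([[3.0, 0.0, 0.0]], (4, 1, 1))
        t = _traj(coords, ["P"])
        res = rdf(t, np.zeros(3), r_max=10.0, bin_width=0.1)
        nz = np.flatnonzero(res.g)
        assert len(nz) == 1
        assert res.edges[nz[0]] <= 3.0 < res.edges[nz[0] + 1]
        assert res.cumulative[-1] == pytest.approx(1.0)

    def test_uniform_sphere_sampling_gives_flat_g(self, rng):
        """Sampling oracle for the normalisation: points uniform in the
        analysis sphere must give g(r) = 1 in every shell."""
        n = 200_000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = 10.0 * rng.random(n) ** (1.0 / 3.0)
        pts = (u * r[:, None])[None, :, :]
        t = _traj(pts, [f"P{i}" for i in range(n)])
        res = rdf(t, np.zeros(3), r_max=10.0, bin_width=0.5)
        # per-shell tolerance = 4 standard errors of the expected count
        expected = n * (res.edges[1:] ** 3 - res.edges[:-1] ** 3) / 10.0**3
        tol = 4.0 / np.sqrt(expected)
        sel = res.centers > 1.0
        assert np.all(np.abs(res.g[sel] - 1.0) < tol[sel])
        # and the sphere-wide mean is pinned tightly
        assert np.average(res.g, weights=expected) == pytest.approx(1.0, abs=0.005)

    def test_cumulative_equals_direct_counting(self, rng):
        pts = rng.uniform(-12, 12, size=(20, 7, 3))
        t = _traj(pts, [f"P{i}" for i in range(7)])
        res = rdf(t, np.zeros(3), r_max=10.0, bin_width=0.25)
        d = np.linalg.norm(pts, axis=2)
        for j, edge in enumerate(res.edges[1:]):
            direct = np.mean(np.sum(d < edge, axis=1))
            # bin-edge ties aside, the running mean count must match exactly
            assert res.cumulative[j] == pytest.approx(direct, abs=1e-12)
        assert np.all(np.diff(res.cumulative) >= 0)
        assert np.all(res.g >= 0)

    def test_empty_neighbourhood(self):
        t = _traj([[[50.0, 50.0, 50.0]]], ["P"])
        res = rdf(t, np.zeros(3), r_max=10.0)
        assert np.all(res.g == 0) and np.all(res.cumulative == 0)

    def test_invalid_parameters(self):
        t = _traj([[[1.0, 0, 0]]], ["P"])
        with pytest.raises(ValueError):
            rdf(t, np.zeros(3), r_max=0.0)
        with pytest.raises(ValueError):
            rdf(t, np.zeros(3), r_max=10.0, bin_width=10.0)


class TestConformers:
    def test_constant_syn_angle(self):
        t = synth_dihedral_trajectory([(10, 70.0)])
        cs = conformer_classify(t)
        assert cs.occupancy == {"syn": 1.0, "anti": 0.0}

    def test_constant_anti_angle(self):
        t = synth_dihedral_trajectory([(10, 180.0)])
        cs = conformer_classify(t)
        assert cs.occupancy == {"syn": 0.0, "anti": 1.0}

    def test_70_30_schedule_counts(self):
        t = synth_dihedral_trajectory([(7, 170.0), (3, 60.0)])
        cs = conformer_classify(t)
        assert cs.occupancy["anti"] == pytest.approx(0.7)
        assert cs.occupancy["syn"] == pytest.approx(0.3)
        assert sum(cs.occupancy.values()) == pytest.approx(1.0)

    def test_occupancy_invariant_under_rigid_motion(self):
        t = synth_dihedral_trajectory([(5, 70.0), (5, -160.0)])
        R = Rotation.from_rotvec([0.4, -0.9, 1.3]).as_matrix()
        moved = _traj(t.coords @ R.T + np.array([10.0, -4.0, 2.0]), t.labels, t.times)
        a = conformer_classify(t).occupancy
        b = conformer_classify(moved).occupancy
        assert a == pytest.approx(b)

    def test_degenerate_frame_labelled_undefined_and_excluded(self):
        t = synth_dihedral_trajectory([(4, 70.0)])
        coords = t.coords.copy()
        coords[1] = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        broken = _traj(coords, t.labels, t.times)
        cs = conformer_classify(broken)
        assert cs.states[1] == "undefined"
        assert cs.occupancy["syn"] == pytest.approx(1.0)

    def test_three_state_windows(self):
        t = synth_dihedral_trajectory([(2, 70.0), (2, 180.0), (1, 120.0)])
        cs = conformer_classify(t, three_state=True)
        assert cs.occupancy == pytest.approx({"syn": 0.4, "anti": 0.4, "other": 0.2})


class TestBindingEvents:
    def _ds(self, values, times=None):
        from bindsteer.analysis import DistanceSeries

        values = np.asarray(values, dtype=float)
        if times is None:
            times = np.arange(len(values), dtype=float)
        return DistanceSeries(np.asarray(times, float), values, "REF", "LIG")

    def test_hand_traced_hysteresis(self):
        evs = detect_binding_events(self._ds([10, 8, 6, 5, 5, 6, 9, 10]),
                                    bind_threshold=7, unbind_threshold=9, dwell=2)
        assert len(evs) == 1
        ev = evs[0]
        assert (ev.start, ev.end, ev.residency) == (2.0, 7.0, 5.0)

    def test_never_bound_empty(self):
        assert detect_binding_events(self._ds([10, 9, 8, 12]), 7, 9, 1) == []

    def test_two_separate_dips_non_overlapping(self):
        evs = detect_binding_events(self._ds([10, 5, 5, 10, 10, 5, 5, 10]),
                                    bind_threshold=7, unbind_threshold=9, dwell=2)
        assert len(evs) == 2
        assert evs[0].end <= evs[1].start
        assert (evs[0].start, evs[1].start) == (1.0, 5.0)

    def test_open_event_closes_at_final_frame(self):
        evs = detect_binding_events(self._ds([10, 5, 5, 5]), 7, 9, 2)
        assert len(evs) == 1 and evs[0].end == 3.0

    def test_reduces_to_threshold_crossing(self, rng):
        d = rng.uniform(3, 12, size=200)
        evs = detect_binding_events(self._ds(d), bind_threshold=7, unbind_threshold=7, dwell=1)
        # reconstruct by plain crossing
        expected = []
        open_t = None
        for i, v in enumerate(d):
            if open_t is None and v < 7:
                open_t = float(i)
            elif open_t is not None and v > 7:
                expected.append((open_t, float(i)))
                open_t = None
        if open_t is not None:
            expected.append((open_t, float(len(d) - 1)))
        assert [(e.start, e.end) for e in evs] == expected

    def test_residency_sum_bounded_by_duration(self, rng):
        d = rng.uniform(3, 12, size=500)
        ds = self._ds(d)
        evs = detect_binding_events(ds, 7, 9, 3)
        assert sum(e.residency for e in evs) <= ds.times[-1] - ds.times[0]

    def test_hysteresis_precondition(self):
        with pytest.raises(ValueError):
            detect_binding_events(self._ds([5.0]), bind_threshold=7, unbind_threshold=5)

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            BindingEvent(start=5.0, end=4.0)


class TestBiasFraction:
    def test_fraction_examples(self):
        assert bias_fraction([True, True] + [False] * 8) == pytest.approx(0.2)
        assert bias_fraction([False] * 5) == 0.0
        assert bias_fraction([True] * 5) == 1.0

    def test_two_dimensional_any_particle(self):
        flags = np.zeros((4, 2), dtype=bool)
        flags[0, 1] = True
        assert bias_fraction(flags) == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bias_fraction(np.zeros((0,), dtype=bool))
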