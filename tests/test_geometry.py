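"""Insertion observables: d_z, events, RMSD, distances, dihedrals, waters,
sodium bridges, and histogram peak detection."""

import numpy as np
import pytest

from lysotraj import geometry as geo
from lysotraj.trajectory import Selection, StructureModel, Trajectory, \
    random_rotation


def simple_traj(coords_per_frame, names=None, resids=None, elements=None):
    frames = np.asarray(coords_per_frame, float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    ref = StructureModel(
        names=names or ["X"] * n,
        elements=elements or ["C"] * n,
        resnames=["UNK"] * n,
        resids=resids if resids is not None else np.arange(1, n + 1),
        chains=["A"] * n,
        coords=frames[0])
    return Trajectory(ref, frames)


class TestDzSeries:
    def test_plain_offset(self):
        traj = simple_traj([[[0, 0, 0], [1, 2, 20.0]]])
        dz = geo.dz_series(traj, Selection.from_indices([1]),
                           Selection.from_indices([0]))
        assert dz[0].values[0] == pytest.approx(20.0)

    def test_coincident_z(self):
        traj = simple_traj([[[5, 5, 7.0], [0, 0, 7.0]]])
        dz = geo.dz_series(traj, Selection.from_indices([1]),
                           Selection.from_indices([0]))
        assert dz[0].values[0] == pytest.approx(0.0)

    def test_ref_must_be_single_atom(self):
        traj = simple_traj([[[0, 0, 0], [0, 0, 1], [0, 0, 2]]])
        with pytest.raises(ValueError, match="exactly 1"):
            geo.dz_series(traj, Selection.from_indices([2]),
                          Selection.from_indices([0, 1]))

    def test_min_reduction(self):
        traj = simple_traj([[[0, 0, 0], [0, 0, 10.0], [0, 0, 4.0]]])
        dz = geo.dz_series(traj, Selection.from_indices([1, 2]),
                           Selection.from_indices([0]))
        assert geo.min_dz_series(dz).values[0] == pytest.approx(4.0)


class TestDetectInsertions:
    def toy(self, insertion_toy):
        gt = insertion_toy["ground_truth"]
        traj = insertion_toy["trajectory"]
        dz = geo.dz_series(traj,
                           Selection.from_indices(gt["lipid_atom_indices"]),
                           Selection.from_indices([gt["ref_atom_index"]]))
        portals = {"TM5/TM8": Selection.from_indices([2, 3]),
                   "TM2/TM11": Selection.from_indices([4, 5])}
        return traj, dz, portals, gt

    def test_reproduces_ground_truth_exactly(self, insertion_toy):
        traj, dz, portals, gt = self.toy(insertion_toy)
        events = geo.detect_insertions(traj, dz, portals)
        assert len(events) == gt["n_events"]
        got = sorted((e.lipid_id, e.entry_frame, e.pathway, e.concomitant)
                     for e in events)
        want = sorted((e["lipid_id"], e["entry_frame"], e["pathway"],
                       e["concomitant"]) for e in gt["events"])
        assert got == want

    def test_grazing_above_threshold_ignored(self):
        # lipid dips to 13.5 A: never crosses the 13 A rule
        F = 60
        z = np.interp(np.arange(F), [0, 30, F - 1], [20.0, 13.5, 20.0])
        frames = np.zeros((F, 4, 3))
        frames[:, 1, 2] = z
        frames[:, 2, :2] = (12, 0)
        frames[:, 3, :2] = (-12, 0)
        traj = simple_traj(frames)
        dz = geo.dz_series(traj, Selection.from_indices([1]),
                           Selection.from_indices([0]))
        events = geo.detect_insertions(
            traj, dz, {"TM5/TM8": Selection.from_indices([2]),
                       "TM2/TM11": Selection.from_indices([3])})
        assert events == []

    def test_hysteresis_debounces_chatter(self):
        # oscillation between 12.5 and 14 A stays one episode (exit needs >15)
        F = 40
        z = np.where(np.arange(F) % 2 == 0, 12.5, 14.0)
        z[-1] = 20.0
        frames = np.zeros((F, 2, 3))
        frames[:, 1, 2] = z
        traj = simple_traj(frames)
        dz = geo.dz_series(traj, Selection.from_indices([1]),
                           Selection.from_indices([0]))
        events = geo.detect_insertions(
            traj, dz, {"TM5/TM8": Selection.from_indices([0])})
        assert len(events) == 1


class TestSubstrateRmsd:
    def make(self, n_prot=10, n_sub=30, seed=0):
        rng = np.random.default_rng(seed)
        prot = rng.uniform(-10, 10, (n_prot, 3))
        sub = rng.uniform(-5, 5, (n_sub, 3))
        return prot, sub

    def test_frame_zero_is_zero(self):
        prot, sub = self.make()
        frames = np.concatenate([prot, sub])[None]
        traj = simple_traj(frames)
        s = geo.substrate_rmsd(traj, Selection.from_indices(range(10, 40)),
                               Selection.from_indices(range(10)))
        assert s.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_displacement(self):
        prot, sub = self.make()
        f0 = np.concatenate([prot, sub])
        f1 = f0.copy()
        f1[10:] += np.array([2.0, 0, 0])
        traj = simple_traj(np.stack([f0, f1]))
        s = geo.substrate_rmsd(traj, Selection.from_indices(range(10, 40)),
                               Selection.from_indices(range(10)))
        assert s.values[1] == pytest.approx(2.0, abs=1e-9)

    def test_random_perturbation_expectation(self):
        # i.i.d. N(0, sigma^2) per coordinate: mean RMSD ~ sigma * sqrt(3)
        prot, sub = self.make(n_sub=2000)
        sigma = 0.8
        rng = np.random.default_rng(1)
        f0 = np.concatenate([prot, sub])
        f1 = f0.copy()
        f1[10:] += rng.normal(0, sigma, (2000, 3))
        traj = simple_traj(np.stack([f0, f1]))
        s = geo.substrate_rmsd(traj, Selection.from_indices(range(10, 2010)),
                               Selection.from_indices(range(10)))
        assert s.values[1] == pytest.approx(sigma * np.sqrt(3), rel=0.03)

    def test_hydrogens_rejected(self):
        traj = simple_traj(np.zeros((1, 4, 3)),
                           elements=["C", "C", "C", "H"])
        with pytest.raises(ValueError, match="hydrogens"):
            geo.substrate_rmsd(traj, Selection.from_indices([3]),
                               Selection.from_indices([0, 1, 2]))


class TestDistanceSeries:
    def test_three_four_five(self):
        traj = simple_traj([[[0, 0, 0], [3, 4, 0]]])
        d = geo.distance_series(traj, Selection.from_indices([0]),
                                Selection.from_indices([1]))
        assert d.values[0] == pytest.approx(5.0)

    def test_min_mode_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            frame = rng.uniform(-10, 10, (12, 3))
            traj = simple_traj(frame[None])
            a = Selection.from_indices(range(5))
            b = Selection.from_indices(range(5, 12))
            got = geo.distance_series(traj, a, b, mode="min").values[0]
            brute = min(np.linalg.norm(frame[i] - frame[j])
                        for i in range(5) for j in range(5, 12))
            assert got == pytest.approx(brute, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        frame = rng.uniform(-10, 10, (8, 3))
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        a = Selection.from_indices(range(4))
        b = Selection.from_indices(range(4, 8))
        for mode in ("min", "centroid"):
            d0 = geo.distance_series(simple_traj(frame[None]), a, b, mode)
            d1 = geo.distance_series(simple_traj((frame @ R.T + t)[None]),
                                     a, b, mode)
            assert d0.values[0] == pytest.approx(d1.values[0], abs=1e-9)


class TestDihedralSeries:
    def test_planar_cis_zero(self):
        coords = [[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]]
        traj = simple_traj([coords])
        d = geo.dihedral_series(traj, Selection.from_indices(range(4)))
        assert d.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_180(self):
        coords = [[1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]]
        traj = simple_traj([coords])
        d = geo.dihedral_series(traj, Selection.from_indices(range(4)))
        assert abs(d.values[0]) == pytest.approx(180.0, abs=1e-9)

    @staticmethod
    def _brute_force(p0, p1, p2, p3):
        # independent reference: project the outer bonds onto the plane
        # normal to the central bond and take the signed angle between them
        b0, b1, b2 = -(p1 - p0), p2 - p1, p3 - p2
        b1 = b1 / np.linalg.norm(b1)
        v = b0 - (b0 @ b1) * b1
        w = b2 - (b2 @ b1) * b1
        return np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(-5, 5, (40, 4, 3))
        traj = simple_traj(pts)
        got = geo.dihedral_series(traj, Selection.from_indices(range(4)))
        want = [self._brute_force(*f) for f in pts]
        np.testing.assert_allclose(got.values, want, atol=1e-6)

    def test_matches_mdanalysis_convention(self):
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(10)
        pts = rng.uniform(-5, 5, (40, 4, 3))
        traj = simple_traj(pts)
        got = geo.dihedral_series(traj, Selection.from_indices(range(4)))
        want = np.degrees(calc_dihedrals(pts[:, 0], pts[:, 1], pts[:, 2],
                                         pts[:, 3]))
        np.testing.assert_allclose(got.values, want, atol=1e-3)

    def test_collinear_rejected(self):
        coords = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]
        traj = simple_traj([coords])
        with pytest.raises(geo.UndefinedDihedralError):
            geo.dihedral_series(traj, Selection.from_indices(range(4)))


class TestWaterCounting:
    def test_no_waters_near(self):
        frames = np.zeros((1, 3, 3))
        frames[0, 1] = (50, 0, 0)
        frames[0, 2] = (60, 0, 0)
        traj = simple_traj(frames, resids=[1, 2, 3])
        c = geo.count_vestibule_waters(traj, Selection.from_indices([1, 2]),
                                       Selection.from_indices([0]))
        assert c.values[0] == 0

    def test_scripted_shell_count(self, insertion_toy):
        gt = insertion_toy["ground_truth"]
        traj = insertion_toy["trajectory"]
        c = geo.count_vestibule_waters(
            traj, Selection.from_indices(gt["water_atom_indices"]),
            Selection.from_indices(gt["shell_atom_indices"]))
        np.testing.assert_array_equal(c.values, gt["water_counts"])

    def test_tree_equals_naive(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            n_w, n_s = 40, 8
            frames = rng.uniform(-8, 8, (3, n_w + n_s, 3))
            resids = list(range(1, n_s + 1)) + \
                [n_s + 1 + k // 2 for k in range(n_w)]  # 2 atoms per water
            traj = simple_traj(frames, resids=resids)
            w = Selection.from_indices(range(n_s, n_s + n_w))
            s = Selection.from_indices(range(n_s))
            a = geo.count_vestibule_waters(traj, w, s, method="tree")
            b = geo.count_vestibule_waters(traj, w, s, method="naive")
            np.testing.assert_array_equal(a.values, b.values)


class TestNaBridge:
    def build(self, na_d, p_d):
        # carboxyl C at origin; Na on x; P on y
        frames = np.zeros((len(na_d), 3, 3))
        frames[:, 1, 0] = na_d
        frames[:, 2, 1] = p_d
        return simple_traj(frames)

    def test_bridge_geometry(self):
        traj = self.build([2.3], [5.0])
        series, s = geo.na_bridge_series(
            traj, Selection.from_indices([0]), Selection.from_indices([1]),
            Selection.from_indices([2]))
        assert series["bridge"].values[0] == 1
        assert s["bridge_fraction"] == 1.0

    def test_distant_na_no_bridge(self):
        traj = self.build([4.0], [3.0])
        series, s = geo.na_bridge_series(
            traj, Selection.from_indices([0]), Selection.from_indices([1]),
            Selection.from_indices([2]))
        assert series["bridge"].values[0] == 0

    def test_toy_fractions(self, insertion_toy):
        gt = insertion_toy["ground_truth"]
        traj = insertion_toy["trajectory"]
        series, s = geo.na_bridge_series(
            traj, Selection.from_indices([gt["carboxyl_atom_index"]]),
            Selection.from_indices([gt["na_atom_index"]]),
            Selection.from_indices(gt["lipid_atom_indices"]))
        np.testing.assert_array_equal(series["bridge"].values,
                                      gt["bridge_frames"])
        expected = gt["bridge_frames"].mean()
        assert s["bridge_fraction"] == pytest.approx(expected)


class TestHistogram:
    def test_single_value(self):
        h = geo.histogram([2.0] * 10, bin_width=0.5)
        assert h.counts.sum() == 10
        assert (h.counts > 0).sum() == 1
        assert len(h.peaks) >= 1

    def test_bimodal_peaks(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(2.5, 0.1, 4000),
                               rng.normal(3.5, 0.1, 3000)])
        h = geo.histogram(vals, bin_width=0.1)
        assert h.counts.sum() == 7000
        top2 = sorted(h.peaks[:2])
        assert abs(top2[0] - 2.5) <= 0.1
        assert abs(top2[1] - 3.5) <= 0.1

    def test_counts_conserved(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 2, 500)
        h = geo.histogram(vals, bin_width=0.25)
        assert h.counts.sum() == 500

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            geo.histogram([])
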