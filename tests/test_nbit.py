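"""Gaussian information quantities against closed forms and brute-force
oracles; Fisher-Jenks against exhaustive enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lysotraj import nbit
from lysotraj import synthetic as syn
from lysotraj.trajectory import Selection, Trajectory, random_rotation

LN2PIE = np.log(2 * np.pi * np.e)


def random_spd(dim, seed, strength=None):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(dim, dim))
    return A @ A.T + (strength if strength is not None else dim) * np.eye(dim)


# --- independent oracle: every quantity from explicit log-determinants -----

def oracle_entropy(C):
    sign, logdet = np.linalg.slogdet(np.atleast_2d(C))
    d = np.atleast_2d(C).shape[0]
    return 0.5 * (d * LN2PIE + logdet)


def oracle_tc(C, blocks):
    allidx = np.concatenate([np.asarray(b, int) for b in blocks])
    h = sum(oracle_entropy(C[np.ix_(b, b)]) for b in blocks)
    return h - oracle_entropy(C[np.ix_(allidx, allidx)])


def oracle_cond_cov(C, keep, cond):
    Caa = C[np.ix_(keep, keep)]
    Cab = C[np.ix_(keep, cond)]
    Cbb = C[np.ix_(cond, cond)]
    return Caa - Cab @ np.linalg.inv(Cbb) @ Cab.T


def oracle_ci(C, blocks, cond):
    allidx = np.concatenate([np.asarray(b, int) for b in blocks])
    Cc = oracle_cond_cov(C, allidx, np.asarray(cond, int))
    pos = {g: i for i, g in enumerate(allidx)}
    sub = [[pos[g] for g in b] for b in blocks]
    return oracle_tc(C, blocks) - oracle_tc(Cc, sub)


class TestEntropy:
    def test_one_dimensional_unit_variance(self):
        assert nbit.entropy(np.array([[1.0]])) == pytest.approx(0.5 * LN2PIE,
                                                                abs=1e-12)

    @pytest.mark.parametrize("d", [2, 5, 9])
    def test_identity_covariance(self, d):
        assert nbit.entropy(np.eye(d)) == pytest.approx(d * 0.5 * LN2PIE,
                                                        abs=1e-12)

    def test_correlated_pair_closed_form(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        want = LN2PIE + 0.5 * np.log(0.75)
        assert nbit.entropy(C) == pytest.approx(want, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            nbit.entropy(np.array([[np.nan]]))

    def test_eigenvalue_floor_applied(self):
        # zero matrix: floored eigenvalues keep the entropy finite
        h = nbit.entropy(np.zeros((3, 3)))
        assert np.isfinite(h)
        assert h == pytest.approx(3 * 0.5 * (LN2PIE + np.log(1e-8)), rel=1e-9)


class TestTotalCorrelation:
    def test_block_diagonal_is_zero(self):
        C = np.eye(6)
        C[0, 1] = C[1, 0] = 0.4   # within-block correlation only
        tc = nbit.total_correlation(C, [[0, 1], [2, 3], [4, 5]])
        assert tc == pytest.approx(0.0, abs=1e-9)

    def test_correlated_pair_closed_form(self):
        rho = 0.6
        C = np.array([[1.0, rho], [rho, 1.0]])
        assert nbit.total_correlation(C, [[0], [1]]) == pytest.approx(
            -0.5 * np.log(1 - rho ** 2), abs=1e-12)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            nbit.total_correlation(np.eye(4), [[0, 1], [1, 2]])

    @pytest.mark.parametrize("seed", range(20))
    def test_nonnegative_on_random_spd(self, seed):
        C = random_spd(6, seed)
        tc = nbit.total_correlation(C, [[0, 1], [2, 3], [4, 5]])
        assert tc >= -1e-9


class TestCoordinationInformation:
    def test_independent_conditioner_gives_zero(self):
        C = np.eye(8)
        C[0, 2] = C[2, 0] = 0.5   # receiver-internal coupling only
        ci = nbit.coordination_information(C, [[0, 1], [2, 3]], [4, 5])
        assert ci == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        C = random_spd(9, seed)
        blocks = [[0, 1], [2, 3]]
        cond = [6, 7, 8]
        got = nbit.coordination_information(C, blocks, cond)
        want = oracle_ci(C, blocks, cond)
        assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_ci_bounded_by_receiver_tc(self, seed):
        C = random_spd(8, seed)
        blocks = [[0, 1], [2, 3]]
        ci = nbit.coordination_information(C, blocks, [5, 6])
        tc = nbit.total_correlation(C, blocks)
        assert ci <= tc + 1e-9

    def test_overlap_with_receiver_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            nbit.coordination_information(np.eye(6), [[0, 1]], [1, 2])

    def test_normalized_percentage(self):
        C = random_spd(6, 3)
        ci, pct = nbit.coordination_information(C, [[0], [1]], [4, 5],
                                                normalized=True)
        tc = nbit.total_correlation(C, [[0], [1]])
        assert pct == pytest.approx(100 * ci / tc, rel=1e-9)


class TestMCI:
    def test_identity_same_site(self):
        C = random_spd(9, 1)
        blocks = [[0, 1], [2, 3]]
        m = [6, 7]
        ci = nbit.coordination_information(C, blocks, m)
        mci = nbit.mutual_coordination_information(C, blocks, m, m)
        assert mci == pytest.approx(ci, abs=1e-10)

    def test_independent_channel_zero(self):
        dim = 10
        C = np.eye(dim)
        C[0, 2] = C[2, 0] = 0.3
        C[0, 6] = C[6, 0] = 0.4   # transmitter coupled to receiver
        # channel coords 8, 9 independent of everything
        mci = nbit.mutual_coordination_information(C, [[0, 1], [2, 3]],
                                                   [6, 7], [8, 9])
        assert mci == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        C = random_spd(10, seed)
        blocks = [[0, 1], [2, 3]]
        m, n = [5, 6], [8, 9]
        want = (oracle_ci(C, blocks, m) + oracle_ci(C, blocks, n)
                - oracle_ci(C, blocks, m + n))
        got = nbit.mutual_coordination_information(C, blocks, m, n)
        assert got == pytest.approx(want, abs=1e-6)


class TestChannelScan:
    def shared_driver_cov(self):
        # hidden driver couples transmitter coords (4,5), receiver (0..3),
        # and channel A (6,7); channel B (8,9) is independent
        rng = np.random.default_rng(0)
        dim = 10
        load = np.zeros(dim)
        for i in (0, 1, 2, 3, 4, 5, 6, 7):
            load[i] = 0.8
        C = np.outer(load, load) + np.eye(dim)
        return C

    def test_planted_channel_ranks_first(self):
        C = self.shared_driver_cov()
        rows = nbit.mci_channel_scan(C, [[0, 1], [2, 3]], [4, 5],
                                     {"planted": [6, 7], "inert": [8, 9]})
        assert rows[0][0] == "planted"
        assert rows[0][1] > rows[1][1]

    def test_independent_channels_near_zero(self):
        C = self.shared_driver_cov()
        rows = dict(nbit.mci_channel_scan(C, [[0, 1], [2, 3]], [4, 5],
                                          {"inert": [8, 9]}))
        assert abs(rows["inert"]) < 1e-6

    def test_table_length_and_disjointness(self):
        C = self.shared_driver_cov()
        rows = nbit.mci_channel_scan(C, [[0, 1]], [4, 5],
                                     {"a": [6], "b": [7], "c": [8]})
        assert len(rows) == 3
        with pytest.raises(ValueError, match="overlap"):
            nbit.mci_channel_scan(C, [[0, 1]], [4, 5], {"bad": [0]})


class TestCovarianceEstimation:
    def test_single_frame_rejected(self):
        spec = syn.SyntheticSpec(kind="coupled_sites", n_frames=1, seed=0,
                                 params={"covariance": np.eye(6)})
        traj, _ = syn.make_coupled_site_ensemble(spec)
        with pytest.raises(ValueError, match="one frame"):
            nbit.covariance(traj, Selection.from_indices([0, 1]))

    def test_identical_frames_zero_covariance(self):
        spec = syn.SyntheticSpec(kind="coupled_sites", n_frames=5, seed=0,
                                 params={"covariance": np.eye(6)})
        traj, _ = syn.make_coupled_site_ensemble(spec)
        frozen = Trajectory(traj.reference,
                            np.repeat(traj.frames[:1], 5, axis=0))
        cov = nbit.covariance(frozen, Selection.from_indices([0, 1]))
        np.testing.assert_allclose(cov.C, 0.0, atol=1e-12)

    def test_marginal_block_consistency(self):
        spec = syn.SyntheticSpec(kind="coupled_sites", n_frames=200, seed=3,
                                 params={"covariance": random_spd(9, 5, 2.0)})
        traj, _ = syn.make_coupled_site_ensemble(spec)
        full = nbit.covariance(traj, Selection.from_indices([0, 1, 2]))
        sub = nbit.covariance(traj, Selection.from_indices([0, 2]))
        idx = full.coord_indices([0, 2])
        np.testing.assert_allclose(full.C[np.ix_(idx, idx)], sub.C,
                                   atol=1e-10)

    def test_estimated_ci_converges_to_planted(self):
        C = syn.coupled_blocks_covariance(3, 1, cross_corr=0.5,
                                          coupled_pairs=[(0, 1), (0, 2)])
        rec = [list(range(3, 6)), list(range(6, 9))]
        trans = list(range(0, 3))
        truth = nbit.coordination_information(C, rec, trans)
        errs = []
        for n in (2_000, 32_000):
            spec = syn.SyntheticSpec(kind="coupled_sites", n_frames=n, seed=8,
                                     params={"covariance": C})
            traj, _ = syn.make_coupled_site_ensemble(spec)
            cov = nbit.covariance(traj, Selection.from_indices(range(3)))
            est = nbit.coordination_information(cov.C, rec, trans)
            errs.append(abs(est - truth))
        assert errs[1] < errs[0]

    def test_ci_invariant_under_global_rotation(self):
        C = syn.coupled_blocks_covariance(3, 2, cross_corr=0.4)
        spec = syn.SyntheticSpec(kind="coupled_sites", n_frames=4000, seed=9,
                                 params={"covariance": C})
        traj, _ = syn.make_coupled_site_ensemble(spec)
        sel = Selection.from_indices(range(6))
        rec = [list(range(6, 12)), list(range(12, 18))]
        trans = list(range(6))
        cov0 = nbit.covariance(traj, sel_all := Selection.from_indices(range(6)),
                               superpose_on=sel_all)
        # rotate every frame rigidly, then remove the motion by superposition
        rng = np.random.default_rng(4)
        R = random_rotation(rng)
        rot = Trajectory(traj.reference, traj.frames @ R.T)
        cov1 = nbit.covariance(rot, sel_all, superpose_on=sel_all)
        ci0 = nbit.coordination_information(cov0.C, [rec[0][:3]], trans[:3])
        ci1 = nbit.coordination_information(cov1.C, [rec[0][:3]], trans[:3])
        assert ci0 == pytest.approx(ci1, abs=1e-6)


# ---------------------------------------------------------------------------

def brute_force_jenks(x, k):
    """Exhaustive search over all placements of k-1 breaks in sorted data."""
    x = np.sort(np.asarray(x, float))
    n = len(x)

    def ssd(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best, best_labels = np.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        total = sum(ssd(x[bounds[i]:bounds[i + 1]]) for i in range(k))
        if total < best - 1e-12:
            best = total
            lab = np.empty(n, int)
            for i in range(k):
                lab[bounds[i]:bounds[i + 1]] = i
            best_labels = lab
    return best, best_labels


class TestFisherJenks:
    def test_separated_clusters(self):
        vals = [1, 2, 3, 10, 11, 12, 100, 101, 102]
        _, labels = nbit.fisher_jenks(vals, k=3)
        assert list(labels) == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 13)
        x = np.sort(rng.uniform(0, 50, n))
        _, labels = nbit.fisher_jenks(x, k=3)
        best_cost, want = brute_force_jenks(x, 3)

        def cost(lab):
            return sum(((x[lab == c] - x[lab == c].mean()) ** 2).sum()
                       for c in np.unique(lab))

        assert cost(labels) == pytest.approx(best_cost, abs=1e-9)

    def test_k_exceeds_n_rejected(self):
        with pytest.raises(ValueError):
            nbit.fisher_jenks([1.0, 2.0], k=3)

    def test_fixed_threshold_mode(self):
        assert nbit.fixed_threshold_labels([14, 20, 30]) == \
            ["low", "average", "high"]
        # boundary values belong to the middle class
        assert nbit.fixed_threshold_labels([15, 28]) == ["average", "average"]

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=3,
                    max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_property_optimal_cost(self, vals):
        x = np.asarray(vals)
        _, labels = nbit.fisher_jenks(x, k=3)
        best_cost, _ = brute_force_jenks(x, 3)
        # compare costs via the label partition on the original ordering
        cost = 0.0
        for c in np.unique(labels):
            seg = x[labels == c]
            cost += ((seg - seg.mean()) ** 2).sum()
        assert cost <= best_cost + 1e-7
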