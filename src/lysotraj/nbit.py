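"""Gaussian configurational-entropy allostery analysis (NbIT).

From the covariance matrix C of atomic positions X (rigid-body motion
removed by prior superposition), the configurational entropy of a set is

    H(X) = 1/2 ln |2 pi e C(X)|     (nats)

Total correlation over a partition X_1..X_N is TC = sum_i H(X_i) - H(joint).
Coordination information between a receiver partition and a transmitter
site X_m is the drop in receiver TC upon conditioning:
CI = TC(X_1..X_N) - TC(X_1..X_N | X_m), with conditional covariances via the
Schur complement. Mutual coordination information through a channel site is
MCI(.|X_m, X_n) = CI(.|X_m) + CI(.|X_n) - CI(.|{X_m, X_n}).

CI is also reported normalized as a percentage of the receiver TC, and
normalized CI values are grouped into low/average/high coordination classes
either by exact Fisher-Jenks natural breaks or by the fixed 15% / 28%
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Selection, Trajectory, superpose

__all__ = [
    "CovarianceModel",
    "SiteDefinition",
    "covariance",
    "entropy",
    "total_correlation",
    "coordination_information",
    "mutual_coordination_information",
    "mci_channel_scan",
    "fisher_jenks",
    "fixed_threshold_labels",
    "EIG_FLOOR",
]

EIG_FLOOR = 1e-8   # A^2: eigenvalue floor; superposition leaves near-singular
                   # rigid-body directions and the log-determinant must be finite
CI_LOW_THRESHOLD = 15.0   # %: below this, "low" coordination
CI_HIGH_THRESHOLD = 28.0  # %: above this, "high" coordination


@dataclass
class SiteDefinition:
    """A named atom set acting as transmitter, receiver or channel."""

    name: str
    atom_indices: np.ndarray
    role: str = "receiver"

    def __post_init__(self):
        self.atom_indices = np.unique(np.asarray(self.atom_indices, int))
        if self.atom_indices.size == 0:
            raise ValueError(f"site {self.name!r} is empty")


@dataclass
class CovarianceModel:
    """Sample covariance of stacked (x,y,z) coordinates of selected atoms."""

    atom_indices: np.ndarray    # atoms of the model, in covariance order
    C: np.ndarray               # (3N, 3N), A^2
    n_frames: int = 0
    eig_floor: float = EIG_FLOOR

    def __post_init__(self):
        self.C = np.asarray(self.C, float)
        self.atom_indices = np.asarray(self.atom_indices, int)
        if self.C.shape != (3 * len(self.atom_indices),) * 2:
            raise ValueError("covariance shape does not match atom count")

    def coord_indices(self, atom_subset) -> np.ndarray:
        """Covariance row/col indices for a subset of *model* atom indices."""
        pos = {a: i for i, a in enumerate(self.atom_indices)}
        out = []
        for a in np.asarray(atom_subset, int):
            if a not in pos:
                raise KeyError(f"atom {a} not in covariance model")
            i = pos[a]
            out.extend((3 * i, 3 * i + 1, 3 * i + 2))
        return np.asarray(out, int)


def covariance(traj: Trajectory, selection: Selection,
               superpose_on: Selection | None = None) -> CovarianceModel:
    """Unbiased sample covariance of atomic positions.

    When `superpose_on` is given, frames are first least-squares fitted on
    that selection to remove rigid-body motion (required for meaningful
    configurational entropies).
    """
    if traj.n_frames < 2:
        raise ValueError("covariance requires more than one frame")
    work = superpose(traj, superpose_on, 0) if superpose_on is not None else traj
    X = work.frames[:, selection.indices].reshape(work.n_frames, -1)
    C = np.cov(X, rowvar=False, bias=False)
    C = np.atleast_2d(C)
    return CovarianceModel(selection.indices.copy(), C, n_frames=work.n_frames)


def _floored_eigvals(C: np.ndarray, floor: float) -> np.ndarray:
    vals = np.linalg.eigvalsh((C + C.T) / 2)
    return np.maximum(vals, floor)


def entropy(C: np.ndarray, eig_floor: float = EIG_FLOOR) -> float:
    """Gaussian configurational entropy H = 1/2 ln|2 pi e C| in nats."""
    C = np.atleast_2d(np.asarray(C, float))
    if not np.isfinite(C).all():
        raise ValueError("covariance contains non-finite entries")
    lam = _floored_eigvals(C, eig_floor)
    return float(0.5 * np.sum(np.log(2 * np.pi * np.e * lam)))


def _check_partition(blocks):
    seen = set()
    for b in blocks:
        s = set(np.asarray(b, int).tolist())
        if seen & s:
            raise ValueError("partition blocks overlap")
        seen |= s
    return seen


def total_correlation(C: np.ndarray, blocks: list[np.ndarray],
                      eig_floor: float = EIG_FLOOR) -> float:
    """TC of a partition: sum of marginal entropies minus the joint entropy.

    `blocks` are disjoint lists of row/col indices into C; the joint is their
    union.
    """
    C = np.asarray(C, float)
    _check_partition(blocks)
    allidx = np.concatenate([np.asarray(b, int) for b in blocks])
    h_joint = entropy(C[np.ix_(allidx, allidx)], eig_floor)
    h_marg = sum(entropy(C[np.ix_(b, b)], eig_floor)
                 for b in (np.asarray(b, int) for b in blocks))
    return float(h_marg - h_joint)


def conditional_covariance(C: np.ndarray, keep: np.ndarray,
                           cond: np.ndarray) -> np.ndarray:
    """Schur complement C_AA - C_AB C_BB^-1 C_BA (pseudo-inverse fallback)."""
    keep = np.asarray(keep, int)
    cond = np.asarray(cond, int)
    Caa = C[np.ix_(keep, keep)]
    Cab = C[np.ix_(keep, cond)]
    Cbb = C[np.ix_(cond, cond)]
    try:
        sol = np.linalg.solve(Cbb, Cab.T)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(Cbb, rcond=1e-10) @ Cab.T
    return Caa - Cab @ sol


def _conditional_tc(C, blocks, cond, eig_floor):
    blocks = [np.asarray(b, int) for b in blocks]
    allidx = np.concatenate(blocks)
    Cc = conditional_covariance(C, allidx, cond)
    # index positions of each block inside the conditioned matrix
    pos = {g: i for i, g in enumerate(allidx)}
    sub_blocks = [np.asarray([pos[g] for g in b], int) for b in blocks]
    return total_correlation(Cc, sub_blocks, eig_floor)


def coordination_information(C: np.ndarray, receiver_blocks: list,
                             cond: np.ndarray,
                             eig_floor: float = EIG_FLOOR,
                             normalized: bool = False):
    """CI of a receiver partition given a conditioning (transmitter) site.

    CI = TC(receiver) - TC(receiver | X_m). With `normalized=True` also
    returns 100 * CI / TC(receiver) (percent of the receiver's total
    correlation explained by the transmitter).
    """
    cond = np.asarray(cond, int)
    rec_set = _check_partition(receiver_blocks)
    if rec_set & set(cond.tolist()):
        raise ValueError("conditioning site overlaps the receiver blocks")
    tc = total_correlation(C, receiver_blocks, eig_floor)
    tc_cond = _conditional_tc(C, receiver_blocks, cond, eig_floor)
    ci = float(tc - tc_cond)
    if not normalized:
        return ci
    pct = float(100.0 * ci / tc) if tc > 0 else float("nan")
    return ci, pct


def mutual_coordination_information(C: np.ndarray, receiver_blocks: list,
                                    cond_m: np.ndarray, cond_n: np.ndarray,
                                    eig_floor: float = EIG_FLOOR) -> float:
    """MCI(.|X_m, X_n) = CI(.|X_m) + CI(.|X_n) - CI(.|{X_m, X_n})."""
    cond_m = np.asarray(cond_m, int)
    cond_n = np.asarray(cond_n, int)
    ci_m = coordination_information(C, receiver_blocks, cond_m, eig_floor)
    ci_n = coordination_information(C, receiver_blocks, cond_n, eig_floor)
    both = np.unique(np.concatenate([cond_m, cond_n]))
    ci_mn = coordination_information(C, receiver_blocks, both, eig_floor)
    return float(ci_m + ci_n - ci_mn)


def mci_channel_scan(C: np.ndarray, receiver_blocks: list,
                     transmitter: np.ndarray,
                     channels: dict[str, np.ndarray],
                     eig_floor: float = EIG_FLOOR) -> list[tuple[str, float]]:
    """MCI through each candidate channel site, ranked descending.

    Candidates must be disjoint from both the transmitter and the receiver.
    """
    rec_set = _check_partition(receiver_blocks)
    t_set = set(np.asarray(transmitter, int).tolist())
    rows = []
    for name, ch in channels.items():
        ch = np.asarray(ch, int)
        if set(ch.tolist()) & (rec_set | t_set):
            raise ValueError(f"channel {name!r} overlaps transmitter/receiver")
        mci = mutual_coordination_information(C, receiver_blocks, transmitter,
                                              ch, eig_floor)
        rows.append((name, mci))
    rows.sort(key=lambda r: -r[1])
    return rows


# ---------------------------------------------------------------------------
# Natural-breaks clustering of normalized CI values

def fisher_jenks(values, k: int = 3):
    """Exact Fisher-Jenks natural breaks by dynamic programming.

    Minimizes the total within-class sum of squared deviations over all ways
    to cut the sorted values into k contiguous classes. Returns
    (break_upper_bounds, labels) where labels[i] is the class (0..k-1, by
    ascending value) of values[i]; with k=3 the classes are also mapped to
    the names "low", "average", "high".
    """
    values = np.asarray(values, float).ravel()
    n = len(values)
    if k > n:
        raise ValueError(f"k={k} exceeds number of values {n}")
    order = np.argsort(values, kind="stable")
    x = values[order]

    # prefix sums for O(1) within-class SSD
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i, j):  # inclusive sorted-index range [i, j]
        m = j - i + 1
        s = cs[j + 1] - cs[i]
        return (cs2[j + 1] - cs2[i]) - s * s / m

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j - 1)
                if v < best:
                    best, arg = v, i
            cost[c, j] = best
            cut[c, j] = arg
    # recover class boundaries (sorted-index start of each class)
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = cut[c, j]
        bounds.append(j)
    bounds = bounds[::-1]  # [0, b1, ..., n]
    labels_sorted = np.empty(n, dtype=int)
    for c in range(k):
        labels_sorted[bounds[c]:bounds[c + 1]] = c
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    breaks = np.array([x[b - 1] for b in bounds[1:]])  # upper bound per class
    return breaks, labels


JENKS_CLASS_NAMES = {0: "low", 1: "average", 2: "high"}


def fixed_threshold_labels(values, low: float = CI_LOW_THRESHOLD,
                           high: float = CI_HIGH_THRESHOLD) -> list[str]:
    """Label normalized CI values as low (< low), average, or high (> high)."""
    out = []
    for v in np.asarray(values, float).ravel():
        if v < low:
            out.append("low")
        elif v > high:
            out.append("high")
        else:
            out.append("average")
    return out
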