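"""Proline kink-angle analysis and HOLE-style pore profiling.

The kink angle is the angle between helix-axis directions fitted to the
segments flanking a kink residue (principal direction of the centered CA
coordinates, oriented N->C, with the kink residue +-1 excluded from both
fits to avoid the distorted turn). The pore profiler slides a plane along
the +z membrane normal and, at each station, finds the in-plane center of
the largest sphere touching no atom — radius = min over atoms of
|center - atom| - vdw — by seeded simulated annealing refined with a local
simplex search, initialized from the previous station's center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import HistogramSummary, histogram
from .trajectory import Selection, StructureModel, Trajectory

__all__ = [
    "KinkSeries",
    "PoreProfile",
    "helix_axis",
    "kink_angle",
    "kink_series",
    "pore_profile",
    "pore_direction",
    "pore_divergence",
    "radius_distribution",
]

BULK_RADIUS_CUTOFF = 10.0   # A: profile ends where the pore opens to bulk
PORE_STEP = 0.25            # A: station spacing along z


@dataclass
class KinkSeries:
    kink_resid: int
    values: np.ndarray          # degrees, per frame
    pre_resids: np.ndarray
    post_resids: np.ndarray


@dataclass
class PoreProfile:
    z: np.ndarray               # station coordinates (A)
    radius: np.ndarray          # largest-sphere radius per station (A)
    centers: np.ndarray         # (S, 3) sphere centers
    frame: int = 0

    def min_radius(self):
        i = int(np.argmin(self.radius))
        return float(self.radius[i]), float(self.z[i])


def _svd_axis(ca: np.ndarray) -> np.ndarray:
    centered = ca - ca.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    return Vt[0]


def helix_axis(ca_coords: np.ndarray) -> np.ndarray:
    """Helix axis of a CA trace, oriented N->C.

    Uses the successive-bisector construction: with chord vectors
    d_i = p_{i+1} - p_i, the second differences s_i = d_{i+1} - d_i point
    from the helix surface toward the axis, and cross(s_i, s_{i+1}) is
    exactly parallel to the axis for an ideal helix of any length >= 4
    residues — unlike a principal-component fit, which is biased by a
    fraction of a turn left over at the segment ends. The estimates are
    averaged; a degenerate (near-straight) trace falls back to the
    principal direction.
    """
    ca = np.asarray(ca_coords, float)
    if len(ca) < 4:
        raise ValueError(f"need >=4 CA atoms to fit a helix axis, got {len(ca)}")
    d = np.diff(ca, axis=0)
    s = np.diff(d, axis=0)
    crosses = np.cross(s[:-1], s[1:])
    norms = np.linalg.norm(crosses, axis=1)
    chord = ca[-1] - ca[0]
    good = norms > 1e-8
    if good.any():
        units = crosses[good] / norms[good, None]
        signs = np.where(units @ chord < 0, -1.0, 1.0)
        axis = (units * signs[:, None]).mean(axis=0)
    else:
        axis = _svd_axis(ca)
    if axis @ chord < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _flank_indices(resids: np.ndarray, kink_resid: int, gap: int = 1):
    pre = np.flatnonzero(resids < kink_resid - gap)
    post = np.flatnonzero(resids > kink_resid + gap)
    if len(pre) < 4 or len(post) < 4:
        raise ValueError(
            f"segments flanking residue {kink_resid} too short "
            f"({len(pre)}/{len(post)} CA atoms; need >=4 each)")
    return pre, post


def kink_angle(coords: np.ndarray, resids: np.ndarray, kink_resid: int,
               gap: int = 1) -> float:
    """Angle (degrees) between helix axes flanking `kink_resid`.

    `coords`/`resids` are the CA trace of the helix in N->C order; the kink
    residue and `gap` neighbours on each side are excluded from both axis
    fits.
    """
    pre, post = _flank_indices(np.asarray(resids, int), kink_resid, gap)
    a1 = helix_axis(coords[pre])
    a2 = helix_axis(coords[post])
    c = np.clip(a1 @ a2, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def kink_series(traj: Trajectory, helix: Selection, kink_resid: int,
                gap: int = 1) -> KinkSeries:
    """Per-frame kink angle for the CA atoms in `helix`."""
    idx = helix.indices
    resids = traj.reference.resids[idx]
    order = np.argsort(resids, kind="stable")
    idx, resids = idx[order], resids[order]
    pre, post = _flank_indices(resids, kink_resid, gap)
    vals = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        ca = frame[idx]
        a1, a2 = helix_axis(ca[pre]), helix_axis(ca[post])
        vals[f] = np.degrees(np.arccos(np.clip(a1 @ a2, -1.0, 1.0)))
    return KinkSeries(kink_resid, vals, resids[pre], resids[post])


# ---------------------------------------------------------------------------
# Pore profiling

class PoreStartError(RuntimeError):
    """The start point is not inside an open cavity."""


def _station_radius(cxy, z, coords, vdw):
    c = np.array([cxy[0], cxy[1], z])
    d = np.linalg.norm(coords - c[None], axis=1) - vdw
    return float(d.min())


def _optimize_center(xy0, z, coords, vdw, rng, n_anneal=120, t0=0.5,
                     step0=0.8, max_shift=2.5):
    """Maximize the station radius over the in-plane center.

    Seeded simulated annealing (2-D moves only, pore axis fixed along z per
    convention) followed by a Nelder-Mead polish. The search is confined to
    a disk of `max_shift` around the previous station's center: outside the
    atom cloud the largest-sphere objective is unbounded, so the walker must
    track the cavity rather than escape it.
    """
    x0 = np.asarray(xy0, float)

    def f(p):
        if np.linalg.norm(p - x0) > max_shift:
            return -np.inf
        return _station_radius(p, z, coords, vdw)

    x = x0.copy()
    fx = _station_radius(x, z, coords, vdw)
    best, fbest = x.copy(), fx
    for k in range(n_anneal):
        frac = 1.0 - k / n_anneal
        temp = t0 * frac + 1e-3
        prop = x + rng.normal(0.0, step0 * frac + 0.05, size=2)
        fp = f(prop)
        if fp > fx or rng.random() < np.exp((fp - fx) / temp):
            x, fx = prop, fp
            if fx > fbest:
                best, fbest = x.copy(), fx

    def neg(p):
        v = f(p)
        return 1e6 if not np.isfinite(v) else -v

    res = minimize(neg, best, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    if -res.fun > fbest:
        best, fbest = res.x, -res.fun
    return best, fbest


def pore_profile(structure: StructureModel, start_point,
                 coords: np.ndarray | None = None,
                 step: float = PORE_STEP,
                 bulk_cutoff: float = BULK_RADIUS_CUTOFF,
                 seed: int = 0, frame: int = 0,
                 n_anneal: int = 120) -> PoreProfile:
    """Largest-sphere pore profile along +z from `start_point`.

    `coords` overrides the structure's coordinates (for per-frame profiles of
    a trajectory). The profile extends in both z directions until the radius
    exceeds `bulk_cutoff` or the atom cloud ends.
    """
    xyz = np.asarray(coords if coords is not None else structure.coords, float)
    vdw = structure.vdw
    rng = np.random.default_rng(seed)
    start = np.asarray(start_point, float)

    c0, r0 = _optimize_center(start[:2], start[2], xyz, vdw, rng,
                              n_anneal=n_anneal)
    if r0 <= 0:
        raise PoreStartError(
            f"start point {start} is not inside an open cavity (r={r0:.2f} A)")
    zmin, zmax = xyz[:, 2].min(), xyz[:, 2].max()

    stations = []  # (z, radius, center3d)

    def walk(direction):
        xy = c0.copy()
        z = start[2] + direction * step
        while zmin - step <= z <= zmax + step:
            xy, r = _optimize_center(xy, z, xyz, vdw, rng, n_anneal=n_anneal)
            stations.append((z, r, np.array([xy[0], xy[1], z])))
            if r > bulk_cutoff:
                break
            z += direction * step

    stations.append((start[2], r0, np.array([c0[0], c0[1], start[2]])))
    walk(+1)
    walk(-1)
    stations.sort(key=lambda s: s[0])
    z = np.array([s[0] for s in stations])
    r = np.array([s[1] for s in stations])
    centers = np.array([s[2] for s in stations])
    return PoreProfile(z=z, radius=r, centers=centers, frame=frame)


def pore_direction(profiles: list[PoreProfile],
                   z_window: tuple[float, float]) -> np.ndarray:
    """Ensemble pore direction: mean of per-frame least-squares line directions.

    Each frame's direction is the principal direction of the sphere centers
    within `z_window`, oriented +z; the ensemble direction is the normalized
    mean over frames.
    """
    dirs = []
    for prof in profiles:
        mask = (prof.z >= z_window[0]) & (prof.z <= z_window[1])
        pts = prof.centers[mask]
        if len(pts) < 2:
            raise ValueError("need >=2 stations within z_window per frame")
        centered = pts - pts.mean(axis=0)
        if np.allclose(centered, 0.0):
            raise ValueError("degenerate: all sphere centers identical")
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        d = Vt[0]
        if d[2] < 0:
            d = -d
        dirs.append(d)
    mean = np.mean(dirs, axis=0)
    return mean / np.linalg.norm(mean)


def pore_divergence(direction_a: np.ndarray, direction_b: np.ndarray) -> float:
    """Angle (degrees) between two ensemble pore directions."""
    c = np.clip(np.dot(direction_a, direction_b), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def radius_distribution(profiles: list[PoreProfile],
                        z_intervals: list[tuple[float, float]],
                        bin_width: float = 0.25) -> dict:
    """Pooled radius histograms per pore-coordinate interval."""
    import warnings

    out = {}
    for (lo, hi) in z_intervals:
        pooled = np.concatenate([
            p.radius[(p.z >= lo) & (p.z <= hi)] for p in profiles])
        key = (float(lo), float(hi))
        if pooled.size == 0:
            warnings.warn(f"no stations in interval [{lo}, {hi}]")
            out[key] = HistogramSummary(np.array([lo, hi]), np.array([0]),
                                        np.array([]), np.array([]))
        else:
            out[key] = histogram(pooled, bin_width=bin_width)
    return out
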