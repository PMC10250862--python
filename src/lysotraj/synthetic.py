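"""Seeded synthetic structures and trajectories with known ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — two conformational ensembles differing in a localized region,
Gaussian coordinate fluctuations with planted inter-site couplings, a
lipid-like particle with a scripted insertion path, ideal kinked helices,
and atom-lined channels with a known radius profile — at desk scale, in
place of microsecond-scale membrane-protein MD. No physical realism is
attempted (no force field, no periodic images, no solvent structure); the
point is exact, machine-readable ground truth for every downstream stage.

Determinism contract: an identical :class:`SyntheticSpec` (including seed)
produces bit-identical output. Per-entity substreams are derived from
``(seed, entity_index)`` so adding entities does not perturb existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .trajectory import StructureModel, Trajectory

__all__ = [
    "SyntheticSpec",
    "make_two_state_ensemble",
    "make_coupled_site_ensemble",
    "make_kinked_helix",
    "make_channel_system",
    "make_insertion_toy",
    "coupled_blocks_covariance",
    "write_ground_truth",
]

KINDS = ("two_state", "coupled_sites", "kinked_helix", "channel", "insertion_toy")

# ideal alpha-helix geometry: exact analytic axis for oracle tests
HELIX_RISE = 1.5        # A per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # A, CA distance from axis


@dataclass
class SyntheticSpec:
    """Declarative recipe for one synthetic system."""

    kind: str
    n_atoms: int = 0
    n_frames: int = 0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown synthetic kind {self.kind!r}")

    def rng(self, *entity) -> np.random.Generator:
        """Substream for an entity, stable under addition of other entities."""
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, *entity])


def write_ground_truth(gt: dict, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(gt, indent=1, default=_default))


def _point_structure(coords, name="CA", resname="ALA", element="C",
                     chain="A", names=None, resnames=None, elements=None,
                     resids=None, vdw=None):
    n = len(coords)
    return StructureModel(
        names=np.array(names if names is not None else [name] * n, dtype=object),
        elements=np.array(elements if elements is not None else [element] * n,
                          dtype=object),
        resnames=np.array(resnames if resnames is not None else [resname] * n,
                          dtype=object),
        resids=np.arange(1, n + 1) if resids is None else np.asarray(resids, int),
        chains=np.array([chain] * n, dtype=object),
        coords=np.asarray(coords, float),
        vdw=vdw,
    )


# ---------------------------------------------------------------------------
# (i) two conformational ensembles differing in a localized region

def make_two_state_ensemble(spec: SyntheticSpec):
    """Two ensembles identical everywhere except a planted region.

    Frames of each state are i.i.d. multivariate-normal draws around a common
    base geometry; in state B the planted atoms' mean is displaced by
    ``shift_magnitude`` along ``shift_direction``. Stands in for the
    first-vs-last-frames ensemble split of a state-transition trajectory.

    params: planted_atoms (indices), shift_magnitude (A, default 3.0),
    shift_direction (default +x), noise_sigma (A, default 0.5),
    frames_per_state (default n_frames).
    """
    if spec.kind != "two_state":
        raise ValueError("spec.kind must be 'two_state'")
    p = spec.params
    n = spec.n_atoms
    planted = np.asarray(p.get("planted_atoms", []), dtype=int)
    if planted.size and (planted.min() < 0 or planted.max() >= n):
        raise ValueError(f"planted atoms out of range [0, {n})")
    shift = float(p.get("shift_magnitude", 3.0))
    direction = np.asarray(p.get("shift_direction", (1.0, 0.0, 0.0)), float)
    direction = direction / np.linalg.norm(direction)
    sigma = float(p.get("noise_sigma", 0.5))
    f_per = int(p.get("frames_per_state", spec.n_frames))

    base_rng = spec.rng(0)
    # base geometry: points on a coarse 3-D grid with jitter, ~4 A spacing
    side = int(np.ceil(n ** (1 / 3)))
    grid = np.array(np.meshgrid(*[np.arange(side)] * 3)).reshape(3, -1).T[:n]
    base = grid * 4.0 + base_rng.uniform(-0.5, 0.5, size=(n, 3))

    mean_a = base
    mean_b = base.copy()
    mean_b[planted] += shift * direction

    frames_a = mean_a[None] + spec.rng(1).normal(0.0, sigma, size=(f_per, n, 3))
    frames_b = mean_b[None] + spec.rng(2).normal(0.0, sigma, size=(f_per, n, 3))

    ref = _point_structure(base)
    gt = {
        "planted_atoms": planted,
        "shift_magnitude": shift,
        "shift_direction": direction,
        "noise_sigma": sigma,
        "frames_per_state": f_per,
    }
    return Trajectory(ref, frames_a), Trajectory(ref, frames_b), gt


# ---------------------------------------------------------------------------
# (ii) Gaussian fluctuations with planted inter-site couplings

def coupled_blocks_covariance(n_sites: int, atoms_per_site: int,
                              cross_corr: float = 0.0,
                              coupled_pairs=None,
                              variance: float = 1.0) -> np.ndarray:
    """Block covariance over 3N coordinates with chosen cross-site correlation.

    Within-site coordinates are independent with `variance`; for each coupled
    site pair, corresponding coordinates are correlated with `cross_corr`.
    """
    d = 3 * atoms_per_site
    dim = n_sites * d
    C = np.eye(dim) * variance
    if coupled_pairs is None and cross_corr:
        coupled_pairs = [(i, i + 1) for i in range(n_sites - 1)]
    for (a, b) in (coupled_pairs or []):
        blk = np.eye(d) * cross_corr * variance
        C[a * d:(a + 1) * d, b * d:(b + 1) * d] = blk
        C[b * d:(b + 1) * d, a * d:(a + 1) * d] = blk
    # validate positive definiteness early
    np.linalg.cholesky(C)
    return C


def make_coupled_site_ensemble(spec: SyntheticSpec):
    """Zero-mean Gaussian trajectory with an exactly known 3Nx3N covariance.

    params: either ``covariance`` (3N x 3N, symmetric positive definite) or a
    block recipe ``{"n_sites", "atoms_per_site", "cross_corr", "coupled_pairs",
    "variance"}``. The returned covariance is exactly the sampling covariance
    used.
    """
    if spec.kind != "coupled_sites":
        raise ValueError("spec.kind must be 'coupled_sites'")
    p = spec.params
    if "covariance" in p:
        C = np.asarray(p["covariance"], float)
    else:
        C = coupled_blocks_covariance(
            p["n_sites"], p["atoms_per_site"], p.get("cross_corr", 0.0),
            p.get("coupled_pairs"), p.get("variance", 1.0))
    dim = C.shape[0]
    if C.shape != (dim, dim) or dim % 3:
        raise ValueError("covariance must be 3N x 3N")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    n_atoms = dim // 3
    if spec.n_atoms and spec.n_atoms != n_atoms:
        raise ValueError(f"n_atoms={spec.n_atoms} but covariance implies {n_atoms}")

    rng = spec.rng(1)
    z = rng.standard_normal((spec.n_frames, dim))
    fluct = z @ L.T
    base = np.zeros((n_atoms, 3))
    base[:, 0] = np.arange(n_atoms) * 10.0   # spaced line; fluctuations added
    frames = base[None] + fluct.reshape(spec.n_frames, n_atoms, 3)
    ref = _point_structure(base)
    return Trajectory(ref, frames), C


# ---------------------------------------------------------------------------
# (iv) ideal alpha-helices with a planted kink

def _ideal_helix(n_res: int, axis: np.ndarray, start: np.ndarray,
                 phase0: float) -> np.ndarray:
    """CA trace of an ideal helix along `axis` starting near `start`."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(axis @ tmp) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    t = np.arange(n_res)
    ang = np.deg2rad(phase0 + HELIX_TWIST * t)
    pts = (start[None]
           + np.outer(t * HELIX_RISE, axis)
           + HELIX_RADIUS * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)))
    return pts


def make_kinked_helix(spec: SyntheticSpec) -> tuple[StructureModel, dict]:
    """CA trace of an ideal helix whose axis bends by exactly ``kink_angle``.

    params: n_pre / n_post (residues per flanking segment, >=6),
    kink_angle (degrees in [0, 90]). The kink residue is a proline placed
    between the segments; ground truth carries both exact axis vectors.
    """
    if spec.kind != "kinked_helix":
        raise ValueError("spec.kind must be 'kinked_helix'")
    p = spec.params
    n_pre = int(p.get("n_pre", 14))
    n_post = int(p.get("n_post", 14))
    angle = float(p.get("kink_angle", 0.0))
    if not (0.0 <= angle <= 90.0):
        raise ValueError("kink_angle must be in [0, 90] degrees")
    if min(n_pre, n_post) < 6:
        raise ValueError("need >=6 residues per flanking segment")

    axis1 = np.array([0.0, 0.0, 1.0])
    a = np.deg2rad(angle)
    axis2 = np.array([np.sin(a), 0.0, np.cos(a)])  # rotate about +y

    pre = _ideal_helix(n_pre, axis1, np.zeros(3), phase0=0.0)
    # the proline continues the first helix by one residue; the axis changes
    # direction exactly at the proline's axis station
    kink_axis_pt = n_pre * HELIX_RISE * axis1
    kink = _ideal_helix(1, axis1, kink_axis_pt, phase0=HELIX_TWIST * n_pre)
    post = _ideal_helix(n_post, axis2, kink_axis_pt + HELIX_RISE * axis2,
                        phase0=HELIX_TWIST * (n_pre + 1))
    coords = np.vstack([pre, kink, post])
    n = len(coords)
    resnames = ["ALA"] * n_pre + ["PRO"] + ["ALA"] * n_post
    model = _point_structure(coords, name="CA", resnames=resnames)
    gt = {
        "kink_angle": angle,
        "kink_resid": n_pre + 1,
        "axis_pre": axis1,
        "axis_post": axis2,
        "n_pre": n_pre,
        "n_post": n_post,
    }
    return model, gt


# ---------------------------------------------------------------------------
# (v) atom-lined channels with a known radius profile

def make_channel_system(spec: SyntheticSpec) -> tuple[StructureModel, dict]:
    """Atoms on rings along an axis forming a channel of known radius.

    At each station ``z`` the ring of atoms sits at distance ``r(z) + vdw``
    from the axis, so the true accessible pore radius at that station is
    exactly ``r(z)``.

    params: stations (z values, A), radius_profile (r(z), A), atoms_per_ring
    (default 16), vdw (default 0.0), tilt_deg (axis tilt from +z about +y,
    default 0), center_xy (default origin).
    """
    if spec.kind != "channel":
        raise ValueError("spec.kind must be 'channel'")
    p = spec.params
    stations = np.asarray(p["stations"], float)
    radii = np.asarray(p["radius_profile"], float)
    if stations.shape != radii.shape:
        raise ValueError("stations and radius_profile must align")
    m = int(p.get("atoms_per_ring", 16))
    vdw = float(p.get("vdw", 0.0))
    tilt = float(p.get("tilt_deg", 0.0))
    cxy = np.asarray(p.get("center_xy", (0.0, 0.0)), float)
    if np.any(radii <= vdw) and vdw > 0:
        pass  # radius measured to sphere surface; any positive r is valid
    if np.any(radii <= 0):
        raise ValueError("radius profile must be positive")

    t = np.deg2rad(tilt)
    R = np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]])
    coords = []
    ang0 = 0.0
    for z, r in zip(stations, radii):
        ang = ang0 + np.linspace(0, 2 * np.pi, m, endpoint=False)
        ring = np.stack([(r + vdw) * np.cos(ang), (r + vdw) * np.sin(ang),
                         np.full(m, z)], axis=1)
        ring = ring @ R.T
        ring[:, 0] += cxy[0]
        ring[:, 1] += cxy[1]
        coords.append(ring)
        ang0 += np.pi / m  # stagger rings so gaps do not align
    coords = np.vstack(coords)
    model = _point_structure(coords, name="C", element="C",
                             vdw=np.full(len(coords), vdw))
    axis = R @ np.array([0.0, 0.0, 1.0])
    gt = {
        "stations": stations,
        "radius_profile": radii,
        "axis": axis,
        "tilt_deg": tilt,
        "vdw": vdw,
        "center_xy": cxy,
    }
    return model, gt


# ---------------------------------------------------------------------------
# (iii) lipid insertion toy with waters and a cation

PORTAL_LABELS = ("TM5/TM8", "TM2/TM11")


def _insertion_events_from_path(dz_path, threshold=13.0, hysteresis=2.0):
    """Episodes of dz <= threshold, ending when dz returns above threshold+hys."""
    events = []
    inside = False
    entry = None
    for i, v in enumerate(dz_path):
        if not inside and v <= threshold:
            inside, entry = True, i
        elif inside and v > threshold + hysteresis:
            events.append((entry, i - 1))
            inside = False
    if inside:
        events.append((entry, len(dz_path) - 1))
    return events


def make_insertion_toy(spec: SyntheticSpec):
    """Scripted lipid-insertion trajectory with waters and one cation.

    Emulates substrate entry through two lateral portals of a transporter:
    each lipid's headgroup phosphorus follows a scripted path in z relative
    to a reference CA atom (the gate residue stand-in), approaching through
    its assigned portal in the xy plane. Waters (single-point, name OH2) are
    scripted to sit inside or outside a 3 A shell of designated sidechain
    atoms; one Na+ follows a scripted distance path to a carboxyl-carbon
    stand-in. Ground truth records true insertion events, pathways, per-frame
    water counts and Na-bridge frames.

    params:
      lipids: list of {"dz_path": [...], "portal": "TM5/TM8"|"TM2/TM11"}
      jitter_sigma: coordinate jitter on lipid P (A, default 0.05)
      n_shell_waters / n_far_waters: ints, or per-frame lists
      na_distance_path: scripted Na-to-carboxyl-C distances (A)
      box: half-width of allowed region (A, default 60)
      threshold / hysteresis: insertion rule used for ground truth (13 / 2 A)
    """
    if spec.kind != "insertion_toy":
        raise ValueError("spec.kind must be 'insertion_toy'")
    p = spec.params
    lipids = p.get("lipids", [])
    n_frames = spec.n_frames
    jitter = float(p.get("jitter_sigma", 0.05))
    box = float(p.get("box", 60.0))
    threshold = float(p.get("threshold", 13.0))
    hysteresis = float(p.get("hysteresis", 2.0))

    portal_xy = {
        "TM5/TM8": np.asarray(p.get("portal_58_xy", (12.0, 0.0)), float),
        "TM2/TM11": np.asarray(p.get("portal_211_xy", (-12.0, 0.0)), float),
    }

    def _per_frame(v, default):
        if v is None:
            v = default
        arr = np.asarray(v)
        if arr.ndim == 0:
            arr = np.full(n_frames, int(arr))
        if len(arr) != n_frames:
            raise ValueError("per-frame parameter length mismatch")
        return arr.astype(int)

    n_shell = _per_frame(p.get("n_shell_waters"), 0)
    n_far = _per_frame(p.get("n_far_waters"), 0)
    max_shell, max_far = int(n_shell.max()), int(n_far.max())
    na_path = p.get("na_distance_path")
    na_path = (np.asarray(na_path, float) if na_path is not None
               else np.full(n_frames, 10.0))
    if len(na_path) != n_frames:
        raise ValueError("na_distance_path length mismatch")

    # --- static atoms -------------------------------------------------------
    names, resnames, elements, resids, base = [], [], [], [], []

    def add(name, resname, element, resid, xyz):
        names.append(name); resnames.append(resname); elements.append(element)
        resids.append(resid); base.append(xyz)

    add("CA", "PHE", "C", 399, (0.0, 0.0, 0.0))          # gate reference CA
    add("CD", "GLU", "C", 312, (4.0, 0.0, 8.0))          # carboxyl carbon
    # portal anchors: two atoms each
    for k, (label, xy) in enumerate(portal_xy.items()):
        rid = (200, 345) if label == "TM5/TM8" else (85, 431)
        for j in range(2):
            add("CA", "POR", "C", rid[j], (xy[0], xy[1] + (j - 0.5) * 2.0, 10.0))
    shell_xyz = np.asarray(p.get("shell_atoms",
                                 [(0.0, 6.0, 16.0), (3.0, -5.0, 16.0),
                                  (-4.0, 2.0, 18.0)]), float)
    for j, xyz in enumerate(shell_xyz):
        add("CZ", "SHL", "C", 500 + j, tuple(xyz))
    lipid_atom0 = len(names)
    for i, lip in enumerate(lipids):
        if lip.get("portal", "TM5/TM8") not in PORTAL_LABELS:
            raise ValueError(f"unknown portal {lip.get('portal')!r}")
        dzp = np.asarray(lip["dz_path"], float)
        if len(dzp) != n_frames:
            raise ValueError(f"lipid {i}: dz_path length != n_frames")
        if np.any(np.abs(dzp) > box):
            raise ValueError(f"lipid {i}: path leaves the box (+-{box} A)")
        add("P", "LPC", "P", 1000 + i, (0.0, 0.0, 0.0))
    water_atom0 = len(names)
    for j in range(max_shell + max_far):
        add("OH2", "TIP3", "O", 2000 + j, (0.0, 0.0, -40.0))
    na_atom = len(names)
    add("NA", "NA", "NA", 3000, (0.0, 0.0, 0.0))

    base = np.asarray(base, float)
    ref = _point_structure(base, names=names, resnames=resnames,
                           elements=elements, resids=resids)

    # --- frames -------------------------------------------------------------
    frames = np.repeat(base[None], n_frames, axis=0)
    carboxyl = base[1]

    gt_events = []
    intervals = []
    for i, lip in enumerate(lipids):
        dzp = np.asarray(lip["dz_path"], float)
        portal = lip.get("portal", "TM5/TM8")
        pxy = portal_xy[portal]
        rng = spec.rng(10, i)
        # xy: sit at the portal while high, move to the axis once inserted
        w = np.clip((20.0 - dzp) / 15.0, 0.0, 1.0)   # 0 in bulk, 1 when deep
        xy = (1 - w)[:, None] * (pxy[None] * 1.3) + w[:, None] * (pxy[None] * 0.1)
        noise = rng.normal(0.0, jitter, size=(n_frames, 3)) if jitter else 0.0
        frames[:, lipid_atom0 + i, 0] = xy[:, 0]
        frames[:, lipid_atom0 + i, 1] = xy[:, 1]
        frames[:, lipid_atom0 + i, 2] = dzp
        if jitter:
            frames[:, lipid_atom0 + i] += noise
        eps = _insertion_events_from_path(dzp, threshold, hysteresis)
        for (a, b) in eps:
            gt_events.append({"lipid_id": i, "entry_frame": int(a),
                              "exit_frame": int(b), "pathway": portal,
                              "min_dz": float(dzp[a:b + 1].min())})
            intervals.append((a, b, len(gt_events) - 1))
    # concomitance: overlapping inserted intervals
    for a1, b1, e1 in intervals:
        for a2, b2, e2 in intervals:
            if e1 < e2 and a1 <= b2 and a2 <= b1:
                gt_events[e1]["concomitant"] = True
                gt_events[e2]["concomitant"] = True
    for ev in gt_events:
        ev.setdefault("concomitant", False)

    # waters: first n_shell at 2.0 A of a shell atom, n_far out at z=-40
    water_counts = np.zeros(n_frames, dtype=int)
    rng_w = spec.rng(20)
    dirs = rng_w.normal(size=(max_shell + max_far, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    for f in range(n_frames):
        ns, nf = int(n_shell[f]), int(n_far[f])
        for j in range(max_shell + max_far):
            atom = water_atom0 + j
            if j < ns:
                host = shell_xyz[j % len(shell_xyz)]
                frames[f, atom] = host + 2.0 * dirs[j]
            elif j < ns + nf:
                frames[f, atom] = (30.0 + 3.0 * j, 0.0, -40.0)
            else:
                frames[f, atom] = (0.0, 0.0, -40.0 - 3.0 * j)  # parked, far
        water_counts[f] = ns

    # cation: scripted distance to the carboxyl carbon along +x
    frames[:, na_atom, 0] = carboxyl[0] + na_path
    frames[:, na_atom, 1] = carboxyl[1]
    frames[:, na_atom, 2] = carboxyl[2]

    # Na-bridge ground truth from the noise-free scripts
    na_cut = float(p.get("na_cut", 2.5))
    p_cut = float(p.get("p_cut", 6.0))
    if lipids:
        p_dists = np.linalg.norm(
            frames[:, lipid_atom0:lipid_atom0 + len(lipids)] - carboxyl[None, None],
            axis=2).min(axis=1)
    else:
        p_dists = np.full(n_frames, np.inf)
    na_close = na_path <= na_cut
    p_close = p_dists < p_cut
    gt = {
        "events": gt_events,
        "n_events": len(gt_events),
        "water_counts": water_counts,
        "na_close_frames": na_close.astype(int),
        "p_close_frames": p_close.astype(int),
        "bridge_frames": (na_close & p_close).astype(int),
        "threshold": threshold,
        "hysteresis": hysteresis,
        "portal_xy": {k: v.tolist() for k, v in portal_xy.items()},
        "lipid_atom_indices": list(range(lipid_atom0, lipid_atom0 + len(lipids))),
        "ref_atom_index": 0,
        "carboxyl_atom_index": 1,
        "shell_atom_indices": list(range(lipid_atom0 - len(shell_xyz), lipid_atom0)),
        "water_atom_indices": list(range(water_atom0, na_atom)),
        "na_atom_index": na_atom,
    }
    return ref, Trajectory(ref, frames), gt
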