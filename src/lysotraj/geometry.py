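"""Per-frame observables for substrate insertion and gating.

Implements the insertion-depth metric d_z (signed z-distance between a lipid
headgroup phosphorus and a reference CA, positive on the extracellular
side), threshold-based insertion-event detection with portal (pathway)
assignment, substrate RMSD after transmembrane-backbone superposition,
distance and dihedral time series, vestibule water counting, sodium-bridge
detection, and fixed-width histograms with peak labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .trajectory import (DegenerateSelectionError, Selection, Trajectory,
                         superpose)

__all__ = [
    "ObservableSeries",
    "InsertionEvent",
    "HistogramSummary",
    "dz_series",
    "min_dz_series",
    "detect_insertions",
    "substrate_rmsd",
    "distance_series",
    "dihedral_series",
    "count_vestibule_waters",
    "na_bridge_series",
    "histogram",
]

DZ_INSERTION_THRESHOLD = 13.0   # A: headgroup counted as inserted at/below this
NA_BRIDGE_CUT = 2.5             # A: Na+ to carboxyl carbon
P_BRIDGE_CUT = 6.0              # A: substrate P to carboxyl carbon
WATER_SHELL_CUT = 3.0           # A: water-to-sidechain vestibule shell


@dataclass
class ObservableSeries:
    """A per-frame scalar time series with units and provenance."""

    name: str
    values: np.ndarray
    units: str = ""
    frames: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.frames is None:
            self.frames = np.arange(len(self.values))
        else:
            self.frames = np.asarray(self.frames, dtype=int)
        if len(self.frames) != len(self.values):
            raise ValueError("frames and values length mismatch")

    def __len__(self):
        return len(self.values)


@dataclass
class InsertionEvent:
    lipid_id: int
    entry_frame: int
    exit_frame: int
    pathway: str            # "TM5/TM8", "TM2/TM11" or "ambiguous"
    min_dz: float
    concomitant: bool = False


@dataclass
class HistogramSummary:
    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: np.ndarray       # bin-center locations of detected peaks, by height
    peak_heights: np.ndarray


def _single_atom(sel: Selection, what: str) -> int:
    if len(sel) != 1:
        raise ValueError(f"{what} must resolve to exactly 1 atom, got {len(sel)}")
    return int(sel.indices[0])


def dz_series(traj: Trajectory, lipid_P: Selection,
              ref_atom: Selection) -> list[ObservableSeries]:
    """Signed z-distance of each lipid P atom to the reference atom, per frame.

    d_z = z(P) - z(ref); positive above the reference (extracellular side up).
    One series per lipid P atom, in selection order.
    """
    ref = _single_atom(ref_atom, "ref_atom")
    out = []
    zref = traj.frames[:, ref, 2]
    for i in lipid_P.indices:
        vals = traj.frames[:, i, 2] - zref
        out.append(ObservableSeries(
            name=f"dz_atom{i}", values=vals, units="A",
            meta={"lipid_atom": int(i), "ref_atom": ref}))
    return out


def min_dz_series(series: list[ObservableSeries]) -> ObservableSeries:
    """Per-frame minimum of d_z over lipids (the headgroup closest to the gate)."""
    stacked = np.stack([s.values for s in series])
    return ObservableSeries("min_dz", stacked.min(axis=0), units="A")


def detect_insertions(traj: Trajectory, dz: list[ObservableSeries],
                      portals: dict[str, Selection],
                      threshold: float = DZ_INSERTION_THRESHOLD,
                      hysteresis: float = 2.0,
                      approach_window: int = 10) -> list[InsertionEvent]:
    """Detect insertion episodes (d_z <= threshold) and assign entry pathways.

    An episode starts at the first frame with d_z <= threshold and ends when
    d_z rises back above threshold + hysteresis (debounces threshold
    chatter). The pathway is the portal whose anchor centroid the P atom
    approached most closely over the `approach_window` frames preceding
    entry (including the entry frame). Two events are flagged concomitant
    when their inserted intervals overlap.
    """
    for label, sel in portals.items():
        if len(sel) == 0:
            raise ValueError(f"portal {label!r} resolves to no atoms")
    events: list[InsertionEvent] = []
    for lip_no, s in enumerate(dz):
        atom = s.meta.get("lipid_atom")
        vals = s.values
        inside, entry = False, None
        episodes = []
        for f, v in enumerate(vals):
            if not inside and v <= threshold:
                inside, entry = True, f
            elif inside and v > threshold + hysteresis:
                episodes.append((entry, f - 1))
                inside = False
        if inside:
            episodes.append((entry, len(vals) - 1))
        for (a, b) in episodes:
            w0 = max(0, a - approach_window + 1)
            p_xyz = traj.frames[w0:a + 1, atom]
            best_label, best_d = "ambiguous", np.inf
            for label, sel in portals.items():
                cent = traj.frames[w0:a + 1, sel.indices].mean(axis=1)
                d = np.linalg.norm(p_xyz - cent, axis=1).min()
                if d < best_d:
                    best_label, best_d = label, d
            events.append(InsertionEvent(
                lipid_id=lip_no, entry_frame=int(a), exit_frame=int(b),
                pathway=best_label, min_dz=float(vals[a:b + 1].min())))
    for i, e1 in enumerate(events):
        for e2 in events[i + 1:]:
            if e1.entry_frame <= e2.exit_frame and e2.entry_frame <= e1.exit_frame:
                e1.concomitant = e2.concomitant = True
    return events


def substrate_rmsd(traj: Trajectory, substrate_heavy: Selection,
                   align: Selection) -> ObservableSeries:
    """Per-frame substrate RMSD to its initial position after backbone alignment.

    Frames are first rigidly superposed on `align` (the transmembrane
    backbone) against frame 0; the RMSD of the substrate heavy atoms to
    their frame-0 positions is then reported.
    """
    if len(substrate_heavy) == 0:
        raise ValueError("substrate selection is empty")
    elems = traj.reference.elements[substrate_heavy.indices]
    if any(str(e).upper() == "H" for e in elems):
        raise ValueError("substrate selection must exclude hydrogens")
    fitted = superpose(traj, align, reference_frame=0)
    ref = fitted.frames[0, substrate_heavy.indices]
    diffs = fitted.frames[:, substrate_heavy.indices] - ref[None]
    rmsd = np.sqrt((diffs ** 2).sum(axis=2).mean(axis=1))
    return ObservableSeries("substrate_rmsd", rmsd, units="A",
                            meta={"align": align.expression,
                                  "substrate": substrate_heavy.expression})


def distance_series(traj: Trajectory, selA: Selection, selB: Selection,
                    mode: str = "atom-atom") -> ObservableSeries:
    """Per-frame distance between two selections.

    mode "atom-atom": both selections are single atoms; "min": minimum over
    all atom pairs (e.g. nearest Na+); "centroid": distance between centroids.
    """
    if len(selA) == 0 or len(selB) == 0:
        raise ValueError("selections must be non-empty")
    A, B = selA.indices, selB.indices
    if mode == "atom-atom":
        ia, ib = _single_atom(selA, "selA"), _single_atom(selB, "selB")
        vals = np.linalg.norm(traj.frames[:, ia] - traj.frames[:, ib], axis=1)
    elif mode == "min":
        vals = np.array([cdist(fr[A], fr[B]).min() for fr in traj.frames])
    elif mode == "centroid":
        vals = np.linalg.norm(traj.frames[:, A].mean(axis=1)
                              - traj.frames[:, B].mean(axis=1), axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ObservableSeries(f"distance[{mode}]", vals, units="A",
                            meta={"selA": selA.expression,
                                  "selB": selB.expression, "mode": mode})


class UndefinedDihedralError(ValueError):
    """A dihedral is undefined because three of its atoms are collinear."""


def dihedral_series(traj: Trajectory, four_atoms: Selection,
                    ordered_indices=None) -> ObservableSeries:
    """Signed dihedral (IUPAC convention) of four ordered atoms, per frame.

    Returns angles in (-180, 180] degrees. `ordered_indices` overrides the
    sorted selection order when the chemical order differs from atom order.
    """
    idx = (np.asarray(ordered_indices, int) if ordered_indices is not None
           else four_atoms.indices)
    if len(idx) != 4:
        raise ValueError(f"dihedral needs exactly 4 atoms, got {len(idx)}")
    p = traj.frames[:, idx]  # (F, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    bad = (np.linalg.norm(n1, axis=1) < 1e-10) | (np.linalg.norm(n2, axis=1) < 1e-10)
    if bad.any():
        raise UndefinedDihedralError(
            f"collinear atoms at frame(s) {np.flatnonzero(bad)[:5].tolist()}")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = (n1 * n2).sum(axis=1)
    y = -(m1 * n2).sum(axis=1)
    ang = np.degrees(np.arctan2(y, x))
    ang[ang <= -180.0] += 360.0
    return ObservableSeries("dihedral", ang, units="deg",
                            meta={"atoms": idx.tolist()})


def count_vestibule_waters(traj: Trajectory, water: Selection,
                           shell_sidechains: Selection,
                           cutoff: float = WATER_SHELL_CUT,
                           method: str = "tree") -> ObservableSeries:
    """Per-frame count of water molecules in the vestibule shell.

    A water belongs to the shell if any of its atoms is within `cutoff` of
    any shell sidechain atom; each water molecule (grouped by residue id) is
    counted once. `method` selects the KD-tree path or the naive double loop
    (kept as an independent cross-check).
    """
    if len(water) == 0 or len(shell_sidechains) == 0:
        raise ValueError("selections must be non-empty")
    widx = water.indices
    sidx = shell_sidechains.indices
    wres = traj.reference.resids[widx]
    counts = np.zeros(traj.n_frames, dtype=int)
    for f, frame in enumerate(traj.frames):
        if method == "tree":
            tree = cKDTree(frame[sidx])
            d, _ = tree.query(frame[widx], k=1,
                              distance_upper_bound=cutoff + 1e-9)
            close = d <= cutoff
        elif method == "naive":
            close = np.zeros(len(widx), dtype=bool)
            for i, wa in enumerate(frame[widx]):
                for sa in frame[sidx]:
                    if np.linalg.norm(wa - sa) <= cutoff:
                        close[i] = True
                        break
        else:
            raise ValueError(f"unknown method {method!r}")
        counts[f] = len(np.unique(wres[close]))
    return ObservableSeries("vestibule_waters", counts, units="count",
                            meta={"cutoff": cutoff, "method": method})


def na_bridge_series(traj: Trajectory, carboxylC: Selection,
                     cations: Selection, lipid_P: Selection,
                     na_cut: float = NA_BRIDGE_CUT,
                     p_cut: float = P_BRIDGE_CUT):
    """Sodium-bridge detection at the headgroup-coordinating acidic residue.

    A frame is a bridge frame when the nearest cation is within `na_cut` of
    the carboxyl carbon AND the nearest substrate P atom is below `p_cut`.
    Returns (na_close, p_close, bridge) boolean series plus a summary with
    the overall bridge fraction and the conditional fraction
    P(P < p_cut | Na <= na_cut).
    """
    ic = _single_atom(carboxylC, "carboxylC")
    if len(cations) == 0 or len(lipid_P) == 0:
        raise ValueError("cation and lipid selections must be non-empty")
    c_xyz = traj.frames[:, ic]
    na_d = np.linalg.norm(
        traj.frames[:, cations.indices] - c_xyz[:, None], axis=2).min(axis=1)
    p_d = np.linalg.norm(
        traj.frames[:, lipid_P.indices] - c_xyz[:, None], axis=2).min(axis=1)
    na_close = na_d <= na_cut
    p_close = p_d < p_cut
    bridge = na_close & p_close
    summary = {
        "bridge_fraction": float(bridge.mean()),
        "na_close_fraction": float(na_close.mean()),
        "conditional_p_given_na": (float(p_close[na_close].mean())
                                   if na_close.any() else float("nan")),
    }
    series = {
        "na_close": ObservableSeries("na_close", na_close.astype(int)),
        "p_close": ObservableSeries("p_close", p_close.astype(int)),
        "bridge": ObservableSeries("na_bridge", bridge.astype(int)),
        "na_distance": ObservableSeries("na_distance", na_d, units="A"),
        "p_distance": ObservableSeries("p_distance", p_d, units="A"),
    }
    return series, summary


def histogram(values, bin_width: float = 0.5, origin: float = 0.0,
              smooth_bins: int = 3) -> HistogramSummary:
    """Fixed-width histogram with peak detection.

    Bins are anchored at `origin`; peaks are local maxima of the
    `smooth_bins`-bin moving average of the counts, ranked by height
    (supports P1/P2-style labelling of bimodal distributions).
    """
    values = np.asarray(values, float).ravel()
    if values.size == 0:
        raise ValueError("histogram needs at least one observation")
    lo = origin + np.floor((values.min() - origin) / bin_width) * bin_width
    hi = origin + np.ceil((values.max() - origin) / bin_width + 1e-12) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    if len(counts) >= smooth_bins:
        kernel = np.ones(smooth_bins) / smooth_bins
        smooth = np.convolve(counts, kernel, mode="same")
    else:
        smooth = counts.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2
    peaks, heights = [], []
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < len(smooth) - 1 else -np.inf
        if smooth[i] > 0 and smooth[i] >= left and smooth[i] > right:
            peaks.append(centers[i])
            heights.append(smooth[i])
    order = np.argsort(heights)[::-1]
    return HistogramSummary(
        bin_edges=edges, counts=counts,
        peaks=np.asarray(peaks)[order] if peaks else np.array([]),
        peak_heights=np.asarray(heights)[order] if peaks else np.array([]))
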