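"""Structures, trajectories, atom selection and rigid-body operations.

Coordinates are in Angstrom throughout; residue numbering is 1-based as in
PDB; the membrane normal is the +z axis by convention. Atom order in a
:class:`StructureModel` is stable and is the canonical pixel order used by
the image encoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StructureModel",
    "Trajectory",
    "Selection",
    "StructureFormatError",
    "SelectionError",
    "DegenerateSelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "superpose",
    "scramble",
    "kabsch",
    "BONDI_RADII",
    "DEFAULT_VDW",
]

# Bondi van der Waals radii (A); anything absent falls back to DEFAULT_VDW.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "ZN": 1.39, "HE": 1.40, "AR": 1.88,
}
DEFAULT_VDW = 1.70


class StructureFormatError(ValueError):
    """Raised for unsupported or malformed structure/trajectory input."""


class SelectionError(ValueError):
    """Raised when a selection expression is invalid or resolves badly."""


class DegenerateSelectionError(ValueError):
    """Raised when a selection is geometrically degenerate for the operation."""


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    if name[:2].upper() in ("CL", "BR", "NA", "MG", "ZN") and len(name) <= 2:
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


@dataclass
class StructureModel:
    """An ordered set of atoms with one coordinate frame.

    Atom order is load-bearing: it defines pixel order for image encoding
    and the row order of every per-atom result.
    """

    names: np.ndarray          # (N,) str
    elements: np.ndarray       # (N,) str
    resnames: np.ndarray       # (N,) str
    resids: np.ndarray         # (N,) int, 1-based
    chains: np.ndarray         # (N,) str
    coords: np.ndarray         # (N, 3) float, Angstrom
    vdw: np.ndarray = None     # (N,) float, Angstrom

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.chains = np.asarray(self.chains, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for arr, label in ((self.names, "names"), (self.elements, "elements"),
                           (self.resnames, "resnames"), (self.resids, "resids"),
                           (self.chains, "chains")):
            if len(arr) != n:
                raise ValueError(f"{label} has length {len(arr)}, expected {n}")
        if self.vdw is None:
            self.vdw = np.array(
                [BONDI_RADII.get(str(e).upper(), DEFAULT_VDW) for e in self.elements],
                dtype=float,
            )
        else:
            self.vdw = np.asarray(self.vdw, dtype=float)
        self._universe = None

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def to_universe(self):
        """Build (and cache) an MDAnalysis Universe mirroring this model."""
        if self._universe is not None:
            return self._universe
        import MDAnalysis as mda

        # group consecutive atoms into residues by (chain, resid)
        keys = list(zip(self.chains, self.resids))
        resindex = np.zeros(self.n_atoms, dtype=int)
        uniq, ridx = [], -1
        prev = None
        for i, k in enumerate(keys):
            if k != prev:
                ridx += 1
                uniq.append(k)
                prev = k
            resindex[i] = ridx
        n_res = ridx + 1
        u = mda.Universe.empty(
            self.n_atoms, n_residues=n_res, atom_resindex=resindex,
            residue_segindex=np.zeros(n_res, dtype=int), trajectory=True,
        )
        u.add_TopologyAttr("name", [str(x) for x in self.names])
        u.add_TopologyAttr("type", [str(x) for x in self.elements])
        u.add_TopologyAttr("element", [str(x) for x in self.elements])
        res_resids = [self.resids[np.flatnonzero(resindex == r)[0]] for r in range(n_res)]
        res_names = [self.resnames[np.flatnonzero(resindex == r)[0]] for r in range(n_res)]
        u.add_TopologyAttr("resid", res_resids)
        u.add_TopologyAttr("resname", [str(x) for x in res_names])
        u.add_TopologyAttr("chainID", [str(x) for x in self.chains])
        u.atoms.positions = self.coords.astype(np.float32)
        self._universe = u
        return u

    def select(self, expression: str) -> "Selection":
        return Selection.resolve(expression, self)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return StructureModel(self.names, self.elements, self.resnames,
                              self.resids, self.chains, np.array(coords, float),
                              vdw=self.vdw.copy())


@dataclass
class Selection:
    """A named atom subset resolved from a selection expression.

    Expressions use the MDAnalysis grammar (``resid``, ``resname``, ``name``,
    ``element``, ``chainID``, combined with ``and``/``or``/``not``); resolving
    the same expression against the same model is deterministic.
    """

    expression: str
    indices: np.ndarray  # sorted atom indices

    @classmethod
    def resolve(cls, expression: str, model: StructureModel) -> "Selection":
        u = model.to_universe()
        try:
            ag = u.select_atoms(expression)
        except Exception as exc:  # MDAnalysis raises its own SelectionError
            raise SelectionError(f"cannot resolve {expression!r}: {exc}") from exc
        return cls(expression, np.sort(ag.indices).astype(int))

    @classmethod
    def from_indices(cls, indices, expression: str = "<indices>") -> "Selection":
        return cls(expression, np.sort(np.asarray(indices, dtype=int)))

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Trajectory:
    """A reference structure plus an ordered stack of coordinate frames."""

    reference: StructureModel
    frames: np.ndarray                 # (F, N, 3) float
    frame_stride_ps: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[1] != self.reference.n_atoms:
            raise ValueError(
                f"frames shape {self.frames.shape} does not match "
                f"{self.reference.n_atoms} reference atoms")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def __getitem__(self, frame_slice) -> "Trajectory":
        sub = np.atleast_3d(self.frames[frame_slice])
        if sub.ndim == 2:
            sub = sub[None]
        return Trajectory(self.reference, sub.copy(), self.frame_stride_ps)


# ---------------------------------------------------------------------------
# File input/output (MDAnalysis-backed)

def read_structure(path, format: str = "PDB") -> StructureModel:
    """Read a single-model PDB into a StructureModel.

    Multi-model files, altloc records and insertion codes are rejected:
    a deterministic, unambiguous atom order is required downstream.
    """
    if format.upper() != "PDB":
        raise StructureFormatError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    if hasattr(u.trajectory, "n_frames") and u.trajectory.n_frames > 1:
        raise StructureFormatError(f"{path}: multi-model PDB not supported")
    ag = u.atoms
    try:
        elements = np.array([str(e) for e in ag.elements], dtype=object)
    except Exception:
        elements = np.array([_guess_element(n) for n in ag.names], dtype=object)
    if any(str(e).strip() == "" for e in elements):
        elements = np.array(
            [str(e) if str(e).strip() else _guess_element(n)
             for e, n in zip(elements, ag.names)], dtype=object)
    unknown = [e for e in set(elements) if str(e).upper() not in BONDI_RADII]
    if unknown:
        warnings.warn(f"unknown elements {sorted(map(str, unknown))}: "
                      f"using default vdW radius {DEFAULT_VDW} A")
    try:
        chains = np.array([str(c) for c in ag.chainIDs], dtype=object)
    except Exception:
        chains = np.array(["A"] * len(ag), dtype=object)
    return StructureModel(
        names=np.array([str(n) for n in ag.names], dtype=object),
        elements=elements,
        resnames=np.array([str(r) for r in ag.resnames], dtype=object),
        resids=np.array(ag.resids, dtype=int),
        chains=chains,
        coords=np.array(ag.positions, dtype=float),
    )


def _validate_pdb_text(path: Path) -> None:
    n_models = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                n_models += 1
                if n_models > 1:
                    raise StructureFormatError(
                        f"{path}:{lineno}: multi-model PDB not supported")
            if rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise StructureFormatError(
                        f"{path}:{lineno}: truncated {rec} record")
                altloc = line[16]
                icode = line[26]
                if altloc not in (" ", ""):
                    raise StructureFormatError(
                        f"{path}:{lineno}: altloc {altloc!r} not supported")
                if icode not in (" ", ""):
                    raise StructureFormatError(
                        f"{path}:{lineno}: insertion code {icode!r} not supported")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    raise StructureFormatError(
                        f"{path}:{lineno}: unparseable coordinates") from None


def write_structure(model: StructureModel, path) -> None:
    """Write a StructureModel as a PDB file."""
    u = model.to_universe()
    u.atoms.positions = model.coords.astype(np.float32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(path, format: str, reference: StructureModel,
                    frame_stride_ps: float | None = None) -> Trajectory:
    """Read a DCD/XTC/CSV trajectory against a reference structure."""
    fmt = format.upper()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "CSV":
        return _read_csv_trajectory(path, reference, frame_stride_ps)
    if fmt not in ("DCD", "XTC"):
        raise StructureFormatError(f"unsupported trajectory format {format!r}")
    import MDAnalysis as mda

    u = reference.to_universe()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u2 = mda.Universe.empty(reference.n_atoms, trajectory=True)
            u2.load_new(str(path), format=fmt)
        except Exception as exc:
            raise StructureFormatError(f"cannot read {path}: {exc}") from exc
        frames = np.array([u2.atoms.positions.copy() for _ in u2.trajectory],
                          dtype=float)
    del u
    if frames.size == 0:
        raise StructureFormatError(f"{path}: trajectory contains no frames")
    if frames.shape[1] != reference.n_atoms:
        raise ValueError(
            f"{path}: {frames.shape[1]} atoms per frame, reference has "
            f"{reference.n_atoms}")
    return Trajectory(reference, frames, frame_stride_ps)


def _read_csv_trajectory(path, reference, frame_stride_ps):
    import pandas as pd

    df = pd.read_csv(path)
    required = {"frame", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise StructureFormatError(
            f"{path}: CSV trajectory needs columns {sorted(required)}")
    if df.empty:
        raise StructureFormatError(f"{path}: trajectory contains no frames")
    n = reference.n_atoms
    frame_ids = np.sort(df["frame"].unique())
    frames = np.empty((len(frame_ids), n, 3), dtype=float)
    for k, f in enumerate(frame_ids):
        sub = df[df["frame"] == f].sort_values("atom")
        if len(sub) != n:
            raise ValueError(
                f"{path}: frame {f} has {len(sub)} atoms, expected {n}")
        frames[k] = sub[["x", "y", "z"]].to_numpy()
    return Trajectory(reference, frames, frame_stride_ps)


def write_trajectory(traj: Trajectory, path, format: str = "DCD") -> None:
    """Write a trajectory as DCD (binary) or CSV (plain-text frame dump)."""
    fmt = format.upper()
    if fmt == "CSV":
        import pandas as pd

        F, N, _ = traj.frames.shape
        frame_col = np.repeat(np.arange(F), N)
        atom_col = np.tile(np.arange(N), F)
        flat = traj.frames.reshape(-1, 3)
        pd.DataFrame({"frame": frame_col, "atom": atom_col,
                      "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
                     ).to_csv(path, index=False, float_format="%.6f")
        return
    if fmt != "DCD":
        raise StructureFormatError(f"unsupported trajectory format {format!r}")
    import MDAnalysis as mda

    u = traj.reference.to_universe()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, format="DCD") as w:
            for frame in traj.frames:
                u.atoms.positions = frame.astype(np.float32)
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Rigid-body operations

def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of `mobile` onto `target` (least squares).

    Returns (R, t) with ``mobile @ R.T + t`` minimizing the RMSD to target.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def superpose(traj: Trajectory, selection: Selection,
              reference_frame=0) -> Trajectory:
    """Least-squares superpose every frame onto a reference.

    The rigid transform is fit on `selection` atoms and applied to all atoms.
    `reference_frame` is either a frame index or an (N, 3) coordinate array
    in reference atom order.
    """
    idx = selection.indices
    if len(idx) < 3:
        raise DegenerateSelectionError(
            f"superposition needs >=3 atoms, got {len(idx)}")
    if np.isscalar(reference_frame):
        ref = traj.frames[int(reference_frame)]
    else:
        ref = np.asarray(reference_frame, float)
    ref_sel = ref[idx]
    centered = ref_sel - ref_sel.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateSelectionError(
            "selection atoms are collinear; superposition is underdetermined")
    out = np.empty_like(traj.frames)
    for k, frame in enumerate(traj.frames):
        R, t = kabsch(frame[idx], ref_sel)
        out[k] = frame @ R.T + t
    return Trajectory(traj.reference, out, traj.frame_stride_ps)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A rotation matrix uniform over SO(3) via unit-quaternion sampling."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def scramble(traj: Trajectory, seed: int,
             translation_scale: float = 50.0) -> Trajectory:
    """Positionally and orientationally scramble every frame.

    Each frame receives an independent uniform random rotation about its
    centroid plus a uniform random translation; internal geometry is
    preserved exactly. Used before image encoding so a classifier cannot
    exploit absolute pose.
    """
    rng = np.random.default_rng(seed)
    out = np.empty_like(traj.frames)
    for k, frame in enumerate(traj.frames):
        R = random_rotation(rng)
        t = rng.uniform(-translation_scale, translation_scale, size=3)
        c = frame.mean(axis=0)
        # re-place the centroid at a random point: no trace of original pose
        out[k] = (frame - c) @ R.T + t
    return Trajectory(traj.reference, out, traj.frame_stride_ps)
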