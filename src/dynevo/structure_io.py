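"""Static structures, conformational ensembles and rigid-body superposition.

The analysis operates on C-alpha traces only: a :class:`Structure` is an
ordered set of labelled sites with 3-D coordinates (in Angstrom), and a
:class:`Trajectory` is an ordered stack of frames over the same sites.
PDB reading/writing is delegated to biotite; a plain tabular format
(``frame site x y z``) is supported as a lightweight alternative for
ensembles that never lived in a PDB file.
"""
from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

#: Default set of residue names treated as hydrophobic. The set is
#: configurable in every operation that consumes it.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "CYS"}
)

_LABEL_RE = re.compile(r"^([A-Z0-9]{1,3})(-?\d+)$")


class StructureError(ValueError):
    """Malformed or inconsistent structural input."""


class DegenerateGeometryError(StructureError):
    """Geometry too degenerate (collinear/coincident) for superposition."""


def _as_coords(x, name="coords") -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise StructureError(f"{name} must be an (N, 3) array, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise StructureError(f"{name} contains non-finite values")
    return a


@dataclass
class Structure:
    """C-alpha trace of a single conformation.

    Sites are identified by residue name + 1-based residue number
    (e.g. ``"LEU29"``); labels are unique and strictly ordered by number.
    """

    res_numbers: np.ndarray          # (N,) int, strictly increasing
    res_names: list[str]             # (N,)
    coords: np.ndarray               # (N, 3) Angstrom
    hydrophobic: np.ndarray = field(default=None)  # (N,) bool

    def __post_init__(self):
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        self.coords = _as_coords(self.coords)
        n = len(self.res_numbers)
        if len(self.res_names) != n or len(self.coords) != n:
            raise StructureError("site arrays have inconsistent lengths")
        if n and np.any(np.diff(self.res_numbers) <= 0):
            raise StructureError("residue numbers must be unique and strictly increasing")
        if self.hydrophobic is None:
            self.hydrophobic = np.array(
                [name in HYDROPHOBIC_RESIDUES for name in self.res_names], dtype=bool
            )
        else:
            self.hydrophobic = np.asarray(self.hydrophobic, dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.res_numbers)

    @property
    def site_labels(self) -> list[str]:
        return [f"{nm}{no}" for nm, no in zip(self.res_names, self.res_numbers)]

    def subset(self, labels: Sequence[str]) -> "Structure":
        index = {lab: i for i, lab in enumerate(self.site_labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise StructureError(f"unknown site labels: {missing}")
        idx = [index[lab] for lab in labels]
        return Structure(
            self.res_numbers[idx],
            [self.res_names[i] for i in idx],
            self.coords[idx],
            self.hydrophobic[idx],
        )


@dataclass
class Trajectory:
    """Ordered conformational ensemble over a fixed set of sites."""

    frames: np.ndarray               # (T, N, 3) Angstrom
    res_numbers: np.ndarray
    res_names: list[str]
    frame_spacing: float = 1.0       # abstract time per frame; metadata only

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must be a (T, N, 3) array")
        if self.frames.shape[0] < 2:
            raise StructureError("a trajectory needs at least 2 frames")
        if self.frames.shape[1] != len(self.res_numbers):
            raise StructureError("frame width does not match the number of sites")
        if not np.all(np.isfinite(self.frames)):
            raise StructureError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_sites(self) -> int:
        return self.frames.shape[1]

    @property
    def site_labels(self) -> list[str]:
        return [f"{nm}{no}" for nm, no in zip(self.res_names, self.res_numbers)]

    def frame_structure(self, t: int) -> Structure:
        return Structure(self.res_numbers, list(self.res_names), self.frames[t])

    def slice(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(self.frames[start:stop], self.res_numbers,
                          list(self.res_names), self.frame_spacing)


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of a mobile coordinate set onto a reference."""

    rotation: np.ndarray     # (3, 3) proper rotation
    translation: np.ndarray  # (3,) Angstrom
    rmsd: float              # Angstrom, weighted

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return _as_coords(coords) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# PDB / table I/O
# ---------------------------------------------------------------------------

def _structure_from_atom_array(atoms, chain, hydrophobic_set, context=""):
    protein = atoms[~atoms.hetero]
    if len(protein) == 0:
        raise StructureError(f"no ATOM records found{context}")
    if chain is None:
        chain = protein.chain_id[0]
    protein = protein[protein.chain_id == chain]
    if len(protein) == 0:
        raise StructureError(f"chain {chain!r} not found{context}")
    ca = protein[protein.atom_name == "CA"]
    if len(ca) == 0:
        raise StructureError(f"no CA atoms found{context}")
    all_res = set(zip(protein.res_id.tolist(), protein.res_name.tolist()))
    ca_res = set(zip(ca.res_id.tolist(), ca.res_name.tolist()))
    skipped = sorted(all_res - ca_res)
    if skipped:
        warnings.warn(
            f"skipping residues without a CA atom{context}: "
            + ", ".join(f"{nm}{no}" for no, nm in skipped),
            stacklevel=3,
        )
    flags = np.array([nm in hydrophobic_set for nm in ca.res_name], dtype=bool)
    return Structure(np.asarray(ca.res_id), [str(n) for n in ca.res_name],
                     np.asarray(ca.coord, dtype=float), flags)


def read_structure(text: str, chain: str | None = None,
                   hydrophobic_set: frozenset = HYDROPHOBIC_RESIDUES) -> Structure:
    """Parse a PDB record stream into a C-alpha :class:`Structure`.

    One site per residue carrying a CA atom, in file order. Residues without
    a CA raise a warning and are skipped; a file with no CA atoms at all is
    an error. Only the first chain is used unless ``chain`` is given.
    """
    pdb = PDBFile.read(io.StringIO(text))
    atoms = pdb.get_structure(model=1)
    return _structure_from_atom_array(atoms, chain, hydrophobic_set)


def write_structure(s: Structure) -> str:
    """Render a C-alpha structure as a single-model PDB string."""
    atoms = bst.AtomArray(s.n_sites)
    atoms.coord = s.coords
    atoms.chain_id[:] = "A"
    atoms.res_id = s.res_numbers
    atoms.res_name = np.asarray(s.res_names)
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    atoms.hetero[:] = False
    pdb = PDBFile()
    pdb.set_structure(atoms)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def _looks_like_pdb(text: str) -> bool:
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec in {"ATOM", "HETATM", "MODEL"}:
            return True
        if rec and rec not in {"REMARK", "HEADER", "TITLE", "CRYST1", "EXPDTA"}:
            return False
    return False


def read_trajectory(text: str, chain: str | None = None,
                    hydrophobic_set: frozenset = HYDROPHOBIC_RESIDUES) -> Trajectory:
    """Parse a multi-model PDB or a ``frame site x y z`` table into a Trajectory.

    Every frame must expose the same sites in the same order; a mismatching
    frame raises :class:`StructureError` naming its (1-based) frame index.
    """
    if _looks_like_pdb(text):
        return _read_trajectory_pdb(text, chain, hydrophobic_set)
    return _read_trajectory_table(text, hydrophobic_set)


def _read_trajectory_pdb(text, chain, hydrophobic_set):
    pdb = PDBFile.read(io.StringIO(text))
    n_models = pdb.get_model_count()
    if n_models < 2:
        raise StructureError("a trajectory needs at least 2 frames (models)")
    structures = []
    ref_labels = None
    for m in range(1, n_models + 1):
        try:
            atoms = pdb.get_structure(model=m)
        except Exception as exc:  # biotite raises on ragged models
            raise StructureError(f"frame {m}: inconsistent atom records ({exc})") from exc
        s = _structure_from_atom_array(atoms, chain, hydrophobic_set,
                                       context=f" in frame {m}")
        if ref_labels is None:
            ref_labels = s.site_labels
        elif s.site_labels != ref_labels:
            raise StructureError(
                f"frame {m}: site set differs from frame 1 "
                f"({s.n_sites} vs {len(ref_labels)} sites)"
            )
        structures.append(s)
    first = structures[0]
    frames = np.stack([s.coords for s in structures])
    return Trajectory(frames, first.res_numbers, list(first.res_names))


def _read_trajectory_table(text, hydrophobic_set):
    header = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in header else ("," if "," in header else r"\s+")
    df = pd.read_csv(io.StringIO(text), sep=sep, float_precision="round_trip")
    expected = ["frame", "site", "x", "y", "z"]
    if list(df.columns) != expected:
        raise StructureError(f"coordinate table must have columns {expected}, "
                             f"got {list(df.columns)}")
    frame_ids = list(dict.fromkeys(df["frame"]))
    if len(frame_ids) < 2:
        raise StructureError("a trajectory needs at least 2 frames")
    ref_sites = None
    frames = []
    for k, fid in enumerate(frame_ids, start=1):
        sub = df[df["frame"] == fid]
        sites = list(sub["site"])
        if ref_sites is None:
            ref_sites = sites
        elif sites != ref_sites:
            raise StructureError(f"frame {k}: site set differs from frame 1")
        frames.append(sub[["x", "y", "z"]].to_numpy(dtype=float))
    numbers, names = [], []
    for lab in ref_sites:
        m = _LABEL_RE.match(str(lab))
        if not m:
            raise StructureError(f"unparseable site label {lab!r} "
                                 "(expected e.g. 'ALA12')")
        names.append(m.group(1))
        numbers.append(int(m.group(2)))
    return Trajectory(np.stack(frames), np.asarray(numbers), names)


def write_trajectory(traj: Trajectory, fmt: str = "table") -> str:
    """Serialize a trajectory; ``table`` round-trips coordinates bit-exactly."""
    if fmt == "table":
        labels = traj.site_labels
        rows = []
        for t in range(traj.n_frames):
            for i, lab in enumerate(labels):
                x, y, z = (float(v) for v in traj.frames[t, i])
                rows.append(f"{t}\t{lab}\t{x!r}\t{y!r}\t{z!r}")
        return "frame\tsite\tx\ty\tz\n" + "\n".join(rows) + "\n"
    if fmt == "pdb":
        stack = bst.AtomArrayStack(traj.n_frames, traj.n_sites)
        stack.coord = traj.frames
        stack.chain_id[:] = "A"
        stack.res_id = traj.res_numbers
        stack.res_name = np.asarray(traj.res_names)
        stack.atom_name[:] = "CA"
        stack.element[:] = "C"
        stack.hetero[:] = False
        pdb = PDBFile()
        pdb.set_structure(stack)
        buf = io.StringIO()
        pdb.write(buf)
        return buf.getvalue()
    raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(mobile, reference, weights=None) -> SuperpositionResult:
    """Optimal (Kabsch-type) weighted rigid-body superposition.

    Finds the proper rotation R and translation t minimizing the weighted
    RMSD between ``R @ mobile + t`` and ``reference``. Reflections are never
    returned. Collinear or coincident site sets are rejected because the
    optimal rotation is then not unique.
    """
    mobile = _as_coords(mobile, "mobile")
    reference = _as_coords(reference, "reference")
    if mobile.shape != reference.shape:
        raise StructureError(
            f"shape mismatch: mobile {mobile.shape} vs reference {reference.shape}")
    n = len(mobile)
    if n < 3:
        raise StructureError("superposition needs at least 3 sites")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise StructureError("weights must be non-negative with positive sum")
        w = w / w.sum()
    mob_c = w @ mobile
    ref_c = w @ reference
    a = reference - ref_c
    b = mobile - mob_c
    for name, arr in (("reference", a), ("mobile", b)):
        sv = np.linalg.svd(arr * np.sqrt(w)[:, None], compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise DegenerateGeometryError(
                f"{name} sites are (near-)collinear; rotation is not unique")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exact fits trigger a scipy notice
        rot, _ = Rotation.align_vectors(a, b, weights=w)
    rmat = rot.as_matrix()
    # recompute the residual directly; align_vectors' rssd loses precision
    # through cancellation on (near-)exact fits
    resid = b @ rmat.T - a
    rmsd = float(np.sqrt(np.sum(w * np.sum(resid * resid, axis=1))))
    translation = ref_c - rmat @ mob_c
    return SuperpositionResult(rotation=rmat, translation=translation, rmsd=rmsd)


def rmsd_between(a: Structure, b: Structure,
                 site_subset: Sequence[str] | None = None) -> float:
    """Minimum RMSD between two structures after superposing on a site subset."""
    if site_subset is not None:
        subset = list(site_subset)
        if not subset:
            raise StructureError("site subset is empty")
        a = a.subset(subset)
        b = b.subset(subset)
    else:
        if a.site_labels != b.site_labels:
            common = [lab for lab in a.site_labels if lab in set(b.site_labels)]
            if not common:
                raise StructureError("structures share no sites")
            a = a.subset(common)
            b = b.subset(common)
    return superpose(b.coords, a.coords).rmsd
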