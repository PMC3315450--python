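"""Shared dynamics space across proteins via the eigenvalue-weighted G matrix.

Each protein contributes its K slowest collective modes, restricted to the
alignment columns ungapped in every protein and weighted by their
eigenvalues, as columns of a common matrix G (3N' rows, P*K columns). The
singular value decomposition of G defines a low-dimensional "dynamics
space"; proteins whose most collective motions resemble each other land
close together in it, regardless of sequence identity.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .essential_dynamics import ModeSet

GAP = -1


class AlignmentError(ValueError):
    """Inconsistent residue-correspondence map."""


@dataclass
class AlignmentMap:
    """Residue correspondence across proteins.

    ``columns[c, p]`` is the 0-based site index of protein ``p`` at
    alignment column ``c``, or -1 for a gap. Internal indices never appear
    in reports; user-facing output uses per-protein site labels.
    """

    protein_ids: tuple[str, ...]
    columns: np.ndarray  # (n_columns, P) int

    def __post_init__(self):
        self.protein_ids = tuple(self.protein_ids)
        self.columns = np.asarray(self.columns, dtype=int)
        if self.columns.ndim != 2 or self.columns.shape[1] != len(self.protein_ids):
            raise AlignmentError("columns must be (n_columns, n_proteins)")
        for p, pid in enumerate(self.protein_ids):
            refs = self.columns[:, p]
            real = refs[refs != GAP]
            if len(np.unique(real)) != len(real):
                raise AlignmentError(f"protein {pid!r}: a site is referenced twice")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[0]

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def ungapped_columns(self) -> np.ndarray:
        """Indices of columns with a site in every protein."""
        return np.nonzero(np.all(self.columns != GAP, axis=1))[0]

    def protein_index(self, protein_id: str) -> int:
        try:
            return self.protein_ids.index(protein_id)
        except ValueError:
            raise AlignmentError(f"unknown protein {protein_id!r}") from None

    @classmethod
    def identity(cls, protein_ids: Sequence[str], n_sites: int) -> "AlignmentMap":
        """Gap-free 1:1 correspondence (same sites in every protein)."""
        cols = np.tile(np.arange(n_sites)[:, None], (1, len(protein_ids)))
        return cls(tuple(protein_ids), cols)

    @classmethod
    def from_fasta(cls, text: str) -> "AlignmentMap":
        """Build from an aligned FASTA ('-' marks gaps)."""
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise AlignmentError("no sequences in alignment")
        length = len(records[0].seq)
        if any(len(r.seq) != length for r in records):
            raise AlignmentError("aligned sequences differ in length")
        cols = np.full((length, len(records)), GAP, dtype=int)
        for p, rec in enumerate(records):
            i = 0
            for c, ch in enumerate(str(rec.seq)):
                if ch != "-":
                    cols[c, p] = i
                    i += 1
        return cls(tuple(r.id for r in records), cols)

    @classmethod
    def from_tsv(cls, text: str) -> "AlignmentMap":
        """Build from TSV ``column<TAB>idA_site<TAB>idB_site...``, '.' = gap.

        Site fields are 0-based site indices into each protein's site order.
        """
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[0] != "column":
            raise AlignmentError("first TSV column must be 'column'")
        ids = tuple(header[1:])
        rows = []
        for ln in lines[1:]:
            fields = ln.split("\t")
            rows.append([GAP if f == "." else int(f) for f in fields[1:]])
        return cls(ids, np.asarray(rows, dtype=int))


@dataclass
class GMatrix:
    """Eigenvalue-weighted multi-protein mode matrix over aligned sites."""

    matrix: np.ndarray                 # (3N', M)
    column_meta: list[dict]            # per column: protein_id, mode_rank, eigenvalue, coverage
    protein_ids: tuple[str, ...]
    k_modes: int
    aligned_columns: np.ndarray        # alignment-column indices used as rows

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class DynamicsSpace:
    """Low-dimensional embedding of proteins from the SVD of G.

    A protein's coordinates are the projections of its eigenvalue-weighted
    slowest-mode column onto the top ``d`` left singular vectors of G
    (``placement="slowest"``; ``"centroid"`` averages the projections of
    all of the protein's K columns instead).
    """

    singular_values: np.ndarray
    protein_coords: np.ndarray         # (P, d)
    protein_ids: tuple[str, ...]
    d: int
    placement: str = "slowest"
    basis: str = "left"                # projection basis recorded for reproducibility

    def to_csv(self) -> str:
        header = "protein," + ",".join(f"dim{i+1}" for i in range(self.d))
        lines = [header]
        for pid, row in zip(self.protein_ids, self.protein_coords):
            lines.append(pid + "," + ",".join(repr(float(v)) for v in row))
        return "\n".join(lines) + "\n"

    def sidecar_json(self) -> str:
        return json.dumps({
            "singular_values": self.singular_values.tolist(),
            "d": self.d,
            "placement": self.placement,
            "basis": self.basis,
            "protein_ids": list(self.protein_ids),
        })


def build_g_matrix(modesets: Mapping[str, ModeSet], align: AlignmentMap,
                   k_modes: int = 10) -> GMatrix:
    """Assemble G: one column per (protein, mode), restricted to aligned sites.

    Each column is the mode's eigenvector restricted to the 3 coordinates of
    every all-ungapped alignment column, multiplied by the mode's eigenvalue.
    Restricted vectors are NOT re-normalized; the retained norm is recorded
    per column as a coverage diagnostic. Column signs are canonicalized
    (largest-magnitude entry positive) so arbitrary eigenvector signs cannot
    move proteins in dynamics space.
    """
    ungapped = align.ungapped_columns()
    if len(ungapped) < 4:
        raise AlignmentError(
            f"need at least 4 all-ungapped alignment columns, got {len(ungapped)}")
    cols, meta = [], []
    for pid in align.protein_ids:
        if pid not in modesets:
            raise AlignmentError(f"no ModeSet for protein {pid!r}")
        ms = modesets[pid]
        if ms.n_modes < k_modes:
            raise AlignmentError(
                f"protein {pid!r} has {ms.n_modes} modes, need {k_modes}")
        p = align.protein_index(pid)
        site_idx = align.columns[ungapped, p]
        if site_idx.max() >= ms.n_sites:
            raise AlignmentError(
                f"alignment references site {site_idx.max()} of {pid!r}, "
                f"which has only {ms.n_sites} sites")
        for rank in range(1, k_modes + 1):
            v = ms.eigenvectors[:, rank - 1].reshape(-1, 3)[site_idx].ravel()
            coverage = float(np.linalg.norm(v))
            imax = int(np.argmax(np.abs(v)))
            if v[imax] < 0:
                v = -v
            lam = float(ms.eigenvalues[rank - 1])
            cols.append(lam * v)
            meta.append({"protein_id": pid, "mode_rank": rank,
                         "eigenvalue": lam, "coverage": coverage})
    return GMatrix(np.column_stack(cols), meta, align.protein_ids, k_modes, ungapped)


def svd_dynamics_space(g: GMatrix, d: int = 2,
                       placement: str = "slowest") -> DynamicsSpace:
    """Thin SVD of G and projection of each protein into ``d`` dimensions."""
    u, s, vt = np.linalg.svd(g.matrix, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    if d > rank:
        raise ValueError(f"requested {d} dimensions but G has rank {rank}")
    basis = u[:, :d]
    coords = np.empty((len(g.protein_ids), d))
    for p, pid in enumerate(g.protein_ids):
        own = [j for j, m in enumerate(g.column_meta) if m["protein_id"] == pid]
        if placement == "slowest":
            col = g.matrix[:, own[0]]   # mode_rank 1 comes first per protein
            coords[p] = basis.T @ col
        elif placement == "centroid":
            coords[p] = (basis.T @ g.matrix[:, own]).mean(axis=1)
        else:
            raise ValueError(f"unknown placement {placement!r}")
    return DynamicsSpace(singular_values=s, protein_coords=coords,
                         protein_ids=g.protein_ids, d=d, placement=placement)


def pairwise_dynamics_distance(space: DynamicsSpace) -> np.ndarray:
    """Symmetric matrix of Euclidean distances between protein coordinates."""
    x = space.protein_coords
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))
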