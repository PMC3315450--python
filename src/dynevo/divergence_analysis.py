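"""Per-site mutation-impact statistics on collective dynamics.

Given slowest-mode fluctuation profiles of three successively diverged
proteins A -> B -> C, the change in per-site fluctuation along each branch
(delta = profile_B - profile_A, etc.) feeds three screens:

* a two-way classification of sites by which branch dominates their
  dynamics change (parallel cutoff lines at +/- cutoff around the
  delta_ab = delta_bc diagonal);
* the net absolute change dd = || |delta_ab| - |delta_bc| ||, whose
  exceedance of a cutoff (default 0.002 A^2) flags sites as critical to
  the functional divergence;
* residue-residue cross-correlation maps and block summaries, and a static
  mean-square-displacement screen between superposed structures
  (default cutoff 6 A^2).

All statistics are indexed by alignment column so insertions/deletions are
handled in one place; a deleted site is reported through its flanking
columns.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics_space import GAP, AlignmentMap
from .essential_dynamics import FluctuationProfile, ModeSet, align_and_center, covariance
from .structure_io import Structure, Trajectory, superpose

#: Default criticality cutoff on |delta-delta fluctuation|, Angstrom^2.
DEFAULT_DD_CUTOFF = 0.002
#: Default cutoff for the static mean-square-displacement screen, Angstrom^2.
DEFAULT_MSD_CUTOFF = 6.0
#: Mean per-site slowest-mode fluctuation (A^2) at which the default dd
#: cutoff is calibrated; see ``scale_dd_cutoff``.
DD_REFERENCE_SCALE = 0.002


@dataclass
class DeltaProfile:
    """Per-alignment-column signed fluctuation change (B minus A), A^2.

    ``values`` is NaN at columns gapped in either protein; ``flank_notes``
    annotates the columns flanking each deletion, mirroring the convention
    of reporting a deleted site through its neighbours.
    """

    values: np.ndarray
    gap_mask: np.ndarray
    flank_notes: dict[int, str]


@dataclass
class CrossCorrelationMatrix:
    """Normalized residue-residue displacement correlations, values in [-1, 1]."""

    values: np.ndarray
    site_labels: list[str] | None = None

    def to_csv(self) -> str:
        labels = self.site_labels or [str(i) for i in range(len(self.values))]
        lines = ["site," + ",".join(labels)]
        for lab, row in zip(labels, self.values):
            lines.append(lab + "," + ",".join(repr(float(v)) for v in row))
        return "\n".join(lines) + "\n"


def delta_fluctuation(profile_a: FluctuationProfile, profile_b: FluctuationProfile,
                      align: AlignmentMap, protein_a: int | str = 0,
                      protein_b: int | str = 1) -> DeltaProfile:
    """Signed per-column fluctuation change, profile_b - profile_a (A^2)."""
    pa = align.protein_index(protein_a) if isinstance(protein_a, str) else protein_a
    pb = align.protein_index(protein_b) if isinstance(protein_b, str) else protein_b
    cols_a = align.columns[:, pa]
    cols_b = align.columns[:, pb]
    for name, cols, prof in (("A", cols_a, profile_a), ("B", cols_b, profile_b)):
        real = cols[cols != GAP]
        if len(real) and real.max() >= len(prof.values):
            raise ValueError(
                f"alignment references site {real.max()} of protein {name}, "
                f"but its profile has {len(prof.values)} sites")
    gap = (cols_a == GAP) | (cols_b == GAP)
    values = np.full(align.n_columns, np.nan)
    ok = ~gap
    values[ok] = profile_b.values[cols_b[ok]] - profile_a.values[cols_a[ok]]
    notes: dict[int, str] = {}
    for c in np.nonzero(gap)[0]:
        for flank in (c - 1, c + 1):
            if 0 <= flank < align.n_columns and not gap[flank]:
                notes[int(flank)] = f"flanks deletion at column {int(c)}"
    return DeltaProfile(values=values, gap_mask=gap, flank_notes=notes)


def classify_two_way(delta_ab: np.ndarray, delta_bc: np.ndarray,
                     cutoff: float = DEFAULT_DD_CUTOFF) -> np.ndarray:
    """Label each column by which branch dominates its dynamics change.

    ``upper_left``  : delta_bc - delta_ab > cutoff (B->C branch dominates),
    ``lower_right`` : delta_ab - delta_bc > cutoff (A->B branch dominates),
    ``central``     : within the +/-cutoff band around the diagonal.
    Columns with NaN deltas (deletions) are labelled ``deleted``.
    """
    delta_ab = np.asarray(delta_ab, dtype=float)
    delta_bc = np.asarray(delta_bc, dtype=float)
    if delta_ab.shape != delta_bc.shape:
        raise ValueError("delta arrays must have equal length")
    labels = np.full(delta_ab.shape, "central", dtype=object)
    diff = delta_bc - delta_ab
    labels[diff > cutoff] = "upper_left"
    labels[-diff > cutoff] = "lower_right"
    labels[np.isnan(diff)] = "deleted"
    return labels


def scale_dd_cutoff(profiles: Sequence[FluctuationProfile],
                    base_cutoff: float = DEFAULT_DD_CUTOFF,
                    reference_scale: float = DD_REFERENCE_SCALE) -> float:
    """Rescale the dd cutoff to the fluctuation magnitude of an ensemble set.

    The default cutoff is calibrated to the reference magnitude
    ``reference_scale`` (mean per-site slowest-mode fluctuation, A^2/site)
    and scales proportionally with the observed pooled magnitude. With the
    defaults (base == reference) the screen reads: a site is critical when
    its net change in slow-mode fluctuation exceeds the average site's
    entire slow-mode fluctuation — a scale-free criterion that sits above
    the collateral mode-renormalization any localized stiffness change
    spreads onto the remaining flexible sites.
    """
    pooled = float(np.mean([np.mean(p.values) for p in profiles]))
    return base_cutoff * pooled / reference_scale


def delta_delta(delta_ab: DeltaProfile | np.ndarray,
                delta_bc: DeltaProfile | np.ndarray,
                align: AlignmentMap,
                site_labels: Mapping[str, Sequence[str]] | None = None,
                cutoff: float = DEFAULT_DD_CUTOFF,
                mutated_sites: Sequence[str] = ()) -> pd.DataFrame:
    """Per-column site-divergence report.

    dd = abs(abs(delta_ab) - abs(delta_bc)); a column is critical when
    dd > cutoff. ``mutated_sites`` are site labels (in any protein's
    labelling); unknown labels raise an error listing them. Returns a
    DataFrame sorted by alignment column with columns
    ``column, site_<id>..., delta_ab, delta_bc, dd, region, critical,
    mutated, note``.
    """
    d_ab = delta_ab.values if isinstance(delta_ab, DeltaProfile) else np.asarray(delta_ab, float)
    d_bc = delta_bc.values if isinstance(delta_bc, DeltaProfile) else np.asarray(delta_bc, float)
    if d_ab.shape != d_bc.shape or len(d_ab) != align.n_columns:
        raise ValueError("delta arrays must match the alignment length")
    dd = np.abs(np.abs(d_ab) - np.abs(d_bc))
    region = classify_two_way(d_ab, d_bc, cutoff)
    critical = dd > cutoff
    critical[np.isnan(dd)] = False

    per_protein_labels: dict[str, list[str]] = {}
    for p, pid in enumerate(align.protein_ids):
        labs = []
        for c in range(align.n_columns):
            s = align.columns[c, p]
            if s == GAP:
                labs.append("-")
            elif site_labels is not None and pid in site_labels:
                labs.append(site_labels[pid][s])
            else:
                labs.append(str(s))
        per_protein_labels[pid] = labs

    label_to_cols: dict[str, set[int]] = {}
    for pid, labs in per_protein_labels.items():
        for c, lab in enumerate(labs):
            if lab != "-":
                label_to_cols.setdefault(lab, set()).add(c)
    unknown = [m for m in mutated_sites if m not in label_to_cols]
    if unknown:
        raise ValueError(f"unknown mutated-site labels: {unknown}")
    mutated_cols: set[int] = set()
    for m in mutated_sites:
        mutated_cols |= label_to_cols[m]

    notes = []
    flank = {}
    for dp in (delta_ab, delta_bc):
        if isinstance(dp, DeltaProfile):
            flank.update(dp.flank_notes)
    for c in range(align.n_columns):
        notes.append(flank.get(c, ""))

    data = {"column": np.arange(align.n_columns)}
    for pid in align.protein_ids:
        data[f"site_{pid}"] = per_protein_labels[pid]
    data.update({
        "delta_ab": d_ab, "delta_bc": d_bc, "dd": dd,
        "region": region,
        "critical": critical,
        "mutated": [c in mutated_cols for c in range(align.n_columns)],
        "note": notes,
    })
    df = pd.DataFrame(data)
    df.attrs["cutoff_A2"] = cutoff
    return df


def cross_correlation(source: Trajectory | ModeSet,
                      site_labels: Sequence[str] | None = None,
                      prealigned: bool = False) -> CrossCorrelationMatrix:
    """Dynamic cross-correlation map (DCCM).

    values(i, j) = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) with dr_i the
    3-vector displacement of site i. From a :class:`ModeSet`, <dr_i dr_j>
    is reconstructed as sum_k lambda_k v_ki v_kj^T traced over x, y, z
    (exact when all modes are retained). From a :class:`Trajectory`, the
    trajectory is rigid-body aligned first unless ``prealigned``.
    """
    if isinstance(source, ModeSet):
        n = source.n_sites
        v = source.eigenvectors.reshape(n, 3, source.n_modes)
        # block trace: sum over xyz of C[3i+a, 3j+a]
        m = np.einsum("iak,jak,k->ij", v, v, source.eigenvalues)
        if site_labels is None:
            site_labels = [str(i) for i in range(n)]
    else:
        traj = source if prealigned else align_and_center(source)
        c = covariance(traj)
        n = traj.n_sites
        blocks = c.reshape(n, 3, n, 3)
        m = np.einsum("iaja->ij", blocks)
        if site_labels is None:
            site_labels = traj.site_labels
    var = np.diag(m).copy()
    bad = np.nonzero(var <= 1e-14 * max(var.max(), 1.0))[0]
    if len(bad):
        raise ValueError(f"zero-variance site(s): {[site_labels[i] for i in bad]}")
    ccm = m / np.sqrt(np.outer(var, var))
    ccm = np.clip(ccm, -1.0, 1.0)
    np.fill_diagonal(ccm, 1.0)
    return CrossCorrelationMatrix(values=ccm, site_labels=list(site_labels))


def submatrix_mean_correlation(ccm: CrossCorrelationMatrix,
                               rows: Sequence[int | str],
                               cols: Sequence[int | str]) -> float:
    """Mean correlation over a rows x cols block, excluding diagonal entries."""
    def _resolve(items):
        out = []
        for it in items:
            if isinstance(it, str):
                if ccm.site_labels is None or it not in ccm.site_labels:
                    raise ValueError(f"unknown site label {it!r}")
                out.append(ccm.site_labels.index(it))
            else:
                out.append(int(it))
        return out

    r = _resolve(rows)
    c = _resolve(cols)
    if not r or not c:
        raise ValueError("row/column site sets must be non-empty")
    vals = [ccm.values[i, j] for i in r for j in c if i != j]
    if not vals:
        raise ValueError("block contains only diagonal entries")
    return float(np.mean(vals))


def static_msd(a: Structure, b: Structure, align: AlignmentMap,
               cutoff: float = DEFAULT_MSD_CUTOFF,
               protein_a: int | str = 0, protein_b: int | str = 1) -> pd.DataFrame:
    """Squared displacement per aligned site between two superposed structures.

    Structure ``b`` is superposed onto ``a`` over all ungapped columns; the
    report flags columns whose squared displacement exceeds ``cutoff``
    (default 6 A^2), a coarse screen for residues repacking into distinct
    static conformations.
    """
    pa = align.protein_index(protein_a) if isinstance(protein_a, str) else protein_a
    pb = align.protein_index(protein_b) if isinstance(protein_b, str) else protein_b
    ungapped = align.ungapped_columns()
    if len(ungapped) < 3:
        raise ValueError("need at least 3 ungapped columns to superpose")
    ia = align.columns[ungapped, pa]
    ib = align.columns[ungapped, pb]
    ca = a.coords[ia]
    cb = superpose(b.coords[ib], ca).apply(b.coords[ib])
    msd = np.sum((cb - ca) ** 2, axis=1)
    df = pd.DataFrame({
        "column": ungapped,
        "site_a": [a.site_labels[i] for i in ia],
        "site_b": [b.site_labels[i] for i in ib],
        "msd_A2": msd,
        "flagged": msd > cutoff,
    })
    df.attrs["cutoff_A2"] = cutoff
    return df
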