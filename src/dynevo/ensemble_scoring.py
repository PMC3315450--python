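"""Scoring, clustering and consensus-contact bookkeeping for candidate folds.

Candidate collapsed conformations are ranked by two complementary packing
criteria — radius of gyration of the hydrophobic residues (compact is
better) and the number of hydrophobic contacts closer than 7.0 A (more is
better) — combined by rank sum. Representative structures come from a
deterministic leader clustering at 1.0 A RMSD radius. Contact maps from
aligned modern-day homologs are intersected into a consensus map in a
common numbering.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import Structure, StructureError, superpose

DEFAULT_CONTACT_CUTOFF = 7.0   # Angstrom, strict inequality
DEFAULT_CLUSTER_RADIUS = 1.0   # Angstrom RMSD

#: Secondary-structure labels treated as loop (excluded from contacts when
#: loop exclusion is enabled).
LOOP_LABELS = frozenset({"loop", "l", "c", "-", ""})


@dataclass(frozen=True)
class ContactMap:
    """Unordered site-label pairs within a distance cutoff."""

    pairs: frozenset  # of 2-tuples (sorted site labels)
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    kind: str = "distance"

    def __post_init__(self):
        for p in self.pairs:
            if p[0] == p[1]:
                raise ValueError(f"self-pair {p} in contact map")

    @staticmethod
    def make(pairs, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> "ContactMap":
        norm = frozenset(tuple(sorted(map(str, p))) for p in pairs)
        return ContactMap(pairs=norm, cutoff=cutoff)

    def to_tsv(self) -> str:
        lines = ["site_i\tsite_j"]
        lines += [f"{i}\t{j}" for i, j in sorted(self.pairs)]
        return "\n".join(lines) + "\n"

    @staticmethod
    def from_tsv(text: str, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> "ContactMap":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if lines and lines[0].startswith("site_i"):
            lines = lines[1:]
        return ContactMap.make((ln.split("\t") for ln in lines), cutoff)


@dataclass
class ClusterResult:
    labels: np.ndarray        # cluster index per input structure
    medoids: list[int]        # index of the post-hoc medoid of each cluster
    leaders: list[int]        # index of the founding member of each cluster
    assignment_rmsd: np.ndarray  # RMSD to the leader at assignment time


def hydrophobic_rg(s: Structure) -> float:
    """Radius of gyration of the hydrophobic C-alpha sites (Angstrom)."""
    coords = s.coords[s.hydrophobic]
    if len(coords) == 0:
        raise StructureError("structure has no hydrophobic sites")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered * centered, axis=1))))


def count_hydrophobic_contacts(s: Structure,
                               cutoff: float = DEFAULT_CONTACT_CUTOFF,
                               ss_labels: Mapping[str, str] | None = None,
                               exclude_loops: bool = True,
                               exclude_same_element: bool = True) -> int:
    """Number of hydrophobic site pairs strictly closer than ``cutoff``.

    When secondary-structure labels are supplied, hydrophobic residues in
    loops are ignored and pairs within the same secondary element are not
    counted (both rules individually switchable). Without labels, all
    hydrophobic pairs are eligible.
    """
    idx = np.nonzero(s.hydrophobic)[0]
    labels = s.site_labels
    if ss_labels is not None and exclude_loops:
        idx = np.array([i for i in idx
                        if str(ss_labels.get(labels[i], "loop")).lower()
                        not in LOOP_LABELS], dtype=int)
    count = 0
    for ai in range(len(idx)):
        for bi in range(ai + 1, len(idx)):
            i, j = idx[ai], idx[bi]
            if ss_labels is not None and exclude_same_element:
                ei = ss_labels.get(labels[i])
                ej = ss_labels.get(labels[j])
                if ei is not None and ei == ej:
                    continue
            if np.linalg.norm(s.coords[i] - s.coords[j]) < cutoff:
                count += 1
    return count


def score_and_rank(ensemble: Sequence[Structure],
                   contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                   ss_labels: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Score every structure and rank by rank sum.

    Ranks: radius of gyration ascending (compact first) plus contact count
    descending (many first), minimum rank for ties. Final ordering breaks
    rank-sum ties by rg, then by input order. Returns a DataFrame in input
    order with columns ``rg_hydrophobic, n_contacts, rank``; rank 1 is best.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    rg = np.array([hydrophobic_rg(s) for s in ensemble])
    nc = np.array([count_hydrophobic_contacts(s, contact_cutoff, ss_labels)
                   for s in ensemble])
    rg_rank = np.array([1 + np.sum(rg < v) for v in rg])
    nc_rank = np.array([1 + np.sum(nc > v) for v in nc])
    combined = rg_rank + nc_rank
    order = sorted(range(len(ensemble)), key=lambda i: (combined[i], rg[i], i))
    final = np.empty(len(ensemble), dtype=int)
    for pos, i in enumerate(order, start=1):
        final[i] = pos
    return pd.DataFrame({"rg_hydrophobic": rg, "n_contacts": nc, "rank": final})


def cluster_representatives(ensemble: Sequence[Structure],
                            radius: float = DEFAULT_CLUSTER_RADIUS) -> ClusterResult:
    """Deterministic leader clustering in RMSD space.

    Structures are scanned in input order; each joins the first existing
    cluster whose founding member (leader) is within ``radius`` RMSD, else
    founds a new cluster. After the scan, each cluster's medoid is the
    member minimizing total intra-cluster RMSD (the medoid may differ from
    the leader; assignment-time consistency is recorded per member).
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    labels = np.full(len(ensemble), -1, dtype=int)
    assignment_rmsd = np.zeros(len(ensemble))
    leaders: list[int] = []
    for i, s in enumerate(ensemble):
        for ci, li in enumerate(leaders):
            r = superpose(s.coords, ensemble[li].coords).rmsd
            if r <= radius:
                labels[i] = ci
                assignment_rmsd[i] = r
                break
        else:
            leaders.append(i)
            labels[i] = len(leaders) - 1
    medoids = []
    for ci in range(len(leaders)):
        members = np.nonzero(labels == ci)[0]
        if len(members) == 1:
            medoids.append(int(members[0]))
            continue
        totals = []
        for m in members:
            totals.append(sum(superpose(ensemble[m].coords,
                                        ensemble[o].coords).rmsd
                              for o in members if o != m))
        medoids.append(int(members[int(np.argmin(totals))]))
    return ClusterResult(labels=labels, medoids=medoids, leaders=leaders,
                         assignment_rmsd=assignment_rmsd)


def contact_map_from_structure(s: Structure,
                               cutoff: float = DEFAULT_CONTACT_CUTOFF,
                               hydrophobic_only: bool = False) -> ContactMap:
    """All site pairs strictly closer than ``cutoff`` (convenience builder)."""
    labels = s.site_labels
    idx = np.nonzero(s.hydrophobic)[0] if hydrophobic_only else np.arange(s.n_sites)
    pairs = set()
    for ai in range(len(idx)):
        for bi in range(ai + 1, len(idx)):
            i, j = idx[ai], idx[bi]
            if np.linalg.norm(s.coords[i] - s.coords[j]) < cutoff:
                pairs.add(tuple(sorted((labels[i], labels[j]))))
    return ContactMap.make(pairs, cutoff)


def consensus_contact_map(homolog_maps: Mapping[str, ContactMap],
                          aligns: Mapping[str, Mapping[str, str]]) -> ContactMap:
    """Intersect homolog contact maps in a common numbering.

    ``aligns[homolog]`` maps that homolog's site labels to target labels;
    pairs touching an unaligned (gapped) site are dropped before the
    intersection. A homolog without an alignment is an error.
    """
    if not homolog_maps:
        raise ValueError("no contact maps supplied")
    translated = []
    cutoff = None
    for hid, cmap in homolog_maps.items():
        if hid not in aligns:
            raise ValueError(f"no alignment for homolog {hid!r}")
        table = aligns[hid]
        pairs = set()
        for i, j in cmap.pairs:
            if i in table and j in table:
                pairs.add(tuple(sorted((table[i], table[j]))))
        translated.append(pairs)
        cutoff = cmap.cutoff if cutoff is None else cutoff
    consensus = set.intersection(*translated)
    return ContactMap.make(consensus, cutoff)
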