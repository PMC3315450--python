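"""End-to-end orchestration: ensembles in, versioned report bundle out.

Per protein: windowed PCA and a convergence verdict (non-convergence is a
gate, not a warning — downstream stages refuse to run without ``force``).
Across proteins: the shared dynamics space, pairwise distances, the
per-site divergence report, and cross-correlation matrices. Every report
embeds the resolved configuration and package version, and reruns with the
same config and seeds are byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .divergence_analysis import (DEFAULT_DD_CUTOFF, DEFAULT_MSD_CUTOFF,
                                  cross_correlation, delta_delta,
                                  delta_fluctuation)
from .dynamics_space import (AlignmentMap, build_g_matrix,
                             pairwise_dynamics_distance, svd_dynamics_space)
from .ensemble_scoring import DEFAULT_CLUSTER_RADIUS, DEFAULT_CONTACT_CUTOFF
from .essential_dynamics import (DEFAULT_PEARSON_CUTOFF, WindowSpec,
                                 check_convergence, fluctuation_profile,
                                 sliding_window_pca, trajectory_modes)
from .structure_io import Trajectory, read_trajectory


class NonConvergenceError(RuntimeError):
    """An ensemble failed the convergence gate."""


@dataclass
class RunConfig:
    """Resolved configuration of a full analysis run.

    All cutoff defaults are the analysis' canonical values: Pearson 0.8,
    dd 0.002 A^2, MSD 6 A^2, contacts 7.0 A, cluster radius 1.0 A, top 10
    modes in the G matrix, at most 30 modes retained per window.
    """

    ensembles: dict = field(default_factory=dict)   # protein id -> path
    alignment: str | None = None                    # path (FASTA or TSV); None = identity
    mutated_sites: list = field(default_factory=list)
    window_length: int = 500
    window_stride: int = 250
    min_windows_converged: int = 4
    k_modes: int = 10
    n_modes_kept: int = 30
    pearson_cutoff: float = DEFAULT_PEARSON_CUTOFF
    dd_cutoff: float = DEFAULT_DD_CUTOFF
    msd_cutoff: float = DEFAULT_MSD_CUTOFF
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS
    seed: int = 0
    out_dir: str = "dynevo_out"

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["dynevo_version"] = __version__
        return d


def run_full_analysis(cfg: RunConfig, trajectories: dict | None = None,
                      align: AlignmentMap | None = None,
                      force: bool = False) -> dict:
    """Run every stage and write the report bundle to ``cfg.out_dir``.

    ``trajectories`` may be supplied directly (label -> Trajectory);
    otherwise they are read from ``cfg.ensembles`` paths. Returns a summary
    dict with the main in-memory results.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if trajectories is None:
        trajectories = {}
        for pid, path in cfg.ensembles.items():
            trajectories[pid] = read_trajectory(Path(path).read_text())
    ids = list(trajectories)
    if align is None:
        if cfg.alignment is not None:
            text = Path(cfg.alignment).read_text()
            if text.lstrip().startswith(">"):
                align = AlignmentMap.from_fasta(text)
            else:
                align = AlignmentMap.from_tsv(text)
        else:
            n_sites = trajectories[ids[0]].n_sites
            align = AlignmentMap.identity(ids, n_sites)

    spec = WindowSpec(cfg.window_length, cfg.window_stride,
                      cfg.min_windows_converged)
    modesets, convergences = {}, {}
    for pid, traj in trajectories.items():
        windows = sliding_window_pca(traj, spec, n_modes=cfg.n_modes_kept)
        conv = check_convergence(windows, spec, threshold=cfg.pearson_cutoff)
        # comparative stages consume the full-trajectory modes (lowest noise)
        modesets[pid] = trajectory_modes(traj, n_modes=cfg.n_modes_kept)
        convergences[pid] = conv
        (out / f"modes_{pid}.json").write_text(modesets[pid].to_json())
        (out / f"convergence_{pid}.json").write_text(json.dumps({
            "protein": pid,
            "pearson_by_pair": conv.pearson_by_pair.tolist(),
            "converged": conv.converged,
            "converged_at": conv.converged_at,
            "threshold": conv.threshold,
        }))
    unconverged = [pid for pid, c in convergences.items() if not c.converged]
    if unconverged and not force:
        raise NonConvergenceError(
            f"unconverged ensembles: {unconverged}; sample more frames and "
            "rerun, or pass force=True")

    g = build_g_matrix(modesets, align, k_modes=cfg.k_modes)
    space = svd_dynamics_space(g)
    dist = pairwise_dynamics_distance(space)
    (out / "dynamics_space.csv").write_text(space.to_csv())
    (out / "dynamics_space.json").write_text(space.sidecar_json())
    (out / "g_matrix_meta.json").write_text(json.dumps({
        "n_columns": g.n_columns, "k_modes": g.k_modes,
        "column_meta": g.column_meta,
    }))
    dist_lines = ["protein," + ",".join(ids)]
    for pid, row in zip(ids, dist):
        dist_lines.append(pid + "," + ",".join(repr(float(v)) for v in row))
    (out / "dynamics_distances.csv").write_text("\n".join(dist_lines) + "\n")

    report = None
    if len(ids) >= 3:
        a, b, c = ids[:3]
        profiles = {pid: fluctuation_profile(modesets[pid], 1) for pid in ids}
        labels = {pid: trajectories[pid].site_labels for pid in ids}
        d_ab = delta_fluctuation(profiles[a], profiles[b], align, a, b)
        d_bc = delta_fluctuation(profiles[b], profiles[c], align, b, c)
        report = delta_delta(d_ab, d_bc, align, site_labels=labels,
                             cutoff=cfg.dd_cutoff,
                             mutated_sites=cfg.mutated_sites)
        header = (f"# dd_cutoff_A2={cfg.dd_cutoff} msd_cutoff_A2={cfg.msd_cutoff} "
                  f"dynevo={__version__}\n")
        (out / "site_divergence.csv").write_text(header + report.to_csv(index=False))

    ccms = {}
    for pid in ids:
        ccm = cross_correlation(modesets[pid],
                                site_labels=trajectories[pid].site_labels)
        ccms[pid] = ccm
        (out / f"ccm_{pid}.csv").write_text(ccm.to_csv())

    (out / "run_config.json").write_text(json.dumps(cfg.resolved(), indent=2,
                                                    sort_keys=True))
    return {"modesets": modesets, "convergence": convergences, "g_matrix": g,
            "dynamics_space": space, "distances": dist, "report": report,
            "ccms": ccms, "alignment": align}
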