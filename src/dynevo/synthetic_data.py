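"""Synthetic conformational ensembles with known ground truth.

An anisotropic elastic network model (ANM) over an idealized C-alpha chain
supplies an analytic positional covariance (the pseudo-inverse of the
spring-network Hessian with rigid modes removed). Ensembles are drawn from
the corresponding stationary Gaussian, optionally contaminated with random
rigid-body motion per frame. Site-localized "mutations" are planted by
rescaling the stiffness of all springs incident to chosen sites, and
inter-region couplings by adding a rank-1 shared-motion term — giving every
analysis stage a scenario whose true perturbed sites, slow modes and
couplings are known exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .structure_io import Structure, Trajectory

DEFAULT_EDGE_CUTOFF = 10.0   # Angstrom
RIGID_MODE_TOL = 1e-8        # eigenvalues below tol * max are rigid modes

# Residue-name cycle for toy chains: mixes hydrophobic and polar residues.
_TOY_RESIDUES = ("ALA", "GLY", "LEU", "SER", "VAL", "GLU", "ILE", "LYS",
                 "PHE", "THR")


class ModelError(ValueError):
    """Invalid elastic-network construction."""


def make_toy_chain(n_sites: int, geometry: str = "helix-loop-helix") -> Structure:
    """Idealized C-alpha trace with ~3.8 A consecutive spacing.

    Geometries: ``extended`` (straight line), ``helix`` (ideal alpha-helix:
    2.3 A radius, 1.5 A rise, 100 degrees per residue), and
    ``helix-loop-helix`` (two antiparallel helices joined by an extended
    loop). Deterministic given its arguments.
    """
    if n_sites < 4:
        raise ValueError("toy chain needs at least 4 sites")
    if geometry == "extended":
        coords = np.zeros((n_sites, 3))
        coords[:, 0] = 3.8 * np.arange(n_sites)
    elif geometry == "helix":
        coords = _helix_coords(n_sites)
    elif geometry == "helix-loop-helix":
        n_loop = max(2, n_sites // 6)
        n_h1 = (n_sites - n_loop + 1) // 2
        n_h2 = n_sites - n_loop - n_h1
        h1 = _helix_coords(n_h1)
        loop = np.zeros((n_loop, 3))
        loop[:, 0] = 3.8 * (1 + np.arange(n_loop))
        loop += h1[-1]
        h2 = _helix_coords(n_h2)[::-1] * np.array([1.0, -1.0, -1.0])
        h2 = h2 - h2[0] + loop[-1] + np.array([3.8, 0.0, 0.0])
        coords = np.vstack([h1, loop, h2])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    names = [_TOY_RESIDUES[i % len(_TOY_RESIDUES)] for i in range(n_sites)]
    return Structure(np.arange(1, n_sites + 1), names, coords)


def _helix_coords(n: int) -> np.ndarray:
    # right-handed alpha-helix CA trace: 2.3 A radius, 1.5 A rise,
    # 100 degrees per residue (virtual CA dihedral ~ +50 degrees)
    radius, rise, turn = 2.3, 1.5, np.deg2rad(-100.0)
    t = np.arange(n)
    return np.column_stack([radius * np.cos(turn * t),
                            radius * np.sin(turn * t),
                            rise * t])


@dataclass
class ENMModel:
    """Elastic network over fixed node coordinates.

    Springs connect all site pairs within ``edge_cutoff``; per-edge
    stiffness defaults to 1 (arbitrary units). ``temperature_scale`` sets
    the overall fluctuation magnitude (A^2) of the implied covariance.
    """

    node_coords: np.ndarray            # (N, 3) Angstrom
    edges: np.ndarray                  # (E, 2) int
    stiffness: np.ndarray              # (E,) > 0
    temperature_scale: float = 1.0

    def __post_init__(self):
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        self.stiffness = np.asarray(self.stiffness, dtype=float)
        if np.any(self.stiffness <= 0):
            raise ModelError("all spring constants must be positive")
        n = len(self.node_coords)
        adj = csr_matrix((np.ones(len(self.edges)),
                          (self.edges[:, 0], self.edges[:, 1])), shape=(n, n))
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ModelError(f"elastic network is disconnected ({n_comp} components)")

    @property
    def n_sites(self) -> int:
        return len(self.node_coords)


def build_enm(structure: Structure | np.ndarray,
              edge_cutoff: float = DEFAULT_EDGE_CUTOFF,
              stiffness: float = 1.0,
              temperature_scale: float = 1.0) -> ENMModel:
    """Construct a uniform-stiffness network from a structure's C-alpha trace."""
    coords = structure.coords if isinstance(structure, Structure) else np.asarray(structure, float)
    d = squareform(pdist(coords))
    i, j = np.nonzero(np.triu(d < edge_cutoff, k=1))
    edges = np.column_stack([i, j])
    return ENMModel(coords, edges, np.full(len(edges), float(stiffness)),
                    temperature_scale)


def enm_covariance(model: ENMModel) -> np.ndarray:
    """Analytic 3N x 3N covariance: pseudo-inverse of the ANM Hessian.

    The six near-zero rigid-body eigenvalues (below 1e-8 x largest) are
    removed; the result is scaled by ``temperature_scale``.
    """
    n = model.n_sites
    h = np.zeros((3 * n, 3 * n))
    for (i, j), k in zip(model.edges, model.stiffness):
        d = model.node_coords[i] - model.node_coords[j]
        e = d / np.linalg.norm(d)
        block = k * np.outer(e, e)
        h[3*i:3*i+3, 3*i:3*i+3] += block
        h[3*j:3*j+3, 3*j:3*j+3] += block
        h[3*i:3*i+3, 3*j:3*j+3] -= block
        h[3*j:3*j+3, 3*i:3*i+3] -= block
    vals, vecs = np.linalg.eigh(h)
    keep = vals > RIGID_MODE_TOL * vals[-1]
    inv = vecs[:, keep] / vals[keep]
    return model.temperature_scale * (inv @ vecs[:, keep].T)


def perturb_model(model: ENMModel, sites: Sequence[int], factor: float) -> ENMModel:
    """Multiply the stiffness of every spring incident to ``sites`` by ``factor``.

    factor > 1 rigidifies the sites (smaller fluctuations), factor < 1
    loosens them. Returns a new model; the input is untouched.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("empty site list")
    if min(sites) < 0 or max(sites) >= model.n_sites:
        raise ValueError(f"site indices out of range 0..{model.n_sites - 1}")
    if factor <= 0:
        raise ValueError("stiffness factor must be positive")
    mask = np.isin(model.edges[:, 0], sites) | np.isin(model.edges[:, 1], sites)
    stiff = model.stiffness.copy()
    stiff[mask] *= factor
    return ENMModel(model.node_coords.copy(), model.edges.copy(), stiff,
                    model.temperature_scale)


def add_coupling(cov: np.ndarray, group1: Sequence[int], group2: Sequence[int],
                 strength: float, axis: Sequence[float] = (1.0, 0.0, 0.0)) -> np.ndarray:
    """Inject a rank-1 shared motion between two site groups.

    A unit displacement pattern moving every site of both groups along
    ``axis`` is added to the covariance with weight ``strength`` (A^2),
    raising the cross-correlation between the groups while keeping the
    matrix positive semi-definite.
    """
    n3 = cov.shape[0]
    u = np.zeros(n3)
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    for s in list(group1) + list(group2):
        u[3*s:3*s+3] = a
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("empty coupling groups")
    u /= norm
    return cov + strength * np.outer(u, u)


def sample_ensemble(cov: np.ndarray, mean: Structure, n_frames: int, seed: int,
                    rigid_noise: bool = False) -> Trajectory:
    """Draw frames from the stationary Gaussian with the given covariance.

    Sampling goes through the symmetric eigenfactorization of ``cov``;
    with ``rigid_noise`` each frame is additionally subjected to a random
    rigid motion (rotation + translation up to 5 A), which a correct
    alignment stage must remove. Fully reproducible per seed.
    """
    cov = np.asarray(cov, dtype=float)
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2)
    if vals[0] < -1e-8 * max(vals[-1], 1.0):
        raise ValueError("covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    half = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n_frames, cov.shape[0]))
    frames = mean.coords[None, :, :] + (z @ half.T).reshape(n_frames, -1, 3)
    if rigid_noise:
        rots = Rotation.random(n_frames, random_state=rng)
        trans = rng.uniform(-5.0, 5.0, size=(n_frames, 3))
        frames = np.einsum("tij,tnj->tni", rots.as_matrix(), frames) + trans[:, None, :]
    return Trajectory(frames, mean.res_numbers, list(mean.res_names))


# ---------------------------------------------------------------------------
# Divergence scenarios
# ---------------------------------------------------------------------------

#: Default planted perturbation: the five most flexible sites of the default
#: 20-site helix-loop-helix chain (termini, loop, helix-2 start). Placing the
#: "mutations" at high-amplitude, functionally important sites emulates the
#: rigidification of a promiscuous binding region into a specific one.
DEFAULT_PERTURBED_SITES = (0, 9, 10, 12, 19)
DEFAULT_STIFFNESS_FACTOR = 4.0


@dataclass
class ScenarioSpec:
    """Three-protein divergence scenario: A and B share a generator, C is
    sampled from a perturbed one (the promiscuous/promiscuous/specific
    triplet in miniature)."""

    n_sites: int = 20
    n_frames: int = 2000
    window_length: int = 500
    window_stride: int = 250
    geometry: str = "helix-loop-helix"
    perturbed_sites: tuple = DEFAULT_PERTURBED_SITES
    stiffness_factor: float = DEFAULT_STIFFNESS_FACTOR
    coupling_blocks: tuple = ()   # ((protein, group1, group2, strength), ...)
    temperature_scale: float = 1.0
    rigid_noise: bool = False
    seed: int = 0

    def protein_seed(self, index: int) -> int:
        """Documented per-protein seed expansion (kept below 2**31)."""
        return (self.seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1)


@dataclass
class ScenarioResult:
    trajectories: dict            # label -> Trajectory
    mean_structure: Structure
    covariances: dict             # label -> ground-truth 3N x 3N covariance
    manifest: dict

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, sort_keys=True, indent=2)


def generate_divergence_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Sample the A/B/C ensembles and return them with a ground-truth manifest."""
    chain = make_toy_chain(spec.n_sites, spec.geometry)
    base = build_enm(chain, temperature_scale=spec.temperature_scale)
    if spec.stiffness_factor == 1.0:
        perturbed = base
    else:
        perturbed = perturb_model(base, spec.perturbed_sites, spec.stiffness_factor)
    cov_base = enm_covariance(base)
    cov_pert = enm_covariance(perturbed)
    covs = {"A": cov_base, "B": cov_base.copy(), "C": cov_pert}
    for entry in spec.coupling_blocks:
        label, g1, g2, strength = entry
        covs[label] = add_coupling(covs[label], g1, g2, strength)
    trajectories = {}
    for i, label in enumerate(("A", "B", "C")):
        trajectories[label] = sample_ensemble(
            covs[label], chain, spec.n_frames, spec.protein_seed(i),
            rigid_noise=spec.rigid_noise)
    manifest = {
        "n_sites": spec.n_sites,
        "n_frames": spec.n_frames,
        "geometry": spec.geometry,
        "window_length": spec.window_length,
        "window_stride": spec.window_stride,
        "perturbed_sites": list(spec.perturbed_sites),
        "stiffness_factor": spec.stiffness_factor,
        "coupling_blocks": [[lab, list(g1), list(g2), s]
                            for lab, g1, g2, s in spec.coupling_blocks],
        "temperature_scale": spec.temperature_scale,
        "rigid_noise": spec.rigid_noise,
        "seed": spec.seed,
        "protein_seeds": {lab: spec.protein_seed(i)
                          for i, lab in enumerate(("A", "B", "C"))},
    }
    return ScenarioResult(trajectories=trajectories, mean_structure=chain,
                          covariances=covs, manifest=manifest)


def generate_switched_trajectory(n_sites: int = 20, n_frames: int = 2000,
                                 seed: int = 0) -> Trajectory:
    """Ensemble whose generator covariance switches halfway through the run.

    The first half samples the base network; the second half samples a
    strongly reshaped one (first helix stiffened x8, second helix loosened
    x1/8), which moves the slow-mode weight from one end of the chain to
    the other. Used to exercise the non-convergence detector.
    """
    chain = make_toy_chain(n_sites, "helix-loop-helix")
    base = build_enm(chain)
    n_h = n_sites // 3
    reshaped = perturb_model(base, list(range(n_h)), 8.0)
    reshaped = perturb_model(reshaped, list(range(n_sites - n_h, n_sites)), 1 / 8.0)
    half = n_frames // 2
    t1 = sample_ensemble(enm_covariance(base), chain, half, seed)
    t2 = sample_ensemble(enm_covariance(reshaped), chain, n_frames - half,
                         (seed + 1) % (2**31 - 1))
    frames = np.concatenate([t1.frames, t2.frames])
    return Trajectory(frames, chain.res_numbers, list(chain.res_names))
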