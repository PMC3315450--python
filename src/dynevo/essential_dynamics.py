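"""Windowed essential dynamics: trajectory PCA with convergence checking.

A trajectory is first superposed frame-by-frame onto an iteratively refined
mean structure so that rigid-body motion cannot masquerade as internal
fluctuation. The 3N x 3N positional covariance of each sliding window is
diagonalized; the top eigenpairs (at most 30, the slowest collective modes)
form a :class:`ModeSet`. Convergence of the sampling is declared when the
per-site fluctuation profiles of the slowest mode agree between successive
windows (Pearson correlation > 0.8) for a configurable number of
consecutive window pairs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_io import StructureError, Trajectory, superpose

#: Hard cap on the number of retained modes: faster, small-amplitude modes
#: are not informative about large-scale functional motion.
MAX_MODES = 30

#: Pearson correlation a successive-window comparison must exceed.
DEFAULT_PEARSON_CUTOFF = 0.8


class ConvergenceError(ValueError):
    """A convergence comparison could not be evaluated."""


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout for windowed PCA.

    ``min_windows_converged`` is the number of consecutive passing
    successive-window comparisons required to declare convergence. The
    default of 4 makes the converged span equal three window-lengths when
    the stride is half the window length.
    """

    length: int
    stride: int
    min_windows_converged: int = 4

    def __post_init__(self):
        if not (0 < self.stride <= self.length):
            raise ValueError("require 0 < stride <= length")
        if self.min_windows_converged < 1:
            raise ValueError("min_windows_converged must be >= 1")

    def starts(self, n_frames: int) -> list[int]:
        if self.length > n_frames:
            raise ValueError(
                f"window length {self.length} exceeds trajectory length {n_frames}")
        return list(range(0, n_frames - self.length + 1, self.stride))


@dataclass
class ModeSet:
    """Eigenvectors/eigenvalues of one window's positional covariance."""

    eigenvalues: np.ndarray    # (K,) Angstrom^2, non-increasing
    eigenvectors: np.ndarray   # (3N, K), orthonormal columns
    mean_coords: np.ndarray    # (N, 3), window-average aligned coordinates
    window_id: int | None = None

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.mean_coords = np.asarray(self.mean_coords, dtype=float)
        if self.eigenvectors.shape[1] != len(self.eigenvalues):
            raise ValueError("eigenvector/eigenvalue count mismatch")
        if len(self.eigenvalues) > MAX_MODES:
            raise ValueError(f"at most {MAX_MODES} modes may be retained")

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_sites(self) -> int:
        return self.eigenvectors.shape[0] // 3

    def to_json(self) -> str:
        return json.dumps({
            "window_id": self.window_id,
            "n_sites": self.n_sites,
            "eigenvalues_A2": self.eigenvalues.tolist(),
            "eigenvectors_flat": self.eigenvectors.ravel(order="F").tolist(),
            "mean_coords": self.mean_coords.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "ModeSet":
        d = json.loads(text)
        vals = np.asarray(d["eigenvalues_A2"])
        vecs = np.asarray(d["eigenvectors_flat"]).reshape(
            3 * d["n_sites"], len(vals), order="F")
        return cls(vals, vecs, np.asarray(d["mean_coords"]), d["window_id"])


@dataclass
class FluctuationProfile:
    """Per-site squared fluctuation amplitude (Angstrom^2) along one mode.

    value(i) = lambda_k * |v_k at site i|^2, so the profile sums to the
    mode's eigenvalue.
    """

    values: np.ndarray
    mode_rank: int  # 1-based; rank 1 is the slowest (largest-eigenvalue) mode


@dataclass
class ConvergenceResult:
    pearson_by_pair: np.ndarray   # P for each successive window pair
    converged: bool
    converged_at: int | None      # window index closing the converged run
    threshold: float = DEFAULT_PEARSON_CUTOFF


# ---------------------------------------------------------------------------

def _kabsch_batch(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``ref`` (batched proper-rotation Kabsch)."""
    ref_c = ref - ref.mean(axis=0)
    mob_c = frames - frames.mean(axis=1, keepdims=True)
    h = np.einsum("tni,nj->tij", mob_c, ref_c)  # per-frame 3x3 covariance
    u, _, vt = np.linalg.svd(h)
    det = np.sign(np.linalg.det(np.einsum("tij,tjk->tik", u, vt)))
    u[:, :, -1] *= det[:, None]  # reject reflections
    rot = np.einsum("tij,tjk->tik", u, vt)  # maps mobile -> reference frame
    return np.einsum("tni,tij->tnj", mob_c, rot) + ref.mean(axis=0)


def align_and_center(traj: Trajectory, reference: str | int = "mean",
                     max_iter: int = 100, tol: float = 1e-12) -> Trajectory:
    """Superpose every frame onto a common reference, removing rigid motion.

    With ``reference="mean"`` the reference is refined iteratively: frames
    are aligned to the current mean structure and the mean recomputed, until
    the mean shifts by less than ``tol`` (Angstrom RMS) or ``max_iter``
    passes. The first frame seeds the iteration. An integer selects a fixed
    reference frame instead.
    """
    frames = traj.frames
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be 'mean' or a frame index")
        # seed with the coordinate mean so an already-aligned trajectory is
        # a fixed point; under heavy rigid contamination the raw mean
        # collapses toward a degenerate shape, so fall back to frame 0
        mean0 = frames.mean(axis=0)
        sv = np.linalg.svd(mean0 - mean0.mean(axis=0), compute_uv=False)
        fv = np.linalg.svd(frames[0] - frames[0].mean(axis=0), compute_uv=False)
        ref = mean0 if sv[1] > 0.1 * fv[1] else frames[0]
        aligned = frames
        for _ in range(max_iter):
            aligned = _kabsch_batch(aligned, ref)
            new_ref = aligned.mean(axis=0)
            shift = np.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1)))
            ref = new_ref
            if shift < tol:
                break
    else:
        ref = frames[int(reference)]
        aligned = _kabsch_batch(frames, ref)
    return Trajectory(aligned, traj.res_numbers, list(traj.res_names),
                      traj.frame_spacing)


def trajectory_modes(traj: Trajectory, n_modes: int = MAX_MODES) -> ModeSet:
    """Modes of the whole (aligned) trajectory: align -> covariance -> eigenmodes.

    The windowed machinery establishes convergence; once converged, the
    full-trajectory mode set is the lowest-noise estimate and is what the
    comparative stages consume.
    """
    aligned = align_and_center(traj)
    c = covariance(aligned)
    return eigenmodes(c, n_modes=n_modes, window_id=None,
                      mean_coords=aligned.frames.mean(axis=0))


def covariance(source: Trajectory | np.ndarray) -> np.ndarray:
    """Positional covariance C = <(x - <x>)(x - <x>)^T> of an aligned window.

    Uses the population (1/T) normalization of a time average. Input is a
    Trajectory or a (T, N, 3) array; output is 3N x 3N in Angstrom^2.
    """
    frames = source.frames if isinstance(source, Trajectory) else np.asarray(source, float)
    if frames.ndim != 3:
        raise ValueError("expected a (T, N, 3) coordinate array")
    t = frames.shape[0]
    if t < 2:
        raise ValueError("covariance needs at least 2 frames")
    x = frames.reshape(t, -1)
    xc = x - x.mean(axis=0)
    return xc.T @ xc / t


def eigenmodes(c: np.ndarray, n_modes: int = MAX_MODES,
               window_id: int | None = None,
               mean_coords: np.ndarray | None = None) -> ModeSet:
    """Top eigenpairs of a covariance matrix, slowest (largest) first.

    Eigenvector signs are fixed by making each vector's largest-magnitude
    component positive, so downstream comparisons are reproducible. Tiny
    negative eigenvalues from roundoff are clipped to zero.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("covariance must be square")
    scale = max(np.abs(c).max(), 1.0)
    if np.abs(c - c.T).max() > 1e-8 * scale:
        raise ValueError("covariance matrix is not symmetric")
    vals, vecs = np.linalg.eigh((c + c.T) / 2)
    order = np.argsort(vals)[::-1]
    k = min(n_modes, MAX_MODES, c.shape[0])
    vals = np.clip(vals[order][:k], 0.0, None)
    vecs = vecs[:, order][:, :k]
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    if mean_coords is None:
        mean_coords = np.zeros((c.shape[0] // 3, 3))
    return ModeSet(vals, vecs, mean_coords, window_id)


def fluctuation_profile(modes: ModeSet, rank: int = 1) -> FluctuationProfile:
    """Eigenvalue-scaled squared per-site amplitude of mode ``rank`` (1-based)."""
    if not (1 <= rank <= modes.n_modes):
        raise ValueError(f"mode rank {rank} out of range 1..{modes.n_modes}")
    v = modes.eigenvectors[:, rank - 1].reshape(-1, 3)
    values = modes.eigenvalues[rank - 1] * np.sum(v * v, axis=1)
    return FluctuationProfile(values=values, mode_rank=rank)


def sliding_window_pca(traj: Trajectory, spec: WindowSpec,
                       n_modes: int = MAX_MODES) -> list[ModeSet]:
    """Run aligned PCA on each sliding window of the trajectory.

    Each window is aligned independently (to its own iterative mean), so a
    window's modes describe fluctuation about that window's average.
    """
    modesets = []
    for wid, start in enumerate(spec.starts(traj.n_frames)):
        window = traj.slice(start, start + spec.length)
        aligned = align_and_center(window)
        c = covariance(aligned)
        ms = eigenmodes(c, n_modes=n_modes, window_id=wid,
                        mean_coords=aligned.frames.mean(axis=0))
        modesets.append(ms)
    return modesets


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def check_convergence(modesets: Sequence[ModeSet], spec: WindowSpec,
                      threshold: float = DEFAULT_PEARSON_CUTOFF,
                      n_modes_compare: int = 1) -> ConvergenceResult:
    """Pearson-based convergence of successive windows' fluctuation profiles.

    For each successive window pair the correlation between slowest-mode
    fluctuation profiles is computed (with ``n_modes_compare > 1``, the
    minimum correlation over the compared mode ranks). The run is converged
    iff the last ``spec.min_windows_converged`` comparisons all exceed the
    threshold; ``converged_at`` reports the window index at which the first
    such run completed.
    """
    if len(modesets) < 2:
        raise ValueError("convergence needs at least 2 windows")
    profiles = []
    for ms in modesets:
        per_mode = []
        for rank in range(1, n_modes_compare + 1):
            p = fluctuation_profile(ms, rank).values
            if np.allclose(p, p[0]):
                raise ConvergenceError(
                    f"window {ms.window_id}: constant fluctuation profile, "
                    "Pearson correlation undefined")
            per_mode.append(p)
        profiles.append(per_mode)
    pearsons = np.array([
        min(_pearson(pa, pb) for pa, pb in zip(profiles[i], profiles[i + 1]))
        for i in range(len(profiles) - 1)
    ])
    passing = pearsons > threshold
    m = spec.min_windows_converged
    converged = len(passing) >= m and bool(np.all(passing[-m:]))
    converged_at = None
    run = 0
    for i, ok in enumerate(passing):
        run = run + 1 if ok else 0
        if run >= m:
            converged_at = i + 1  # window index closing the run
            break
    return ConvergenceResult(pearson_by_pair=pearsons, converged=converged,
                             converged_at=converged_at, threshold=threshold)


def profile_to_csv(profile: FluctuationProfile,
                   site_labels: Sequence[str] | None = None) -> str:
    labels = site_labels if site_labels is not None else range(len(profile.values))
    lines = ["site,value_A2"]
    lines += [f"{lab},{float(v)!r}" for lab, v in zip(labels, profile.values)]
    return "\n".join(lines) + "\n"
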