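"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: superposition is
minimized by hierarchical grid search over Euler angles, covariance by an
explicit double loop, eigenpairs by power iteration with deflation, and
rank-sum scoring by direct enumeration.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray,
                     coarse: int = 24, zoom_levels: int = 10,
                     n_starts: int = 3) -> float:
    """Minimum RMSD over rigid motions via hierarchical rotation-angle search.

    The optimal translation for any rotation matches the centroids, so the
    search is over rotations only, parameterized as rotation (axis-angle)
    vectors — a chart free of the gimbal degeneracy that traps box-zooming
    in Euler-angle space. A coarse grid over the cube containing the pi-ball
    is refined by repeated 3x zooms around each of the best few candidates.
    """
    a = reference - reference.mean(axis=0)
    b = mobile - mobile.mean(axis=0)
    n = len(a)

    def batch_rmsd(vecs):
        rots = Rotation.from_rotvec(vecs).as_matrix()
        moved = np.einsum("bij,nj->bni", rots, b)
        return np.sqrt(np.sum((moved - a) ** 2, axis=(1, 2)) / n)

    grids = [np.linspace(-np.pi, np.pi, coarse)] * 3
    mesh = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    r = batch_rmsd(mesh)
    starts = mesh[np.argsort(r)[:n_starts]]
    best_rmsd = float(r.min())
    step0 = np.full(3, 2 * np.pi / (coarse - 1))
    for start in starts:
        best, step = start, step0.copy()
        for _ in range(zoom_levels):
            grids = [np.linspace(best[k] - step[k], best[k] + step[k], 9)
                     for k in range(3)]
            mesh = np.stack(np.meshgrid(*grids, indexing="ij"),
                            axis=-1).reshape(-1, 3)
            r = batch_rmsd(mesh)
            i = np.argmin(r)
            if r[i] < best_rmsd:
                best_rmsd = float(r[i])
            best = mesh[i]
            step = step / 3.0
    return best_rmsd


def naive_covariance(frames: np.ndarray) -> np.ndarray:
    """Element-by-element double-loop covariance with 1/T normalization."""
    t = frames.shape[0]
    x = frames.reshape(t, -1)
    mean = x.mean(axis=0)
    d = x.shape[1]
    c = np.zeros((d, d))
    for i in range(d):
        for j in range(d):
            acc = 0.0
            for k in range(t):
                acc += (x[k, i] - mean[i]) * (x[k, j] - mean[j])
            c[i, j] = acc / t
    return c


def power_iteration_eigh(c: np.ndarray, k: int, n_iter: int = 5000,
                         tol: float = 1e-14) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of a symmetric PSD matrix by power iteration + deflation."""
    c = c.copy().astype(float)
    rng = np.random.default_rng(12345)
    vals, vecs = [], []
    for _ in range(k):
        v = rng.standard_normal(c.shape[0])
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(n_iter):
            w = c @ v
            norm = np.linalg.norm(w)
            if norm == 0:
                lam = 0.0
                break
            w /= norm
            if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
                v = w
                lam = float(v @ c @ v)
                break
            v = w
            lam = norm
        vals.append(float(v @ c @ v))
        vecs.append(v.copy())
        c -= vals[-1] * np.outer(v, v)
    return np.array(vals), np.column_stack(vecs)


def naive_align(frames: np.ndarray, max_iter: int = 100,
                tol: float = 1e-12) -> np.ndarray:
    """Iterative-mean alignment using per-frame scipy Kabsch (no batching).

    Matches the documented convention: the iteration is seeded with the
    coordinate mean (valid for the non-contaminated inputs used in tests).
    """
    ref = frames.mean(axis=0)
    aligned = frames.copy()
    for _ in range(max_iter):
        out = []
        for f in aligned:
            fc = f - f.mean(axis=0)
            rc = ref - ref.mean(axis=0)
            rot, _ = Rotation.align_vectors(rc, fc)
            out.append(fc @ rot.as_matrix().T + ref.mean(axis=0))
        aligned = np.stack(out)
        new_ref = aligned.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1)))
        ref = new_ref
        if shift < tol:
            break
    return aligned


def rank_sum_order(rg: np.ndarray, contacts: np.ndarray) -> list[int]:
    """Brute-force rank-sum ordering: rg ascending + contacts descending,
    minimum rank for ties, final ties broken by rg then input order."""
    n = len(rg)
    combined = []
    for i in range(n):
        rg_rank = 1 + sum(1 for j in range(n) if rg[j] < rg[i])
        nc_rank = 1 + sum(1 for j in range(n) if contacts[j] > contacts[i])
        combined.append(rg_rank + nc_rank)
    return sorted(range(n), key=lambda i: (combined[i], rg[i], i))


def pairwise_rmsd_matrix(coord_sets: list[np.ndarray]) -> np.ndarray:
    """All-pairs minimum RMSD via the grid-search oracle (small inputs only)."""
    n = len(coord_sets)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = grid_search_rmsd(coord_sets[i], coord_sets[j])
    return m
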