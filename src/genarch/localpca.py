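"""Local-PCA genome-structure scan, plus LD pruning and genome-wide IBS.

The scan follows the lostruct recipe: a PCA of individual dosages per
window, a Frobenius dissimilarity between the rank-k covariance
approximations of windows, classical MDS of the dissimilarity matrix, and
extraction of the three "corners" of the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, GenotypeMatrix


@dataclass
class WindowPCA:
    window_id: int
    eigenvalues: np.ndarray   # (k,), descending, >= 0
    eigenvectors: np.ndarray  # (k, n_individuals), orthonormal rows
    total_variance: float
    zero_variance: bool = False


@dataclass
class MDSEmbedding:
    coords: np.ndarray       # (n_windows, d)
    eigenvalues: np.ndarray  # descending eigenvalues of the centred matrix


def _imputed_dosages(gm: GenotypeMatrix) -> np.ndarray:
    """Individual x site dosage matrix with per-site mean imputation."""
    d = gm.dosages().astype(float)
    miss = d == MISSING
    if miss.any():
        with np.errstate(invalid="ignore"):
            col_mean = np.where(
                (~miss).sum(axis=0) > 0,
                np.nansum(np.where(miss, np.nan, d), axis=0)
                / np.maximum((~miss).sum(axis=0), 1),
                0.0,
            )
        d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
    return d


def window_pca(gm: GenotypeMatrix, k: int = 2, window_id: int = 0) -> WindowPCA:
    """Top-k eigenpairs of the individual covariance of centred dosages."""
    d = _imputed_dosages(gm)
    n_ind = d.shape[0]
    if n_ind < k + 1:
        raise ValueError("need at least k+1 individuals")
    x = d - d.mean(axis=0, keepdims=True)
    cov = x @ x.T / max(x.shape[1], 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0, None)
    total = float(np.clip(vals, 0, None).sum())
    return WindowPCA(window_id, lam, vecs[:, order].T.copy(), total, total < 1e-12)


def window_distance(a: WindowPCA, b: WindowPCA) -> float:
    """Frobenius distance between the rank-k covariance approximations."""
    if a.eigenvectors.shape != b.eigenvectors.shape:
        raise ValueError("windows must share individuals and k")
    cross = (a.eigenvectors @ b.eigenvectors.T) ** 2
    d2 = (
        float(np.sum(a.eigenvalues**2))
        + float(np.sum(b.eigenvalues**2))
        - 2.0 * float(a.eigenvalues @ cross @ b.eigenvalues)
    )
    return float(np.sqrt(max(d2, 0.0)))


def distance_matrix(pcas: list[WindowPCA]) -> np.ndarray:
    n = len(pcas)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = window_distance(pcas[i], pcas[j])
    return dm


def mds(dist: np.ndarray, d: int = 2) -> MDSEmbedding:
    """Classical MDS: double-centring of squared distances + eigh."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam = np.clip(vals[:d], 0, None)
    coords = vecs[:, :d] * np.sqrt(lam)
    return MDSEmbedding(coords, vals)


def corners(
    embedding: MDSEmbedding, fraction: float = 0.1, exact: bool = False
) -> list[np.ndarray]:
    """Three window sets nearest the three extremes of the embedding.

    Extreme points are picked greedily — farthest from the centroid, then
    twice the point maximizing the minimum distance to those already
    chosen — or, with ``exact``, the triple maximizing summed pairwise
    distance (O(n^3), for small n).  Each corner holds the
    ceil(fraction * n) windows nearest its extreme; overlaps are allowed.
    """
    x = embedding.coords[:, :2]
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 windows")
    if exact:
        best, best_val = None, -1.0
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    v = (
                        np.linalg.norm(x[i] - x[j])
                        + np.linalg.norm(x[i] - x[k])
                        + np.linalg.norm(x[j] - x[k])
                    )
                    if v > best_val:
                        best, best_val = (i, j, k), v
        extremes = list(best)
    else:
        centroid = x.mean(axis=0)
        first = int(np.argmax(np.linalg.norm(x - centroid, axis=1)))
        extremes = [first]
        for _ in range(2):
            dmin = np.min(
                np.stack([np.linalg.norm(x - x[e], axis=1) for e in extremes]),
                axis=0,
            )
            extremes.append(int(np.argmax(dmin)))
    k_win = int(np.ceil(fraction * n))
    out = []
    for e in extremes:
        d = np.linalg.norm(x - x[e], axis=1)
        out.append(np.argsort(d, kind="stable")[:k_win])
    return out


# ---------------------------------------------------------------------------
# LD pruning and IBS
# ---------------------------------------------------------------------------
def _r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix, r2_threshold: float = 0.2, window: int = 50
) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning on dosages.

    A SNP is kept iff its r-squared with every previously kept SNP within
    the ``window``-SNP lookback is at most ``r2_threshold``.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2 threshold must be in (0, 1]")
    d = gm.dosages()
    kept: list[int] = []
    for j in range(gm.n_sites):
        ok = True
        for k in reversed(kept):
            if j - k > window:
                break
            if _r2(d[:, k], d[:, j]) > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    idx = np.asarray(kept, dtype=int)
    return GenotypeMatrix(
        gm.alleles[:, idx],
        gm.positions[idx],
        gm.seq_length,
        list(gm.pops),
        gm.chrom,
        gm.phased,
    )


def ibs_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Mean per-site allele-sharing fraction between individuals.

    Sharing per site is 1 - |dosage_i - dosage_j| / 2; pairs without any
    complete site get NaN.
    """
    d = gm.dosages().astype(float)
    n = d.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            ok = (d[i] != MISSING) & (d[j] != MISSING)
            if not ok.any():
                continue
            share = 1.0 - np.abs(d[i, ok] - d[j, ok]) / 2.0
            out[i, j] = out[j, i] = float(share.mean())
    return out
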