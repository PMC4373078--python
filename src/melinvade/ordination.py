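"""Non-metric multidimensional scaling (Kruskal stress-1).

Minimizes stress-1 = sqrt( sum_(i<j) (d_ij - dhat_ij)^2 / sum_(i<j) d_ij^2 ),
where d_ij are configuration distances and dhat_ij the disparities obtained
by monotone (pool-adjacent-violators) regression of the configuration
distances on the rank order of the input dissimilarities.  Ties in the
dissimilarities are treated with Kruskal's primary approach: tied
dissimilarities do not constrain the order of their disparities.

The configuration is improved by Guttman-transform majorization steps; each
run starts either from the classical (metric/PCoA) solution or from a seeded
random configuration, and the lowest-stress run wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: pd.DataFrame  # specimens x dims, principal-axes convention
    stress_pct: float          # Kruskal stress-1 x 100
    n_starts: int
    seed: int
    best_start_index: int      # 0 = PCoA start
    converged: bool
    stress_history: list[float] | None = None


def _disparities(dist: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Monotone regression of configuration distances on dissimilarity order.

    Primary tie treatment: within a block of tied dissimilarities the
    distances are pre-sorted, so PAVA never forces tied dissimilarities to
    share a disparity.
    """
    order = np.lexsort((dist, delta))
    fit = isotonic_regression(dist[order], increasing=True)
    dhat = np.empty_like(dist)
    dhat[order] = fit.x
    return dhat


def stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(dist ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def stress_from_coords(d: pd.DataFrame | np.ndarray, coords: np.ndarray) -> float:
    """Recompute stress-1 (on [0, 1]) of a configuration against dissimilarities."""
    delta = squareform(np.asarray(d, dtype=float), checks=False)
    dist = pdist(np.asarray(coords, dtype=float))
    return stress1(dist, _disparities(dist, delta))


def _pcoa(dmat: np.ndarray, dims: int) -> np.ndarray:
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dmat ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dims]
    w = np.clip(w[idx], 0, None)
    return v[:, idx] * np.sqrt(w)


def _guttman(x: np.ndarray, delta: np.ndarray, max_iter: int, tol: float,
             ) -> tuple[np.ndarray, list[float], bool]:
    n = x.shape[0]
    history: list[float] = []
    converged = False
    dist = pdist(x)
    dhat = _disparities(dist, delta)
    s = stress1(dist, dhat)
    history.append(s)
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        b = -squareform(ratio, checks=False)
        np.fill_diagonal(b, -b.sum(axis=1))
        x_new = (b @ x) / n
        dist_new = pdist(x_new)
        dhat_new = _disparities(dist_new, delta)
        s_new = stress1(dist_new, dhat_new)
        if s_new > s + 1e-12:
            # majorization step did not reduce normalized stress; keep the
            # previous configuration so the reported history is monotone
            converged = True
            break
        x, dist, dhat = x_new, dist_new, dhat_new
        history.append(s_new)
        if s - s_new < tol * max(s, np.finfo(float).tiny):
            s = s_new
            converged = True
            break
        s = s_new
    return x, history, converged


def nmmds(d: pd.DataFrame | np.ndarray,
          dims: int = 3,
          n_starts: int = 20,
          seed: int = 0,
          max_iter: int = 500,
          tol: float = 1e-7) -> OrdinationResult:
    """Best-of-`n_starts` non-metric MDS of a square dissimilarity matrix.

    Start 0 is the classical-scaling (PCoA) configuration; the remaining
    starts are seeded random configurations.  Returns centered coordinates
    rotated to principal axes, with each axis' sign fixed so its
    largest-magnitude coordinate is positive, and stress-1 x 100.
    """
    if isinstance(d, pd.DataFrame):
        labels = [str(x) for x in d.index]
        dmat = d.to_numpy(dtype=float)
    else:
        dmat = np.asarray(d, dtype=float)
        labels = [str(i) for i in range(dmat.shape[0])]
    n = dmat.shape[0]
    if dmat.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(dmat, dmat.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if dims >= n - 1:
        raise ValueError("dims must be < n_specimens - 1")
    delta = squareform(dmat, checks=False)
    if np.all(delta == 0):
        raise ValueError("degenerate input: all dissimilarities are zero")

    rng = np.random.default_rng(seed)
    scale = delta[delta > 0].mean()
    best: tuple[float, np.ndarray, list[float], bool, int] | None = None
    for start in range(n_starts):
        if start == 0:
            x0 = _pcoa(dmat, dims)
            if np.allclose(x0, 0):
                x0 = rng.normal(scale=scale, size=(n, dims))
        else:
            x0 = rng.normal(scale=scale, size=(n, dims))
        x, history, converged = _guttman(x0, delta, max_iter, tol)
        s = history[-1]
        if best is None or s < best[0]:
            best = (s, x, history, converged, start)

    s, x, history, converged, start = best
    # output convention: centered, principal axes, positive dominant loading
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for k in range(x.shape[1]):
        if np.abs(x[:, k]).max() > 0 and x[np.argmax(np.abs(x[:, k])), k] < 0:
            x[:, k] = -x[:, k]
    coords = pd.DataFrame(x, index=pd.Index(labels, name="specimen_id"),
                          columns=[f"axis{i + 1}" for i in range(dims)])
    return OrdinationResult(labels=labels, coordinates=coords,
                            stress_pct=100.0 * s, n_starts=n_starts, seed=seed,
                            best_start_index=start, converged=converged,
                            stress_history=history)
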