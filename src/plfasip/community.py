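"""Community-structure analysis of PLFA fingerprints.

The biomarker concentration matrix (samples × biomarkers) is treated as
a community table: Hellinger-transformed (square root of relative
abundances), summarized as pairwise Bray-Curtis dissimilarities,
ordinated by non-metric multidimensional scaling (NMDS, minimizing
Kruskal stress-1 against a monotone regression of embedded distances on
the dissimilarities), and tested for group separation with a one-way
permutation ANOSIM.

NMDS is implemented here rather than delegated because the pipeline
needs a seeded, restartable optimizer whose stress trace is monotone
non-increasing within a start (each accepted step must not raise
stress-1) and whose best-of-restarts bookkeeping is reproducible.  The
building blocks are standard: isotonic regression from scikit-learn for
the monotone fit, a Guttman-transform step with backtracking line
search for the configuration update, and a metric (principal
coordinates) solution as the first start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "hellinger",
    "bray_curtis",
    "dissimilarity_matrix",
    "nmds",
    "anosim",
    "community_analysis",
    "OrdinationResult",
    "AnosimResult",
    "CommunityOrdination",
]


def hellinger(matrix):
    """Hellinger transform: sqrt of each value over its row sum.

    Each transformed row has unit sum of squares, so Euclidean distance
    on the transform equals the Hellinger distance between the raw
    relative-abundance profiles.  Accepts an array or DataFrame and
    returns the same type.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("community matrix must be 2-D (samples × biomarkers)")
    if np.any(X < 0):
        raise ValueError("community matrix must be non-negative")
    row_sums = X.sum(axis=1)
    zero = np.nonzero(row_sums == 0)[0]
    if len(zero):
        name = matrix.index[zero[0]] if is_frame else zero[0]
        raise ValueError(f"sample {name!r} has zero total abundance")
    out = np.sqrt(X / row_sums[:, None])
    if is_frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity Σ|x−y| / Σ(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def dissimilarity_matrix(matrix, metric: str = "braycurtis") -> np.ndarray:
    """Square pairwise dissimilarity matrix of sample rows."""
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    return squareform(pdist(X, metric=metric))


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    converged: bool
    stress_history: list[float] = field(default_factory=list)


def _check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return 0.5 * (d + d.T)


def _pcoa_coords(d: np.ndarray, k: int) -> np.ndarray:
    """Classical (metric) scaling used as the first NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom == 0:
        # collapsed configuration: stress-1 is 0/0 there; treat as the
        # worst possible fit so degenerate solutions never win
        return float("inf")
    return float(np.sqrt(((dist - disp) ** 2).sum() / denom))


def nmds(
    d,
    k: int = 2,
    restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs ``restarts`` starts (a principal-coordinates start plus random
    configurations) and returns the best.  Within a start, candidate
    Guttman-transform steps are accepted only if they do not increase
    stress-1 (with backtracking), so the stress history of the returned
    solution is monotone non-increasing.  Deterministic for a given
    seed.  Ties in the monotone regression receive the primary
    (within-tie averaging) treatment.
    """
    D = _check_square(d)
    n = D.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    dissim = D[iu]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    def full_stress(X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        dist = pdist(X)
        # isotonic regression of distances on dissimilarities; equal
        # dissimilarities share one fitted value (primary tie treatment)
        disp = iso.fit_transform(dissim, dist)
        return _stress1(dist, disp), dist, disp

    best: OrdinationResult | None = None
    for start in range(max(restarts, 1)):
        if start == 0:
            X = _pcoa_coords(D, k)
        else:
            X = rng.standard_normal((n, k)) * dissim.mean()
        stress, dist, disp = full_stress(X)
        history = [stress]
        converged = False
        for _ in range(max_iter):
            # Guttman transform with the current disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, disp / np.where(dist > 0, dist, 1.0), 0.0)
            B = squareform(-ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X_new = B @ X / n
            step = X_new - X
            alpha = 1.0
            accepted = False
            while alpha > 1e-4:
                cand = X + alpha * step
                s_cand, dist_c, disp_c = full_stress(cand)
                if s_cand < stress:
                    X, dist, disp = cand, dist_c, disp_c
                    # stress-1 is scale-invariant, so renormalize the
                    # configuration to stop it drifting toward collapse
                    scale = np.sqrt((dist**2).mean())
                    if scale > 0:
                        X, dist, disp = X / scale, dist / scale, disp / scale
                    improved = stress - s_cand
                    stress = s_cand
                    history.append(stress)
                    accepted = True
                    if improved < tol:
                        converged = True
                    break
                alpha *= 0.5
            if not accepted:
                converged = True
            if converged:
                break
        # report on the dissimilarity scale: rms embedded distance matches
        # rms dissimilarity (stress is unaffected by uniform scaling)
        final_dist = pdist(X)
        rms = np.sqrt((final_dist**2).mean())
        if rms > 0:
            X = X * np.sqrt((dissim**2).mean()) / rms
        X = X - X.mean(axis=0)
        if best is None or stress < best.stress:
            best = OrdinationResult(X, stress, converged, history)
    return best


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int


def anosim(d, groups, n_perm: int = 999, seed: int | None = None) -> AnosimResult:
    """One-way analysis of similarity on a dissimilarity matrix.

    All pairwise dissimilarities are ranked; the statistic is

        R = (mean between-group rank − mean within-group rank) / (M / 2)

    with M = n(n−1)/2 pairs, so R ∈ [−1, 1] and R = 1 when every
    between-group pair is more dissimilar than every within-group pair.
    The permutation p-value uses the upper tail and includes the
    observed labelling: p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm).
    """
    D = _check_square(d)
    groups = np.asarray(groups)
    n = D.shape[0]
    if len(groups) != n:
        raise ValueError("one group label per sample required")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if counts.min() < 2:
        small = labels[counts.argmin()]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    iu = np.triu_indices(n, 1)
    ranks = rankdata(D[iu])
    denom = len(ranks) / 2.0
    gi, gj = iu

    def r_stat(g: np.ndarray) -> float:
        within = g[gi] == g[gj]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(groups)) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(r=r_obs, p=p, n_permutations=n_perm)


@dataclass
class CommunityOrdination:
    """NMDS coordinates with the companion ANOSIM test."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool
    anosim_r: float
    anosim_p: float
    n_permutations: int


def community_analysis(
    matrix: pd.DataFrame,
    groups,
    k: int = 2,
    restarts: int = 20,
    n_perm: int = 999,
    seed: int | None = None,
) -> CommunityOrdination:
    """Hellinger → Bray-Curtis → NMDS + ANOSIM on a community matrix."""
    transformed = hellinger(matrix)
    D = dissimilarity_matrix(transformed)
    ord_res = nmds(D, k=k, restarts=restarts, seed=seed)
    an = anosim(D, groups, n_perm=n_perm, seed=seed)
    coords = pd.DataFrame(
        ord_res.coordinates,
        index=matrix.index if isinstance(matrix, pd.DataFrame) else None,
        columns=[f"NMDS{i + 1}" for i in range(ord_res.coordinates.shape[1])],
    )
    coords["group"] = np.asarray(groups)
    return CommunityOrdination(
        coordinates=coords,
        stress=ord_res.stress,
        converged=ord_res.converged,
        anosim_r=an.r,
        anosim_p=an.p,
        n_permutations=an.n_permutations,
    )
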