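"""Agreement between two shape spaces.

Distance profiles and matrices over score spaces, ordinary regressions, the
Mantel matrix-correlation permutation test, Procrustean randomisation
(PROTEST), eigenvalue-spectrum correlation, auxiliary two-sample and rank
statistics, and per-vertex surface distance fields for heatmaps.
"""

from __future__ import annotations

from itertools import permutations as _permutations

import numpy as np
from scipy import stats as _stats
from scipy.spatial.distance import pdist, squareform

from .mesh import TriangleMesh, closest_point_distance
from .shape_space import ShapeScores

__all__ = [
    "distance_to_reference",
    "score_distance_matrix",
    "linear_fit_r2",
    "mantel_test",
    "protest",
    "eigenvalue_correlation",
    "auxiliary_stats",
    "per_vertex_distance",
]


def _matrix(scores) -> np.ndarray:
    if isinstance(scores, ShapeScores):
        return np.asarray(scores.scores, dtype=float)
    return np.asarray(scores, dtype=float)


def distance_to_reference(scores: ShapeScores, reference_id: str) -> np.ndarray:
    """Euclidean distance of every specimen's score row to the reference's."""
    ref = scores.row(reference_id)
    return np.linalg.norm(scores.scores - ref, axis=1)


def score_distance_matrix(scores) -> np.ndarray:
    """All pairwise Euclidean distances over all axes."""
    X = _matrix(scores)
    if len(X) < 2:
        raise ValueError("need >= 2 specimens")
    return squareform(pdist(X, metric="euclidean"))


def linear_fit_r2(x, y):
    """OLS fit y = a x + b: returns (slope, intercept, r_squared, p_value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = _stats.linregress(x, y)
    ss_res = float(np.sum((y - (res.slope * x + res.intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(res.slope), float(res.intercept), r2, float(res.pvalue)


# ---------------------------------------------------------------------------
# Mantel


def _lower(d: np.ndarray) -> np.ndarray:
    return d[np.tril_indices(len(d), -1)]


def mantel_test(d1: np.ndarray, d2: np.ndarray, n_perm: int | str = 9999, seed: int | None = None):
    """Mantel matrix correlation with a one-sided (greater) permutation test.

    r is the Pearson correlation of the strictly-lower-triangle entries;
    the test permutes rows and columns of ``d2`` jointly.  With
    ``n_perm='all'`` every relabelling is enumerated and
    p = #{r_perm >= r_obs} / n! (the identity included); otherwise
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) over seeded draws.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n = len(d1)
    if d1.shape != d2.shape or n < 4:
        raise ValueError("need two equal n x n matrices with n >= 4")
    v1 = _lower(d1)
    if np.ptp(v1) == 0 or np.ptp(_lower(d2)) == 0:
        raise ValueError("constant lower triangle")
    v1 = (v1 - v1.mean()) / v1.std()

    def corr(dd):
        v2 = _lower(dd)
        s = v2.std()
        if s == 0:
            return 0.0
        return float(np.mean(v1 * (v2 - v2.mean()) / s))

    r_obs = corr(d2)
    if n_perm == "all":
        count, total = 0, 0
        for perm in _permutations(range(n)):
            p = np.array(perm)
            if corr(d2[np.ix_(p, p)]) >= r_obs - 1e-12:
                count += 1
            total += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        p = rng.permutation(n)
        if corr(d2[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + int(n_perm))


# ---------------------------------------------------------------------------
# PROTEST


def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> float:
    sv = np.linalg.svd(X.T @ Y, compute_uv=False)
    return max(1.0 - sv.sum() ** 2, 0.0)


def _protest_normalise(M: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    ss = np.sqrt(np.sum(Mc**2))
    if ss <= 0:
        raise ValueError("degenerate (constant) configuration")
    return Mc / ss


def protest(scores_x, scores_y, n_perm: int | str = 9999, seed: int | None = None):
    """PROcrustean randomisation TEST between two score matrices.

    Both matrices are column-centred and scaled to unit total sum of
    squares; the symmetric Procrustes statistic is
    m2 = 1 - (sum of singular values of X'Y)^2, with correlation
    sqrt(1 - m2) and rmse sqrt(m2 / n).  Significance permutes the rows of
    Y (exhaustively when ``n_perm='all'``).
    Returns (ss_m2, rmse, correlation, p).
    """
    X = _matrix(scores_x)
    Y = _matrix(scores_y)
    n = len(X)
    if len(Y) != n or n < 3:
        raise ValueError("need matched score matrices with >= 3 specimens")
    k = min(X.shape[1], Y.shape[1])
    X = _protest_normalise(X[:, :k])
    Y = _protest_normalise(Y[:, :k])
    m2_obs = _procrustes_m2(X, Y)
    if n_perm == "all":
        count, total = 0, 0
        for perm in _permutations(range(n)):
            if _procrustes_m2(X, Y[list(perm)]) <= m2_obs + 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_perm)):
            if _procrustes_m2(X, Y[rng.permutation(n)]) <= m2_obs + 1e-12:
                count += 1
        p = (1 + count) / (1 + int(n_perm))
    corr = float(np.sqrt(max(1.0 - m2_obs, 0.0)))
    rmse = float(np.sqrt(m2_obs / n))
    return m2_obs, rmse, corr, p


def eigenvalue_correlation(spec_a, spec_b):
    """R^2 and p of the linear fit between two paired eigenvalue spectra
    (percent variance per axis)."""
    a = np.asarray(spec_a, dtype=float)
    b = np.asarray(spec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectra must have equal axis counts")
    if np.ptp(b) == 0:
        return 0.0, 1.0
    _, _, r2, p = linear_fit_r2(a, b)
    return r2, p


# ---------------------------------------------------------------------------
# Auxiliary statistics


def auxiliary_stats(a, b, kind: str, seed: int | None = None):
    """Welch's unequal-variance t test or Spearman rank correlation.

    Welch returns (t, df, p) with Welch-Satterthwaite degrees of freedom;
    Spearman returns (rho, n, p), with a permutation p-value (all n! or
    sampled) when n < 10 where the asymptotic approximation is poor.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind == "welch_t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 per sample")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            raise ValueError("zero variance in both samples")
        res = _stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.df), float(res.pvalue)
    if kind == "spearman":
        n = len(a)
        if n < 3 or len(b) != n:
            raise ValueError("need paired vectors with >= 3 entries")
        rho = float(_stats.spearmanr(a, b).statistic)
        if n < 10:
            ra = _stats.rankdata(a)
            rb = _stats.rankdata(b)

            def srho(perm_rb):
                return float(np.corrcoef(ra, perm_rb)[0, 1])

            count, total = 0, 0
            for perm in _permutations(range(n)):
                if abs(srho(rb[list(perm)])) >= abs(rho) - 1e-12:
                    count += 1
                total += 1
            p = count / total
        else:
            p = float(_stats.spearmanr(a, b).pvalue)
        return rho, n, p
    raise ValueError(f"unknown kind: {kind}")


# ---------------------------------------------------------------------------
# Heatmap fields


def per_vertex_distance(
    a: TriangleMesh, b: TriangleMesh, mode: str = "corresponding", signed: bool = False
) -> np.ndarray:
    """Per-vertex scalar distance field from mesh ``a`` to mesh ``b``.

    ``corresponding`` requires equal vertex counts and ordering and measures
    |a_i - b_i|; ``closest`` measures distance to the nearest point on the
    surface of ``b``.  ``signed`` multiplies by the sign of the
    displacement's projection on a's outward vertex normal (corresponding
    mode) or on the direction from b's surface (closest mode uses a's
    normals against the offset to the nearest surface point as well).
    """
    if mode == "corresponding":
        if a.n_vertices != b.n_vertices:
            raise ValueError("corresponding mode requires equal vertex counts")
        disp = b.vertices - a.vertices
        d = np.linalg.norm(disp, axis=1)
    elif mode == "closest":
        d = closest_point_distance(a.vertices, b)
        disp = None
    else:
        raise ValueError(f"unknown mode: {mode}")
    if signed:
        normals = _vertex_normals(a)
        if disp is None:
            # Sign by whether the vertex lies outside (along its normal) of b's
            # nearest surface: approximate with displacement to b's centroid-free
            # offset via a small normal step comparison.
            eps = 1e-3 * max(np.ptp(a.vertices), 1.0)
            d_out = closest_point_distance(a.vertices + eps * normals, b)
            sign = np.where(d_out >= d, 1.0, -1.0)
        else:
            proj = np.einsum("ij,ij->i", disp, normals)
            sign = np.where(proj >= 0, 1.0, -1.0)
        d = sign * d
    return d


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.vertices[mesh.faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1)
    norms[norms == 0] = 1.0
    return vn / norms[:, None]
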