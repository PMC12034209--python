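"""Macroevolutionary statistics on multivariate shape data.

Phylogenetic signal is the multivariate generalisation of Blomberg's K: the
ratio of ordinary to phylogenetically weighted summed squared distances of
tip shapes from the generalised-least-squares root estimate, divided by its
Brownian-motion expectation, so that the univariate case reduces exactly to
Blomberg's K and a star phylogeny gives K = 1.  Group disparity is the
Procrustes variance, and group evolutionary rates are multivariate Brownian
rates compared by simulation under a pooled single-rate null.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import PhylogenyError
from .shape_space import ShapeScores

__all__ = [
    "Phylogeny",
    "GroupLabels",
    "read_newick",
    "phylo_covariance",
    "simulate_bm",
    "kmult",
    "morphological_disparity",
    "compare_evolutionary_rates",
]


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths whose tips index specimens."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise PhylogenyError("duplicate tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None or edge.length <= 0:
                raise PhylogenyError("all branch lengths must be positive")

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def tip_depths(self) -> dict:
        depths = {}
        for leaf in self.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths


def read_newick(path_or_string) -> Phylogeny:
    s = str(path_or_string)
    try:
        if s.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=s, schema="newick", preserve_underscores=True)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise PhylogenyError(f"could not parse Newick input: {exc}") from exc
    return Phylogeny(tree)


def phylo_covariance(phy: Phylogeny, tip_order: list | None = None) -> np.ndarray:
    """C_ij = shared root-to-tip path length of tips i and j."""
    order = tip_order or phy.tip_labels
    index = {label: i for i, label in enumerate(order)}
    missing = set(phy.tip_labels) - set(order)
    if missing or len(order) != phy.n_tips:
        raise PhylogenyError("tip_order must be exactly the tree's tips")
    n = len(order)
    C = np.zeros((n, n))
    # Depth-first accumulation: each edge contributes its length to every
    # pair of tips in the clade below it.
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = [index[leaf.taxon.label] for leaf in node.leaf_iter()]
        length = node.edge.length or 0.0
        C[np.ix_(tips, tips)] += length
    return C


def simulate_bm(
    phy: Phylogeny,
    n_traits: int,
    rate=1.0,
    rng: np.random.Generator | None = None,
    tip_order: list | None = None,
) -> np.ndarray:
    """Brownian motion along branches from a zero root state.

    ``rate`` is either a scalar variance per unit branch length or a mapping
    ``tip-clade group -> rate`` paired with per-node group assignment via
    ``rate[group_of_edge]`` when given as ``(groups, rate_map)``; see
    ``compare_evolutionary_rates`` for the grouped use.
    """
    rng = rng or np.random.default_rng()
    order = tip_order or phy.tip_labels
    index = {label: i for i, label in enumerate(order)}
    values = {phy.tree.seed_node: np.zeros(n_traits)}
    if isinstance(rate, tuple):
        groups, rate_map = rate
        def edge_rate(node):
            tips = [leaf.taxon.label for leaf in node.leaf_iter()]
            labels = {groups[t] for t in tips if t in groups}
            if len(labels) == 1:
                return rate_map[labels.pop()]
            return float(np.mean(list(rate_map.values())))
    else:
        def edge_rate(node):
            return float(rate)
    out = np.zeros((len(order), n_traits))
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        sd = np.sqrt(edge_rate(node) * (node.edge.length or 0.0))
        values[node] = values[node.parent_node] + sd * rng.standard_normal(n_traits)
        if node.is_leaf():
            out[index[node.taxon.label]] = values[node]
    return out


# ---------------------------------------------------------------------------
# K_mult


def _gls_root(Y: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    ones = np.ones(len(Y))
    w = Cinv @ ones
    return (w @ Y) / (ones @ w)


def _kmult_stat(Y: np.ndarray, C: np.ndarray, Cinv: np.ndarray) -> float:
    n = len(Y)
    a = _gls_root(Y, Cinv)
    E = Y - a
    num = float(np.sum(E * E))
    den = float(np.einsum("id,ij,jd->", E, Cinv, E))
    if den <= 0 or num <= 0:
        raise ValueError("zero total variance")
    ones = np.ones(n)
    expectation = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return (num / den) / expectation


def kmult(
    scores,
    phy: Phylogeny,
    n_perm: int = 99,
    seed: int | None = None,
) -> tuple[float, float]:
    """Multivariate phylogenetic signal with a tip-shuffling permutation test.

    p = (1 + #{K_perm >= K_obs}) / (1 + n_perm).
    """
    Y, order = _scores_matrix(scores)
    if phy.n_tips < 4:
        raise ValueError("need >= 4 tips")
    C = phylo_covariance(phy, tip_order=order)
    Cinv = _chol_inverse(C)
    k_obs = _kmult_stat(Y, C, Cinv)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(Y))
        if _kmult_stat(Y[perm], C, Cinv) >= k_obs:
            count += 1
    return k_obs, (1 + count) / (1 + n_perm)


def _chol_inverse(C: np.ndarray) -> np.ndarray:
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise PhylogenyError("phylogenetic covariance is not positive definite") from exc
    Linv = np.linalg.inv(L)
    return Linv.T @ Linv


def _scores_matrix(scores):
    if isinstance(scores, ShapeScores):
        return np.asarray(scores.scores, dtype=float), list(scores.specimen_ids)
    Y = np.asarray(scores, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y, [str(i) for i in range(len(Y))]


# ---------------------------------------------------------------------------
# Disparity


@dataclass
class GroupLabels:
    """specimen id -> categorical label."""

    labels: dict

    def vector(self, ids: list) -> np.ndarray:
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise KeyError(f"unlabelled specimens: {missing[:5]}")
        return np.array([self.labels[i] for i in ids])


def _procrustes_variance(Y: np.ndarray) -> float:
    c = Y - Y.mean(axis=0)
    return float(np.sum(c * c)) / len(Y)


def morphological_disparity(
    scores,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
):
    """Per-group Procrustes variance PV_g = sum_i |y_i - ybar_g|^2 / n_g and
    permutation p-values (group-label shuffling) for each pairwise |PV_a - PV_b|."""
    Y, ids = _scores_matrix(scores)
    g = groups.vector(ids) if isinstance(groups, GroupLabels) else np.asarray(groups)
    cats = sorted(set(g.tolist()))
    counts = {c: int(np.sum(g == c)) for c in cats}
    if min(counts.values()) < 2:
        raise ValueError("every group needs >= 2 specimens")
    pv = {c: _procrustes_variance(Y[g == c]) for c in cats}
    rng = np.random.default_rng(seed)
    pairs = [(a, b) for i, a in enumerate(cats) for b in cats[i + 1 :]]
    obs = {p: abs(pv[p[0]] - pv[p[1]]) for p in pairs}
    counts_ge = {p: 0 for p in pairs}
    for _ in range(n_perm):
        gp = rng.permutation(g)
        pvp = {c: _procrustes_variance(Y[gp == c]) for c in cats}
        for p in pairs:
            if abs(pvp[p[0]] - pvp[p[1]]) >= obs[p] - 1e-15:
                counts_ge[p] += 1
    pvals = {p: (1 + counts_ge[p]) / (1 + n_perm) for p in pairs}
    return pv, pvals


# ---------------------------------------------------------------------------
# Evolutionary rates


def _group_rates(Y, C, Cinv, Cinv_sqrt, g):
    a = _gls_root(Y, Cinv)
    Z = Cinv_sqrt @ (Y - a)
    sq = np.sum(Z * Z, axis=1)
    d = Y.shape[1]
    return {c: float(sq[g == c].mean()) / d for c in sorted(set(g.tolist()))}


def compare_evolutionary_rates(
    scores,
    phy: Phylogeny,
    groups,
    n_sim: int = 100,
    seed: int | None = None,
):
    """Per-group multivariate Brownian rates and a simulation-based test of
    their ratio.

    sigma2_g is the mean squared norm of the phylogenetically transformed
    residuals (symmetric inverse square root of C, residuals about the GLS
    root) over the group's tips, divided by the trait dimension.  The
    statistic is max/min; its p-value comes from ``n_sim`` simulations under
    the pooled single-rate Brownian model on the same tree.
    """
    Y, ids = _scores_matrix(scores)
    g = groups.vector(ids) if isinstance(groups, GroupLabels) else np.asarray(groups)
    cats = sorted(set(g.tolist()))
    if set(ids) != set(phy.tip_labels):
        raise PhylogenyError("specimens and tree tips must match")
    C = phylo_covariance(phy, tip_order=ids)
    Cinv = _chol_inverse(C)
    eigval, eigvec = np.linalg.eigh(C)
    if eigval.min() <= 0:
        raise PhylogenyError("phylogenetic covariance is not positive definite")
    Cinv_sqrt = eigvec @ np.diag(eigval**-0.5) @ eigvec.T
    rates = _group_rates(Y, C, Cinv, Cinv_sqrt, g)
    vals = np.array([rates[c] for c in cats])
    ratio = float(vals.max() / vals.min()) if len(cats) > 1 else 1.0
    if len(cats) < 2:
        return rates, ratio, 1.0
    pooled = float(np.mean(np.sum((Cinv_sqrt @ (Y - _gls_root(Y, Cinv))) ** 2, axis=1)) / Y.shape[1])
    rng = np.random.default_rng(seed)
    d = Y.shape[1]
    count = 0
    for _ in range(n_sim):
        Ysim = simulate_bm(phy, d, rate=pooled, rng=rng, tip_order=ids)
        r = _group_rates(Ysim, C, Cinv, Cinv_sqrt, g)
        rv = np.array([r[c] for c in cats])
        if rv.max() / rv.min() >= ratio:
            count += 1
    p = (1 + count) / (1 + n_sim)
    return rates, ratio, p
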