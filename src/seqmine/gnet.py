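"""Regulatory module-network learning.

Differentially expressed genes are clustered by K-means on their
(z-scored) expression profiles; each cluster gets a binary decision tree
over transcription-factor (TF) expression whose leaves carry Gaussian
models of the member genes' expression in the conditions routed to them;
genes are then reassigned to the module whose tree gives their profile the
highest likelihood, and the refit/reassign loop iterates until the total
log-likelihood converges. Modules are scored by mean pairwise Pearson
correlation of member profiles and exported as a global TF→gene network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import NoTFError, SeqmineError, ValidationError

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GnetConfig:
    """Loop controls for module-network learning.

    ``n_clusters=None`` selects max(2, n_genes // 20) capped at 10.
    ``rel_tol`` is the relative total log-likelihood improvement below
    which the refit/reassign loop stops. ``variance_floor`` keeps leaf
    Gaussians proper on constant data.
    """

    n_clusters: int | None = None
    max_depth: int = 3
    max_iter: int = 100
    rel_tol: float = 1e-6
    seed: int = 0
    min_module_size: int = 2
    variance_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if self.rel_tol <= 0:
            raise ValidationError("rel_tol must be > 0")

    def resolve_k(self, n_genes: int) -> int:
        k = self.n_clusters if self.n_clusters is not None else min(
            10, max(2, n_genes // 20)
        )
        if k > n_genes:
            logger.warning("K=%d > %d genes; reducing K", k, n_genes)
            k = n_genes
        return k


@dataclass
class TreeNode:
    """Internal node (tf, threshold, children) or leaf (mean, variance)."""

    tf: str | None = None
    threshold: float = 0.0
    left: "TreeNode | None" = None   # conditions with TF expression < threshold
    right: "TreeNode | None" = None  # conditions with TF expression >= threshold
    mean: float = 0.0
    variance: float = 1.0

    @property
    def is_leaf(self) -> bool:
        return self.tf is None


@dataclass
class RegulatoryTree:
    """Binary TF decision tree over conditions with Gaussian leaves."""

    root: TreeNode
    used_tfs: list[str]

    def leaf_params(self, tf_expr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Per-condition (mean, variance) after routing each condition.

        ``tf_expr`` is TFs × conditions; every condition reaches exactly
        one leaf.
        """
        n_cond = tf_expr.shape[1]
        mu = np.empty(n_cond)
        var = np.empty(n_cond)
        for c in range(n_cond):
            node = self.root
            while not node.is_leaf:
                val = tf_expr.at[node.tf, tf_expr.columns[c]]
                node = node.left if val < node.threshold else node.right
            mu[c], var[c] = node.mean, node.variance
        return mu, var

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def render(self, indent: str = "  ") -> str:
        """Indented text rendering, for reports."""
        lines: list[str] = []

        def _walk(node: TreeNode, depth: int) -> None:
            pad = indent * depth
            if node.is_leaf:
                lines.append(f"{pad}leaf: mean={node.mean:.3f} var={node.variance:.3f}")
            else:
                lines.append(f"{pad}{node.tf} < {node.threshold:.3f} ?")
                _walk(node.left, depth + 1)
                _walk(node.right, depth + 1)

        _walk(self.root, 0)
        return "\n".join(lines)


@dataclass
class RegulatoryModule:
    module_id: int
    members: list[str]
    tree: RegulatoryTree
    correlation_score: float
    log_likelihood: float


@dataclass
class RegulatoryNetwork:
    """Global TF→gene edge set over the exported modules."""

    edges: set[tuple[str, str, int]]
    tf_nodes: set[str]
    gene_nodes: set[str]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class GnetResult:
    modules: list[RegulatoryModule]
    assignment: pd.Series  # gene -> module_id
    trace: list[float]
    n_iter: int
    converged: bool


def require_tfs(de_genes: Iterable[str], tf_list: Iterable[str]) -> set[str]:
    """TFs usable as regulators: the intersection of the TF list with DE genes.

    Module-network learning needs at least one transcription factor; an
    empty intersection aborts the stage (the pipeline logs and skips it).
    """
    usable = set(de_genes) & set(tf_list)
    if not usable:
        raise NoTFError("no transcription factors among the DE genes")
    return usable


def kmeans_init(expr: pd.DataFrame, k: int, seed: int) -> np.ndarray:
    """K-means cluster labels on per-gene z-scored profiles (deterministic)."""
    z = _zscore_rows(expr.to_numpy(dtype=float))
    k = min(k, len(expr))
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(z)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _gaussian_ll(values: np.ndarray, floor: float) -> tuple[float, float, float]:
    """(log-likelihood, mean, variance) of values under their own ML Gaussian."""
    n = values.size
    mu = float(values.mean())
    var = max(float(values.var()), floor)
    ll = -0.5 * n * (_LOG_2PI + math.log(var)) - float(
        ((values - mu) ** 2).sum()
    ) / (2.0 * var)
    return ll, mu, var


def learn_tree(
    member_expr: np.ndarray,
    tf_expr: pd.DataFrame,
    config: GnetConfig,
) -> RegulatoryTree:
    """Greedy top-down binary decision tree over TF expression.

    ``member_expr`` is members × conditions; ``tf_expr`` is TFs ×
    conditions (same column order). At each node, candidate splits are
    (tf, threshold) with thresholds at midpoints between consecutive
    distinct TF values over the node's conditions; the split maximizing
    the pooled Gaussian log-likelihood gain of the member expression
    values is taken; growth stops at ``max_depth`` or when no split has
    positive gain. Leaves store the ML mean and (floored) variance of all
    member values in their conditions.
    """
    if member_expr.ndim != 2:
        raise ValidationError("member_expr must be 2-D (members x conditions)")
    tf_values = tf_expr.to_numpy(dtype=float) if len(tf_expr) else np.empty((0, member_expr.shape[1]))
    tf_ids = list(tf_expr.index)
    used: list[str] = []

    def _grow(cond_idx: np.ndarray, depth: int) -> TreeNode:
        values = member_expr[:, cond_idx].ravel()
        ll_here, mu, var = _gaussian_ll(values, config.variance_floor)
        leaf = TreeNode(mean=mu, variance=var)
        if depth >= config.max_depth or len(cond_idx) < 2:
            return leaf
        best_gain = 0.0
        best: tuple[int, float, np.ndarray] | None = None
        for ti in range(len(tf_ids)):
            vals = tf_values[ti, cond_idx]
            distinct = np.unique(vals)
            if distinct.size < 2:
                continue
            for lo, hi in zip(distinct[:-1], distinct[1:]):
                thr = 0.5 * (lo + hi)
                left_mask = vals < thr
                left_vals = member_expr[:, cond_idx[left_mask]].ravel()
                right_vals = member_expr[:, cond_idx[~left_mask]].ravel()
                ll_l, _, _ = _gaussian_ll(left_vals, config.variance_floor)
                ll_r, _, _ = _gaussian_ll(right_vals, config.variance_floor)
                gain = ll_l + ll_r - ll_here
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best = (ti, thr, left_mask)
        if best is None:
            return leaf
        ti, thr, left_mask = best
        tf_id = tf_ids[ti]
        if tf_id not in used:
            used.append(tf_id)
        return TreeNode(
            tf=tf_id,
            threshold=thr,
            left=_grow(cond_idx[left_mask], depth + 1),
            right=_grow(cond_idx[~left_mask], depth + 1),
        )

    root = _grow(np.arange(member_expr.shape[1]), 0)
    return RegulatoryTree(root=root, used_tfs=used)


def gene_log_likelihood(
    profile: np.ndarray, tree: RegulatoryTree, tf_expr: pd.DataFrame
) -> float:
    """Sum over conditions of log N(x_c; mu_leaf(c), var_leaf(c))."""
    profile = np.asarray(profile, dtype=float)
    if profile.size != tf_expr.shape[1]:
        raise ValidationError(
            f"profile length {profile.size} != {tf_expr.shape[1]} conditions"
        )
    mu, var = tree.leaf_params(tf_expr)
    return float(
        (-0.5 * (_LOG_2PI + np.log(var)) - (profile - mu) ** 2 / (2 * var)).sum()
    )


def _ll_matrix(
    expr: np.ndarray, trees: Sequence[RegulatoryTree], tf_expr: pd.DataFrame
) -> np.ndarray:
    """genes × trees log-likelihoods, vectorized over genes."""
    out = np.empty((expr.shape[0], len(trees)))
    for j, tree in enumerate(trees):
        mu, var = tree.leaf_params(tf_expr)
        out[:, j] = (
            -0.5 * (_LOG_2PI + np.log(var)) - (expr - mu) ** 2 / (2 * var)
        ).sum(axis=1)
    return out


def reassign(
    expr: np.ndarray,
    trees: Sequence[RegulatoryTree],
    tf_expr: pd.DataFrame,
    min_module_size: int = 2,
) -> tuple[np.ndarray, list[int]]:
    """Assign each gene to the tree that best explains its profile.

    Ties break toward the lowest module index. Modules ending up smaller
    than ``min_module_size`` are dissolved (smallest first) and their
    members redistributed to the next-best surviving module. Returns the
    assignment (as indices into ``trees``) and the surviving tree indices.
    """
    if len(trees) == 0:
        raise ValidationError("need at least one tree")
    ll = _ll_matrix(expr, trees, tf_expr)
    active = list(range(len(trees)))
    while True:
        sub = ll[:, active]
        labels = np.asarray(active)[np.argmax(sub, axis=1)]
        sizes = {m: int((labels == m).sum()) for m in active}
        if len(active) == 1:
            return labels, active
        undersized = [m for m in active if sizes[m] < min_module_size]
        if not undersized:
            return labels, active
        # dissolve the smallest offending module (lowest id on ties)
        victim = min(undersized, key=lambda m: (sizes[m], m))
        active.remove(victim)


def module_correlation(member_expr: np.ndarray) -> tuple[float, bool]:
    """Mean pairwise Pearson correlation of member profiles.

    Returns (score, flagged); flagged is True for the degenerate cases
    (fewer than 2 members -> score 1.0 by convention; zero-variance
    profiles, whose pairs contribute 0).
    """
    m = member_expr.shape[0]
    if m < 2:
        return 1.0, True
    sd = member_expr.std(axis=1)
    flagged = bool((sd == 0).any())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(member_expr)
    corr = np.nan_to_num(corr, nan=0.0)
    iu = np.triu_indices(m, k=1)
    return float(corr[iu].mean()), flagged


def fit(
    expr: pd.DataFrame,
    tf_expr: pd.DataFrame,
    config: GnetConfig = GnetConfig(),
) -> GnetResult:
    """Learn regulatory modules by iterated tree refit and gene reassignment.

    ``expr`` is member genes × conditions (the genes being clustered);
    ``tf_expr`` is TFs × the same conditions. K-means seeds the clusters;
    each iteration refits one tree per module (keeping the previous tree
    when the refit does not improve the current members' likelihood, so
    the loop is monotone) and reassigns genes by likelihood; the loop
    stops when the relative total log-likelihood improvement drops below
    ``rel_tol`` or after ``max_iter`` iterations.
    """
    if list(expr.columns) != list(tf_expr.columns):
        raise ValidationError("expr and tf_expr must share condition columns")
    if len(tf_expr) == 0:
        raise NoTFError("no TF expression profiles supplied")
    genes = list(expr.index)
    x = expr.to_numpy(dtype=float)
    k = config.resolve_k(len(genes))
    labels = kmeans_init(expr, k, config.seed)

    # drop undersized seed clusters before the first trace entry; genes from
    # dropped clusters go to their best-likelihood surviving tree
    keep = [m for m in range(k) if (labels == m).sum() >= config.min_module_size]
    if not keep:
        keep = [int(np.bincount(labels).argmax())]
    trees = [learn_tree(x[labels == m], tf_expr, config) for m in keep]
    remap = {m: i for i, m in enumerate(keep)}
    ll_mat = _ll_matrix(x, trees, tf_expr)
    labels = np.asarray(
        [
            remap[int(lab)] if int(lab) in remap else int(np.argmax(ll_mat[i]))
            for i, lab in enumerate(labels)
        ]
    )
    total = float(ll_mat[np.arange(len(genes)), labels].sum())
    trace = [total]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        new_trees = []
        for m, old_tree in enumerate(trees):
            members = x[labels == m]
            cand = learn_tree(members, tf_expr, config)
            # keep-best: never let a refit lower the current members' likelihood
            ll_old = _ll_matrix(members, [old_tree], tf_expr).sum()
            ll_new = _ll_matrix(members, [cand], tf_expr).sum()
            new_trees.append(cand if ll_new >= ll_old else old_tree)
        trees = new_trees
        labels, active = reassign(x, trees, tf_expr, config.min_module_size)
        trees = [trees[i] for i in active]
        labels = _compact(labels, active)
        ll_mat = _ll_matrix(x, trees, tf_expr)
        total_new = float(ll_mat[np.arange(len(genes)), labels].sum())
        trace.append(total_new)
        if abs(total_new - total) <= config.rel_tol * max(abs(total), 1.0):
            total = total_new
            converged = True
            break
        total = total_new

    modules = []
    for m, tree in enumerate(trees):
        member_ids = [g for g, lab in zip(genes, labels) if lab == m]
        member_x = x[labels == m]
        score, _ = module_correlation(member_x)
        ll_m = float(ll_mat[labels == m, m].sum())
        modules.append(
            RegulatoryModule(
                module_id=m,
                members=member_ids,
                tree=tree,
                correlation_score=score,
                log_likelihood=ll_m,
            )
        )
    assignment = pd.Series(labels, index=pd.Index(genes, name="gene"), name="module_id")
    return GnetResult(
        modules=modules,
        assignment=assignment,
        trace=trace,
        n_iter=n_iter,
        converged=converged,
    )


def _compact(labels: np.ndarray, active: Sequence[int]) -> np.ndarray:
    """Renumber labels to 0..len(active)-1 in active order."""
    remap = {m: i for i, m in enumerate(active)}
    return np.asarray([remap[int(l)] for l in labels])


def export_network(
    modules: Sequence[RegulatoryModule], top_n: int = 10
) -> RegulatoryNetwork:
    """Edge set of the top modules ranked by expression correlation score.

    One edge per (tf in the module's tree) × (member gene); self-edges are
    dropped. When fewer than ``top_n`` modules exist, all are used.
    """
    if len(modules) == 0:
        raise SeqmineError("no modules to export")
    if top_n > len(modules):
        logger.warning("top_n=%d > %d modules; using all", top_n, len(modules))
    ranked = sorted(modules, key=lambda m: (-m.correlation_score, m.module_id))
    edges: set[tuple[str, str, int]] = set()
    tf_nodes: set[str] = set()
    gene_nodes: set[str] = set()
    for module in ranked[:top_n]:
        for tf in module.tree.used_tfs:
            for gene in module.members:
                if tf == gene:
                    continue
                edges.add((tf, gene, module.module_id))
                tf_nodes.add(tf)
                gene_nodes.add(gene)
    return RegulatoryNetwork(edges=edges, tf_nodes=tf_nodes, gene_nodes=gene_nodes)
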