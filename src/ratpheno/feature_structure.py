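"""Relationships among behavioral variables.

Spearman correlation structure, hierarchical clustering of variables under a
sign-independent Euclidean distance (so that perfectly anti-correlated
Z-scored variables are treated as identical), cophenetic validation of the
tree, chi-squared tests of cluster × valence/test separation, subsampling
permutation reliability of that separation, and common factor analysis with
varimax rotation.

The sign-independent distance is the method-defining primitive here:
``d(x, y) = min(‖x − y‖₂, ‖x + y‖₂)``. On Z-scored variable vectors it sends
a variable and its negation to distance 0, letting Ward's method assemble
variables by strength of association regardless of direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import num_obs_y, pdist, squareform

from . import stats as rstats
from .core_data import DegenerateDataError, ZScoredMatrix
from .synthetic import shuffle_dataset, subsample

__all__ = [
    "CorrelationMatrix",
    "LinkageTree",
    "ClusterAssignment",
    "PermutationSummary",
    "FactorSolution",
    "spearman_matrix",
    "sign_independent_distance",
    "sign_independent_pdist",
    "ward_linkage",
    "cophenetic_coefficient",
    "cut_tree",
    "label_separation_test",
    "clustering_reliability",
    "varimax",
    "factor_analysis",
]


def _as_array(Z) -> np.ndarray:
    return Z.values if isinstance(Z, ZScoredMatrix) else np.asarray(Z, dtype=float)


def _columns_of(Z, P: int) -> list[str]:
    if isinstance(Z, ZScoredMatrix):
        return list(Z.columns)
    return [f"var{j}" for j in range(P)]


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho with two-sided p values."""

    r: np.ndarray
    p: np.ndarray
    names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.names, columns=self.names)


@dataclass
class LinkageTree:
    """Agglomerative merge sequence in scipy's 4-column linkage format.

    Each row of ``merges`` is (node_a, node_b, height, size); heights are the
    dissimilarity at which the pair merged. ``labels`` name the leaves.
    """

    merges: np.ndarray
    labels: list[str]
    metric: str

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Plain Newick export of the merge tree (heights as branch lengths)."""
        n = self.n_leaves
        node: dict[int, tuple[str, float]] = {
            i: (self.labels[i], 0.0) for i in range(n)
        }
        for k, (a, b, h, _sz) in enumerate(self.merges):
            (sa, ha), (sb, hb) = node[int(a)], node[int(b)]
            rep = f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})"
            node[n + k] = (rep, float(h))
        return node[2 * n - 2][0] + ";"


@dataclass
class ClusterAssignment:
    """Item → cluster labels with optional diagnostics."""

    labels: np.ndarray
    k: int
    method: str
    silhouette: np.ndarray | None = None
    inertia: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def mean_silhouette(self) -> float | None:
        return None if self.silhouette is None else float(np.mean(self.silhouette))


@dataclass
class PermutationSummary:
    """Outcome of a resampling reliability run."""

    n_iter: int
    fraction_significant: float
    alpha: float
    null_kind: str  # "subsample" or "shuffled"
    p_values: np.ndarray
    n_skipped: int = 0


@dataclass
class FactorSolution:
    """Common-factor solution: loadings, uniquenesses, rotation applied."""

    loadings: np.ndarray
    uniquenesses: np.ndarray
    rotation: str
    names: list[str]
    converged: bool = True
    heywood: bool = False

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"factor{j + 1}" for j in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.names, columns=cols)


# -- correlation --------------------------------------------------------------


def spearman_matrix(Z: "ZScoredMatrix | np.ndarray") -> CorrelationMatrix:
    """Pairwise Spearman correlation among variables (mid-ranks for ties)."""
    X = _as_array(Z)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 observations for the correlation matrix")
    if (X.std(axis=0) == 0).any():
        bad = [c for c, s in zip(_columns_of(Z, X.shape[1]), X.std(axis=0)) if s == 0]
        raise DegenerateDataError(f"constant columns have undefined correlation: {bad}")
    rho, p = sps.spearmanr(X, axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(r=rho, p=p, names=_columns_of(Z, X.shape[1]))


# -- distances and trees -------------------------------------------------------


def sign_independent_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """min(‖x−y‖₂, ‖x+y‖₂): Euclidean distance up to a global sign flip."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(min(np.linalg.norm(x - y), np.linalg.norm(x + y)))


def sign_independent_pdist(items: np.ndarray) -> np.ndarray:
    """Condensed pairwise sign-independent distances between rows of ``items``."""
    X = np.asarray(items, dtype=float)
    sq = (X**2).sum(axis=1)
    gram = X @ X.T
    d_minus = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * gram, 0.0))
    d_plus = np.sqrt(np.maximum(sq[:, None] + sq[None, :] + 2 * gram, 0.0))
    d = np.minimum(d_minus, d_plus)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def correlation_pdist(items: np.ndarray, kind: str = "one_minus_abs_spearman") -> np.ndarray:
    """Condensed 1−|rho| distances between rows (variables as items)."""
    rho, _ = sps.spearmanr(items.T, axis=0)
    if np.ndim(rho) == 0:
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - np.abs(rho)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def ward_linkage(items: np.ndarray, metric: str = "euclidean") -> LinkageTree:
    """Ward minimum-variance agglomeration over the rows of ``items``.

    ``metric`` is ``"euclidean"``, ``"sign_independent"``,
    ``"one_minus_abs_spearman"``, or ``"precomputed"`` (then ``items`` is a
    condensed distance vector). Non-Euclidean metrics are fed through the
    Lance–Williams Ward update as if they were Euclidean, the standard
    practical approximation.
    """
    if metric == "precomputed":
        y = np.asarray(items, dtype=float)
        n = num_obs_y(y)
        labels = [f"item{i}" for i in range(n)]
    else:
        X = np.asarray(items, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need at least 2 items to cluster")
        labels = [f"item{i}" for i in range(X.shape[0])]
        if metric == "euclidean":
            y = pdist(X, metric="euclidean")
        elif metric == "sign_independent":
            y = sign_independent_pdist(X)
        elif metric == "one_minus_abs_spearman":
            y = correlation_pdist(X)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    if np.isnan(y).any():
        raise ValueError("NaN distances: cannot build the linkage tree")
    merges = sch.linkage(y, method="ward")
    return LinkageTree(merges=merges, labels=labels, metric=metric)


def cophenetic_coefficient(tree: LinkageTree, d: np.ndarray) -> float:
    """Correlation between tree-implied (cophenetic) and original distances."""
    d = np.asarray(d, dtype=float)
    if d.ndim == 2:
        d = squareform(d, checks=False)
    if num_obs_y(d) != tree.n_leaves:
        raise ValueError("distances and tree cover different item sets")
    if tree.n_leaves < 3:
        raise ValueError("cophenetic correlation needs at least 3 items")
    c, _ = sch.cophenet(tree.merges, d)
    return float(c)


def cut_tree(tree: LinkageTree, k: int) -> ClusterAssignment:
    """Cut the tree into exactly ``k`` clusters (removing the k−1 tallest merges)."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k={k} out of range [1, {tree.n_leaves}]")
    labels = sch.fcluster(tree.merges, t=k, criterion="maxclust")
    return ClusterAssignment(labels=np.asarray(labels), k=int(len(set(labels))), method="ward")


def label_separation_test(
    assignment: ClusterAssignment, labels: Sequence
) -> rstats.ContingencyResult:
    """Chi-squared association between cluster membership and external labels."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(assignment.labels):
        raise ValueError("labels must cover every clustered item")
    if assignment.k < 2:
        raise ValueError("need at least 2 clusters to test separation")
    table = pd.crosstab(pd.Series(assignment.labels), pd.Series(labels)).to_numpy()
    return rstats.chi2_association(table)


# -- permutation reliability ---------------------------------------------------


def clustering_reliability(
    Z: "ZScoredMatrix | np.ndarray",
    var_labels: Sequence,
    fraction: float = 0.7,
    axis: str = "observations",
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    shuffled: bool = False,
    metric: str = "sign_independent",
    k: int = 2,
) -> PermutationSummary:
    """Reliability of the variable-cluster / label separation under subsampling.

    Each iteration subsamples ``fraction`` of the data along ``axis``
    (observations = rats, variables = columns), rebuilds the variable tree
    (Ward on the chosen metric), cuts it at ``k`` clusters and records the
    chi-squared p of cluster × ``var_labels`` association. The summary is the
    fraction of iterations with p < ``alpha``.

    ``shuffled=True`` runs the identical procedure on column-shuffled data
    (fresh shuffle each iteration), the null that destroys all covariance.
    Iterations whose subsample makes the test degenerate (e.g. one label
    class absent) are counted as non-significant.
    """
    X = _as_array(Z)
    var_labels = np.asarray(var_labels, dtype=object)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    ps = np.ones(n_iter)
    n_skipped = 0
    for it in range(n_iter):
        W = shuffle_dataset(X, rng) if shuffled else X
        if axis == "variables":
            sub, idx = subsample(W, fraction, axis="variables", seed=rng)
            lab = var_labels[idx]
        else:
            sub, _ = subsample(W, fraction, axis="observations", seed=rng)
            lab = var_labels
        try:
            tree = ward_linkage(sub.T, metric=metric)
            cut = cut_tree(tree, k)
            ps[it] = label_separation_test(cut, lab).p
        except ValueError:
            n_skipped += 1
            ps[it] = 1.0  # conservative: a degenerate iteration is not evidence
    frac = float(np.mean(ps < alpha))
    return PermutationSummary(
        n_iter=n_iter,
        fraction_significant=frac,
        alpha=alpha,
        null_kind="shuffled" if shuffled else "subsample",
        p_values=ps,
        n_skipped=n_skipped,
    )


# -- factor analysis -----------------------------------------------------------


def varimax(L: np.ndarray, normalize: bool = True, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal; Kaiser-normalized).

    Maximizes the variance of squared loadings within each factor. Being
    orthogonal, it leaves each variable's communality unchanged.
    """
    L = np.asarray(L, dtype=float)
    p, m = L.shape
    if m < 2:
        return L.copy()
    h = np.sqrt((L**2).sum(axis=1)) if normalize else np.ones(p)
    h = np.where(h == 0, 1.0, h)
    A = L / h[:, None]
    R = np.eye(m)
    var_old = 0.0
    for _ in range(max_iter):
        B = A @ R
        U, _s, Vt = np.linalg.svd(
            A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        R = U @ Vt
        var_new = float(_s.sum())
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    return (A @ R) * h[:, None]


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations as starting communalities."""
    try:
        Rinv = np.linalg.inv(R)
        smc = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        offdiag = R - np.eye(R.shape[0])
        smc = np.abs(offdiag).max(axis=1) ** 2
    return np.clip(smc, 0.0, 0.999)


def factor_analysis(
    Z: "ZScoredMatrix | np.ndarray",
    n_factors: int,
    rotation: str = "varimax",
    max_iter: int = 500,
    tol: float = 1e-8,
) -> FactorSolution:
    """Common factor analysis by iterated principal-axis factoring.

    The correlation matrix has its diagonal replaced by communality estimates
    (initialized at the squared multiple correlations) and is
    eigendecomposed; loadings come from the top ``n_factors`` eigenpairs and
    the communalities are re-estimated until convergence. Uniqueness is
    1 − communality by construction. Heywood cases (communality reaching 1)
    are clipped and flagged. Factors are ordered by explained variance and
    sign-fixed so each factor's largest-|loading| entry is positive.
    """
    X = _as_array(Z)
    P = X.shape[1]
    if not 1 <= n_factors < P:
        raise ValueError(f"n_factors must be in [1, {P - 1}]")
    R = np.corrcoef(X, rowvar=False)
    h2 = _smc(R)
    heywood = False
    converged = False
    L = np.zeros((P, n_factors))
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        w, V = np.linalg.eigh(Rr)
        order = np.argsort(w)[::-1][:n_factors]
        w_top = np.clip(w[order], 0.0, None)
        L = V[:, order] * np.sqrt(w_top)
        h2_new = np.clip((L**2).sum(axis=1), 0.0, 1.0)
        if ((L**2).sum(axis=1) > 1.0).any():
            heywood = True
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            converged = True
            break
        h2 = h2_new
    if rotation == "varimax":
        L = varimax(L)
    elif rotation not in {None, "none"}:
        raise ValueError(f"unknown rotation {rotation!r}")
    # order by explained variance, sign-fix for reproducibility
    order = np.argsort(-(L**2).sum(axis=0), kind="stable")
    L = L[:, order]
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
    h2 = np.clip((L**2).sum(axis=1), 0.0, 1.0)
    return FactorSolution(
        loadings=L,
        uniquenesses=1.0 - h2,
        rotation=rotation or "none",
        names=_columns_of(Z, P),
        converged=converged,
        heywood=heywood,
    )
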