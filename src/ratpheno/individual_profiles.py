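"""Clustering of individual rats into multivariate behavioral profiles.

Covers the helplessness classifier (k-means on shuttle-box escape failures
and mean escape latency), k-means profile discovery with many random
restarts, silhouette diagnostics, cluster-number selection (pure silhouette
or the semi-supervised rule that additionally requires the clusters to
separate the stress groups), hierarchical profile clustering, per-cluster
Z-profiles, and correspondence between two clusterings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from . import stats as rstats
from .core_data import BehavioralDataset, ZScoredMatrix, zscore
from .feature_structure import ClusterAssignment, LinkageTree, cut_tree, ward_linkage

__all__ = [
    "ClusterProfile",
    "KSelection",
    "Correspondence",
    "kmeans_best_of_restarts",
    "silhouette_values",
    "classify_helplessness",
    "select_k",
    "hier_profiles",
    "hierarchy_scan",
    "cluster_profiles",
    "cluster_correspondence",
]


def _as_array(Z) -> np.ndarray:
    return Z.values if isinstance(Z, ZScoredMatrix) else np.asarray(Z, dtype=float)


@dataclass
class ClusterProfile:
    """Per-cluster behavioral profile: mean Z ± SEM, sizes, group composition."""

    mean_z: np.ndarray  # clusters × variables
    sem_z: np.ndarray   # clusters × variables, NaN for singleton clusters
    sizes: np.ndarray
    composition: pd.DataFrame  # clusters × {NS, IS} counts
    cluster_ids: np.ndarray
    variable_names: list[str]


@dataclass
class KSelection:
    """Outcome of cluster-number selection."""

    k: int | None
    mode: str
    table: pd.DataFrame  # per-k mean silhouette (+ chi2 p in semi-supervised mode)
    reason: str = ""


@dataclass
class Correspondence:
    """Agreement between two clusterings of the same rats."""

    contingency: np.ndarray
    matched_pairs: list[tuple[int, int]]
    jaccard: list[float]
    agreement: float


# -- k-means and silhouettes ---------------------------------------------------


def kmeans_best_of_restarts(
    X: "ZScoredMatrix | np.ndarray",
    k: int,
    n_restarts: int = 10_000,
    seed: int | None = None,
) -> ClusterAssignment:
    """k-means (Lloyd, squared-Euclidean) keeping the best of many restarts.

    Initial centroids are drawn uniformly from the observations; the restart
    with the lowest within-cluster sum of squares (inertia) wins. Many
    restarts guard against convergence to local minima — the variability that
    motivates re-running the algorithm in the first place. Deterministic
    given ``seed``.
    """
    X = _as_array(X)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
    ).fit(X)
    labels = km.labels_.astype(int)
    sil, flags = (None, [])
    if 2 <= k < n or (k >= 2 and len(set(labels)) >= 2):
        try:
            sil, flags = silhouette_values(X, labels)
        except ValueError:
            sil, flags = None, ["silhouette undefined"]
    return ClusterAssignment(
        labels=labels,
        k=int(len(set(labels))),
        method="kmeans",
        silhouette=sil,
        inertia=float(km.inertia_),
        flags=flags,
    )


def silhouette_values(
    X: "ZScoredMatrix | np.ndarray",
    labels: Sequence[int],
    distance: str = "sqeuclidean",
) -> tuple[np.ndarray, list[str]]:
    """Per-item silhouette values s_i = (b_i − a_i)/max(a_i, b_i).

    a_i is the mean distance to the other members of the item's cluster and
    b_i the mean distance to the members of the closest other cluster.
    Distances default to squared Euclidean, consistent with the k-means
    objective. Conventions for degenerate cases, each flagged: singleton
    clusters get s = 1; an item with a_i = b_i = 0 gets s = 0.
    """
    X = _as_array(X)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if distance not in {"sqeuclidean", "euclidean"}:
        raise ValueError(f"unknown distance {distance!r}")
    D = cdist(X, X, metric=distance)
    n = X.shape[0]
    s = np.zeros(n)
    flags: list[str] = []
    members = {c: np.where(labels == c)[0] for c in uniq}
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 1.0
            flags.append(f"item {i}: singleton cluster, s=1 by convention")
            continue
        a = D[i, own[own != i]].mean()
        b = min(D[i, members[c]].mean() for c in uniq if c != labels[i])
        m = max(a, b)
        if m == 0:
            s[i] = 0.0
            flags.append(f"item {i}: zero distances, s=0 by convention")
        else:
            s[i] = (b - a) / m
    return s, flags


# -- helplessness --------------------------------------------------------------


def classify_helplessness(
    dataset: BehavioralDataset,
    failures_var: str = "SB_escape_failures",
    latency_var: str = "SB_mean_escape_latency",
    k_candidates: Sequence[int] = (2, 3, 4),
    n_restarts: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, ClusterAssignment]:
    """Classify rats as helpless (H) or non-helpless (NH) from the shuttle box.

    The two escape-performance variables are Z-scored and k-means clustered;
    the number of clusters is chosen by mean silhouette over
    ``k_candidates``. The cluster with the highest mean (Z-scored) escape
    failures is labeled H; all other clusters are NH. Returns the per-rat
    H/NH labels and the underlying cluster assignment.
    """
    try:
        pair = np.column_stack([dataset.column(failures_var), dataset.column(latency_var)])
    except KeyError as e:
        raise ValueError(f"dataset lacks a required shuttle-box variable: {e}") from e
    Z2 = zscore(pair).values  # raises DegenerateDataError if a variable is constant
    best = None
    for k in k_candidates:
        a = kmeans_best_of_restarts(Z2, k, n_restarts=n_restarts, seed=seed)
        if a.mean_silhouette is None:
            continue
        if best is None or a.mean_silhouette > best.mean_silhouette:
            best = a
    if best is None:
        raise ValueError("no candidate k produced a valid silhouette")
    means = [Z2[best.labels == c, 0].mean() for c in range(best.k)]
    h_cluster = int(np.argmax(means))
    hn = np.where(best.labels == h_cluster, "H", "NH").astype(object)
    return hn, best


# -- cluster-number selection --------------------------------------------------


def select_k(
    X: "ZScoredMatrix | np.ndarray",
    k_range: Sequence[int],
    mode: str = "silhouette",
    groups: Sequence | None = None,
    delta: float = 0.02,
    alpha: float = 0.05,
    n_restarts: int = 1000,
    seed: int | None = None,
) -> KSelection:
    """Choose the number of k-means clusters.

    ``mode="silhouette"`` returns the k with the highest mean silhouette.
    ``mode="semi_supervised"`` implements the study's rule: among the
    candidate k whose mean silhouette is within ``delta`` of the maximum,
    return the largest k whose cluster × group chi-squared is significant at
    ``alpha`` — i.e. the finest clustering that is both internally compact
    and still separates the stress groups. If no candidate qualifies the
    selection is explicit ``None``.
    """
    X = _as_array(X)
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k > X.shape[0] - 1 for k in k_range):
        raise ValueError(f"k_range must lie within [2, {X.shape[0] - 1}]")
    if mode not in {"silhouette", "semi_supervised"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "semi_supervised" and groups is None:
        raise ValueError("semi_supervised selection needs group labels")
    rows = []
    assignments: dict[int, ClusterAssignment] = {}
    for k in k_range:
        a = kmeans_best_of_restarts(X, k, n_restarts=n_restarts, seed=seed)
        assignments[k] = a
        row = {"k": k, "mean_silhouette": a.mean_silhouette}
        if mode == "semi_supervised":
            try:
                from .feature_structure import label_separation_test

                row["chi2_p"] = label_separation_test(a, np.asarray(groups, dtype=object)).p
            except ValueError:
                row["chi2_p"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    if mode == "silhouette":
        k_best = int(table.loc[table["mean_silhouette"].idxmax(), "k"])
        return KSelection(k=k_best, mode=mode, table=table)
    top = table["mean_silhouette"].max()
    ok = table[(table["mean_silhouette"] >= top - delta) & (table["chi2_p"] < alpha)]
    if ok.empty:
        return KSelection(
            k=None, mode=mode, table=table,
            reason="no k is both near-top in silhouette and group-separating",
        )
    return KSelection(k=int(ok["k"].max()), mode=mode, table=table)


# -- hierarchical profiles -----------------------------------------------------


def hier_profiles(Z: "ZScoredMatrix | np.ndarray", k: int) -> ClusterAssignment:
    """Ward/Euclidean hierarchical clustering of rats, cut at k clusters."""
    X = _as_array(Z)
    tree = ward_linkage(X, metric="euclidean")
    cut = cut_tree(tree, k)
    sil, flags = (None, [])
    if cut.k >= 2:
        sil, flags = silhouette_values(X, cut.labels)
    return ClusterAssignment(
        labels=cut.labels, k=cut.k, method="ward", silhouette=sil, flags=flags
    )


def hierarchy_scan(
    tree: LinkageTree, groups: Sequence, k_range: Sequence[int] = range(2, 8)
) -> pd.DataFrame:
    """Chi-squared of cluster × group at every cut height k in ``k_range``.

    Degenerate cuts are flagged instead of raised: a cut whose table cannot
    be tested (empty marginal) gets a NaN p, and a cut whose table has
    expected counts below 1 (inevitable as k approaches n) keeps its chi2 but
    carries the degenerate flag, since the chi-squared approximation is
    unreliable there.
    """
    from .feature_structure import label_separation_test

    groups = np.asarray(groups, dtype=object)
    rows = []
    for k in k_range:
        cut = cut_tree(tree, int(k))
        try:
            res = label_separation_test(cut, groups)
            rows.append({"k": int(k), "chi2": res.chi2, "df": res.df, "p": res.p,
                         "degenerate": bool((res.expected < 1).any())})
        except ValueError:
            rows.append({"k": int(k), "chi2": np.nan, "df": np.nan, "p": np.nan,
                         "degenerate": True})
    return pd.DataFrame(rows)


def cluster_profiles(
    Z: "ZScoredMatrix | np.ndarray",
    assignment: ClusterAssignment,
    groups: Sequence,
) -> ClusterProfile:
    """Per-cluster mean Z ± SEM per variable, cluster sizes, NS/IS composition.

    SEM of a singleton cluster is undefined and reported as NaN.
    """
    X = _as_array(Z)
    groups = np.asarray(groups, dtype=object)
    if len(assignment.labels) != X.shape[0]:
        raise ValueError("assignment does not match the number of rats")
    ids = np.unique(assignment.labels)
    names = (
        list(Z.columns) if isinstance(Z, ZScoredMatrix) else [f"var{j}" for j in range(X.shape[1])]
    )
    mean_z = np.vstack([X[assignment.labels == c].mean(axis=0) for c in ids])
    sem_z = np.vstack(
        [
            X[assignment.labels == c].std(axis=0, ddof=1) / np.sqrt((assignment.labels == c).sum())
            if (assignment.labels == c).sum() > 1
            else np.full(X.shape[1], np.nan)
            for c in ids
        ]
    )
    sizes = np.asarray([(assignment.labels == c).sum() for c in ids])
    comp = pd.DataFrame(
        {
            g: [int(((assignment.labels == c) & (groups == g)).sum()) for c in ids]
            for g in ("NS", "IS")
        },
        index=ids,
    )
    return ClusterProfile(
        mean_z=mean_z, sem_z=sem_z, sizes=sizes, composition=comp,
        cluster_ids=ids, variable_names=names,
    )


def cluster_correspondence(a: ClusterAssignment, b: ClusterAssignment) -> Correspondence:
    """How well two clusterings of the same rats agree.

    Builds the cluster × cluster contingency table, finds the one-to-one
    cluster matching that maximizes total overlap (optimal assignment), and
    reports per-matched-pair Jaccard indices plus the overall agreement
    (matched overlap / n). Label-permutation invariant.
    """
    la, lb = np.asarray(a.labels), np.asarray(b.labels)
    if la.size != lb.size:
        raise ValueError("assignments cover different item sets")
    ua, ub = np.unique(la), np.unique(lb)
    table = np.zeros((ua.size, ub.size), dtype=int)
    for i, ca in enumerate(ua):
        for j, cb in enumerate(ub):
            table[i, j] = int(((la == ca) & (lb == cb)).sum())
    ri, ci = linear_sum_assignment(-table)
    pairs = [(int(ua[i]), int(ub[j])) for i, j in zip(ri, ci)]
    jac = []
    for i, j in zip(ri, ci):
        inter = table[i, j]
        union = table[i, :].sum() + table[:, j].sum() - inter
        jac.append(float(inter / union) if union else 0.0)
    agreement = float(table[ri, ci].sum() / la.size)
    return Correspondence(contingency=table, matched_pairs=pairs, jaccard=jac, agreement=agreement)
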