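"""Principal-component patterns, their reliability, and PC-based classification.

PCA (via SVD of the centered matrix) summarizes the battery into orthogonal
covariation patterns. Three procedures assess whether those patterns are
real rather than sampling noise:

* a shuffled-data null for the explained variance of each component
  (column-wise permutation destroys covariance, so components exceeding the
  null's 95th percentile carry genuine structure);
* split-data reliability — PCs recomputed on 70% subsamples are matched to
  the full-data PCs by maximum |correlation| of coefficients and of scores;
* a cumulative-PC linear discriminant classifier (70/30 splits, repeated)
  compared against the same classifier run on shuffled data.

A VIF screen (1/(1−R²) of each variable regressed on its peers) supports
choosing representative variables with minimal multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import stats as rstats
from .core_data import ZScoredMatrix
from .synthetic import shuffle_dataset, subsample, subsample_size

__all__ = [
    "PCAResult",
    "ShuffledVarianceNull",
    "PCReliability",
    "LDAEvaluation",
    "pca",
    "shuffled_variance_null",
    "pc_reliability",
    "vif",
    "pc_group_comparison",
    "lda_cumulative_accuracy",
]


def _as_array(Z) -> np.ndarray:
    return Z.values if isinstance(Z, ZScoredMatrix) else np.asarray(Z, dtype=float)


@dataclass
class PCAResult:
    """Principal components of a rats × variables matrix.

    ``coefficients`` is variables × components with orthonormal columns,
    ``scores`` = centered data × coefficients, ``explained_pct`` sums to 100.
    Component signs follow the convention that each component's
    largest-|coefficient| entry is positive, making coefficient tables
    reproducible across runs and platforms.
    """

    coefficients: np.ndarray
    scores: np.ndarray
    explained_pct: np.ndarray
    columns: list[str]
    sign_convention: str = "largest-abs-coefficient-positive"

    @property
    def n_components(self) -> int:
        return self.coefficients.shape[1]

    def coefficients_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.n_components)]
        return pd.DataFrame(self.coefficients, index=self.columns, columns=cols)


@dataclass
class ShuffledVarianceNull:
    """Observed explained variance against a column-shuffled null."""

    observed_pct: np.ndarray
    null_pct: np.ndarray  # (n_iter, n_components)
    threshold_pct: np.ndarray  # per-component null percentile
    flags: np.ndarray  # observed > threshold
    percentile: float
    n_iter: int

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


@dataclass
class PCReliability:
    """Split-data PC reproducibility: median of per-iteration max |correlation|."""

    median_coeff: np.ndarray
    median_scores: np.ndarray
    n_iter: int
    fraction: float
    shuffled: bool


@dataclass
class LDAEvaluation:
    """Accuracy of LDA on cumulative PC sets, with a shuffled-data null."""

    k_values: list[int]
    mean_accuracy: np.ndarray
    null_mean_accuracy: np.ndarray
    p: np.ndarray
    n_iter: int


# -- PCA ----------------------------------------------------------------------


def pca(Z: "ZScoredMatrix | np.ndarray") -> PCAResult:
    """PCA by singular value decomposition of the column-centered matrix.

    Components are ordered by decreasing explained variance; with n rats and
    P variables at most min(n−1, P) components exist (trailing ones on
    rank-deficient input simply explain 0%).
    """
    X = _as_array(Z)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    n, P = X.shape
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    K = min(n - 1, P)
    coeff = Vt[:K].T
    svals = s[:K]
    var = svals**2
    total = var.sum()
    if total == 0:
        raise ValueError("all-constant matrix has no principal components")
    explained = var / total * 100.0
    scores = Xc @ coeff
    for j in range(K):
        if coeff[np.argmax(np.abs(coeff[:, j])), j] < 0:
            coeff[:, j] = -coeff[:, j]
            scores[:, j] = -scores[:, j]
    cols = list(Z.columns) if isinstance(Z, ZScoredMatrix) else [f"var{j}" for j in range(P)]
    return PCAResult(coefficients=coeff, scores=scores, explained_pct=explained, columns=cols)


def shuffled_variance_null(
    Z: "ZScoredMatrix | np.ndarray",
    n_iter: int = 1000,
    seed: int | None = None,
    percentile: float = 95.0,
) -> ShuffledVarianceNull:
    """Per-component explained-variance null from column-shuffled data.

    Flags the observed components whose explained % exceeds the null's
    ``percentile`` (default 95th), i.e. more structure than chance.
    """
    if n_iter < 100:
        raise ValueError("need n_iter >= 100 for a stable null percentile")
    X = _as_array(Z)
    observed = pca(X).explained_pct
    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, observed.size))
    for it in range(n_iter):
        null[it] = pca(shuffle_dataset(X, rng)).explained_pct
    thr = np.percentile(null, percentile, axis=0)
    return ShuffledVarianceNull(
        observed_pct=observed,
        null_pct=null,
        threshold_pct=thr,
        flags=observed > thr,
        percentile=percentile,
        n_iter=n_iter,
    )


def _match_abs_corr(ref: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """For each column of ``ref``, max |Pearson r| against any column of ``cand``."""
    A = ref - ref.mean(axis=0)
    B = cand - cand.mean(axis=0)
    sa = np.linalg.norm(A, axis=0)
    sb = np.linalg.norm(B, axis=0)
    sa = np.where(sa == 0, np.inf, sa)
    sb = np.where(sb == 0, np.inf, sb)
    C = np.abs((A.T @ B) / np.outer(sa, sb))
    return C.max(axis=1)


def pc_reliability(
    Z: "ZScoredMatrix | np.ndarray",
    fraction: float = 0.7,
    n_iter: int = 100,
    seed: int | None = None,
    shuffled: bool = False,
) -> PCReliability:
    """Reproducibility of each PC under observation subsampling.

    Per iteration, PCA is recomputed on a ``fraction`` subsample of rats and
    each full-data PC is matched to the subsample PC with the highest
    absolute Pearson correlation — coefficients compared over all variables,
    scores over the shared rats (absolute value, because a subsample can flip
    a component's sign). Reported values are medians over iterations.
    ``shuffled=True`` applies the identical procedure to a column-shuffled
    copy of the data, giving the chance level of PC reproducibility.
    """
    X = _as_array(Z)
    rng = np.random.default_rng(seed)
    if shuffled:
        X = shuffle_dataset(X, rng)
    full = pca(X)
    K = full.n_components
    coeff_max = np.empty((n_iter, K))
    score_max = np.empty((n_iter, K))
    for it in range(n_iter):
        sub, idx = subsample(X, fraction, axis="observations", seed=rng)
        part = pca(sub)
        coeff_max[it] = _match_abs_corr(full.coefficients, part.coefficients)
        score_max[it] = _match_abs_corr(full.scores[idx], part.scores)
    return PCReliability(
        median_coeff=np.median(coeff_max, axis=0),
        median_scores=np.median(score_max, axis=0),
        n_iter=n_iter,
        fraction=fraction,
        shuffled=shuffled,
    )


# -- multicollinearity ---------------------------------------------------------


def vif(Z_subset: "ZScoredMatrix | np.ndarray", threshold: float = 1.1) -> pd.DataFrame:
    """Variance inflation factors: VIF_j = 1/(1−R²_j).

    R²_j comes from an ordinary least-squares regression of variable j on all
    the other variables (with intercept). VIF above ``threshold`` (study
    convention: 1.1) flags multicollinearity; perfect collinearity reports
    ``inf``.
    """
    X = _as_array(Z_subset)
    n, P = X.shape
    if n <= P:
        raise ValueError(f"VIF needs more rows than columns (got {n} x {P})")
    names = (
        list(Z_subset.columns)
        if isinstance(Z_subset, ZScoredMatrix)
        else [f"var{j}" for j in range(P)]
    )
    out = []
    for j in range(P):
        y = X[:, j]
        A = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError(f"constant column {names[j]!r}: VIF undefined")
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"variable": names[j], "vif": v, "flagged": bool(v > threshold)})
    return pd.DataFrame(out)


# -- per-PC group tests --------------------------------------------------------


def pc_group_comparison(
    scores: np.ndarray, groups: Sequence, route: str = "auto"
) -> pd.DataFrame:
    """Group comparison of every PC's scores (auto t / rank-sum route)."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups, dtype=object)
    levels = sorted(set(groups), key=str)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a = groups == levels[0]
    rows = []
    for j in range(scores.shape[1]):
        res = rstats.compare_groups(scores[a, j], scores[~a, j], route=route)
        rows.append(
            {"pc": j + 1, "method": res.method, "statistic": res.statistic,
             "df": res.df, "p": res.p}
        )
    return pd.DataFrame(rows)


# -- LDA on cumulative PCs -----------------------------------------------------


def _split_accuracy(
    S: np.ndarray, y: np.ndarray, n_train: int, rng: np.random.Generator
) -> float:
    """One unstratified 70/30 split; redraw if a class is absent from training."""
    n = S.shape[0]
    for _ in range(1000):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if len(set(y[train])) == 2 and test.size:
            break
    else:
        raise RuntimeError("could not draw a split containing both classes")
    clf = LinearDiscriminantAnalysis(solver="svd")
    clf.fit(S[train], y[train])
    return float(np.mean(clf.predict(S[test]) == y[test]))


def lda_cumulative_accuracy(
    scores: np.ndarray,
    labels: Sequence,
    n_iter: int = 1000,
    train_frac: float = 0.7,
    seed: int | None = None,
    k_values: Sequence[int] | None = None,
) -> LDAEvaluation:
    """Classification accuracy of LDA on cumulative PC sets, against a null.

    For each k, a linear discriminant (pooled covariance, no shrinkage;
    singular covariances handled by the SVD solver) is trained on the scores
    of PC1..k using random 70/30 train/test splits, ``n_iter`` times; the
    reported accuracy is the mean over iterations. The null repeats the
    procedure on column-shuffled scores, and the permutation p for each k is
    (1 + #{null accuracies ≥ observed mean}) / (n_iter + 1).
    """
    S = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=object)
    if S.shape[0] != y.size:
        raise ValueError("scores and labels must cover the same rats")
    classes, counts = np.unique(y.astype(str), return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need exactly 2 classes with >= 2 members each")
    K = S.shape[1]
    ks = list(k_values) if k_values is not None else list(range(2, K + 1))
    if any(k < 1 or k > K for k in ks):
        raise ValueError(f"k values must be within [1, {K}]")
    n_train = subsample_size(S.shape[0], train_frac)
    if n_train < 2 or n_train >= S.shape[0]:
        raise ValueError("train fraction leaves too few rats for train or test")
    rng = np.random.default_rng(seed)
    S_null = shuffle_dataset(S, rng)
    mean_acc = np.empty(len(ks))
    null_mean = np.empty(len(ks))
    pvals = np.empty(len(ks))
    for i, k in enumerate(ks):
        obs = np.array([_split_accuracy(S[:, :k], y, n_train, rng) for _ in range(n_iter)])
        nul = np.array([_split_accuracy(S_null[:, :k], y, n_train, rng) for _ in range(n_iter)])
        mean_acc[i] = obs.mean()
        null_mean[i] = nul.mean()
        pvals[i] = (1.0 + np.sum(nul >= obs.mean())) / (n_iter + 1.0)
    return LDAEvaluation(
        k_values=ks,
        mean_accuracy=mean_acc,
        null_mean_accuracy=null_mean,
        p=pvals,
        n_iter=n_iter,
    )
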