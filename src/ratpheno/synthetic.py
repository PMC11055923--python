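"""Synthetic behavioral-battery generator and permutation utilities.

The generator emulates the statistical structure of a rodent stress battery:
two groups (no-shock NS, inescapable-shock IS), ~26 variables over 8 tests,
strong intra-test but weak inter-test correlation, a latent
resilience–susceptibility axis that loads on every variable with a
valence-dependent sign, a helpless (H) subpopulation concentrated in the
shocked group, and multivariate profile clusters implemented as mean offsets
on variable blocks.

The model for rat ``i``, variable ``v`` belonging to test ``t``:

    x_iv = lambda_test * f_it  +  sign_v * lambda_sus * s_i
           + lambda_val * g_{i, valence(v)}
           + H_i * delta_H_sb * [v in SB susceptibility block]
           + offset[c_i, v]  +  noise_sd * eps_iv

with per-test factors ``f_it ~ N(0,1)``, susceptibility score
``s_i ~ N(0,1) + delta_H * H_i``, latent helplessness flag ``H_i`` drawn per
group, per-valence factors ``g_{i,res}, g_{i,sus} ~ N(0,1)``, profile-cluster
id ``c_i``, and ``sign_v`` = +1 for susceptibility-valenced variables and −1
for resilience-valenced ones.

The valence factors matter: a purely bipolar axis (the ``lambda_sus`` term)
is antisymmetric in valence, and the sign-independent clustering distance
``min(‖x−y‖, ‖x+y‖)`` is blind to antisymmetric structure — a resilience
variable's negation is indistinguishable from a susceptibility variable.
Real batteries separate valence classes because susceptibility measures also
share covariance among themselves that is not the mirror image of the
resilience measures'; ``lambda_val`` plants exactly that.

Shuffling (independent per-column permutation) and 70% subsampling are the
null/permutation primitives used by every reliability procedure downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_data import BehavioralDataset, VariableMeta, ZScoredMatrix

__all__ = [
    "DEFAULT_TESTS",
    "REPRESENTATIVE_SIX",
    "SyntheticConfig",
    "GroundTruth",
    "generate_battery",
    "shuffle_dataset",
    "subsample",
]

# (test, [(variable, valence), ...]) — 26 variables over the 8 battery tests.
DEFAULT_TESTS: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = (
    ("OF", (("OF_total_distance", "resilience"),
            ("OF_center_time", "resilience"),
            ("OF_rearing", "resilience"),
            ("OF_corner_time", "susceptibility"))),
    ("FST", (("FST_immobility", "susceptibility"),
             ("FST_swimming", "resilience"),
             ("FST_climbing", "resilience"))),
    ("SIT", (("SIT_social_pref_ratio", "resilience"),
             ("SIT_corner_ratio", "susceptibility"))),
    ("EPM", (("EPM_open_arms_time", "resilience"),
             ("EPM_closed_arms_time", "susceptibility"),
             ("EPM_open_entries", "resilience"),
             ("EPM_head_dips", "resilience"))),
    ("NOR", (("NOR_st_discrimination", "resilience"),
             ("NOR_lt_discrimination", "resilience"),
             ("NOR_total_exploration", "resilience"))),
    ("PPI", (("PPI_startle_amplitude", "susceptibility"),
             ("PPI_habituation_pct", "resilience"),
             ("PPI_ppi71", "resilience"),
             ("PPI_ppi77", "resilience"),
             ("PPI_ppi83", "resilience"))),
    ("SPT", (("SPT_avg_sucrose_pref", "resilience"),
             ("SPT_d1_sucrose_pref", "resilience"))),
    ("SB", (("SB_escape_failures", "susceptibility"),
            ("SB_mean_escape_latency", "susceptibility"),
            ("SB_fr1_escape_latency", "susceptibility"))),
)

#: One representative variable per test commonly used for the reduced,
#: multicollinearity-screened analysis (six of the eight tests).
REPRESENTATIVE_SIX = (
    "OF_total_distance",
    "FST_immobility",
    "SIT_social_pref_ratio",
    "EPM_open_arms_time",
    "SPT_avg_sucrose_pref",
    "SB_escape_failures",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults mirror the study scale (22 NS / 23 IS).

    Parameters
    ----------
    lambda_test
        Loading of the shared per-test factor (drives intra-test correlation).
    lambda_sus
        Loading of the latent susceptibility axis (drives weak, sign-coherent
        inter-test correlation).
    lambda_val
        Loading of the two valence-specific factors (one shared by all
        resilience variables, one by all susceptibility variables). This is
        the non-antisymmetric part of the valence structure, the part a
        sign-independent distance can actually see.
    delta_H
        Shift of the susceptibility score for latent-H (helpless) rats, in SD
        units of the axis.
    delta_H_sb
        Additional mean offset of latent-H rats on the shuttle-box
        susceptibility variables: helpless animals fail most escape trials,
        so their shuttle-box scores sit far above the rest of the population.
    pi_H_IS, pi_H_NS
        Helpless mixture proportions per group (defaults 20/23 and 8/22).
    n_profile_clusters
        Number of multivariate profile clusters; the last cluster is a
        "generalized susceptibility" profile (positive offset on every
        susceptibility variable, negative on every resilience variable),
        intermediate clusters each elevate one test block.
    cluster_offset
        Magnitude of the profile-cluster mean offsets.
    noise_sd
        Residual (variable-specific) noise SD.
    """

    n_NS: int = 22
    n_IS: int = 23
    tests: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = DEFAULT_TESTS
    lambda_test: float = 0.8
    lambda_sus: float = 0.5
    lambda_val: float = 0.6
    delta_H: float = 1.0
    delta_H_sb: float = 3.0
    pi_H_IS: float = 20 / 23
    pi_H_NS: float = 8 / 22
    n_profile_clusters: int = 3
    cluster_offset: float = 0.8
    noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_NS < 1 or self.n_IS < 1:
            raise ValueError("group sizes must be positive")
        for name, p in (("pi_H_IS", self.pi_H_IS), ("pi_H_NS", self.pi_H_NS)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive (variables need positive variance)")
        if self.lambda_test**2 + self.lambda_sus**2 + self.noise_sd**2 <= 0:
            raise ValueError("implied variable variance must be positive")
        if self.n_profile_clusters < 1:
            raise ValueError("need at least one profile cluster")

    @property
    def meta(self) -> list[VariableMeta]:
        return [
            VariableMeta(name=v, test=t, valence=val)
            for t, variables in self.tests
            for v, val in variables
        ]

    @property
    def n_variables(self) -> int:
        return sum(len(vs) for _, vs in self.tests)


@dataclass(frozen=True)
class GroundTruth:
    """Latent quantities behind a generated battery."""

    susceptibility: np.ndarray  # per-rat latent score s_i
    helpless: np.ndarray        # per-rat bool, latent H flag
    profile_cluster: np.ndarray  # per-rat int cluster id


def _cluster_offsets(config: SyntheticConfig) -> np.ndarray:
    """(n_clusters, n_variables) mean-offset matrix for the profile clusters.

    Cluster 0 is baseline (no offset); the last cluster is the generalized
    susceptibility profile; clusters in between elevate one test block each.
    """
    meta = config.meta
    K, P = config.n_profile_clusters, len(meta)
    offsets = np.zeros((K, P))
    if K == 1:
        return offsets
    sign = np.where(np.asarray([m.valence for m in meta]) == "susceptibility", 1.0, -1.0)
    offsets[K - 1] = config.cluster_offset * sign
    test_names = [t for t, _ in config.tests]
    tests_of = np.asarray([m.test for m in meta])
    for c in range(1, K - 1):
        block = tests_of == test_names[(c - 1) % len(test_names)]
        offsets[c, block] = config.cluster_offset
    return offsets


def generate_battery(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[BehavioralDataset, GroundTruth]:
    """Draw one synthetic battery dataset plus its latent ground truth.

    Fully reproducible from ``seed`` (falls back to ``config.seed``). Profile
    clusters are tied to helplessness the way the study's profiles were:
    latent-H rats fall in the generalized-susceptibility cluster with
    probability 0.8, everyone else is uniform over the remaining clusters.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_NS + config.n_IS
    meta = config.meta
    P = len(meta)
    group = np.asarray(["NS"] * config.n_NS + ["IS"] * config.n_IS, dtype=object)

    pi = np.where(group == "IS", config.pi_H_IS, config.pi_H_NS)
    helpless = rng.random(n) < pi
    s = rng.standard_normal(n) + config.delta_H * helpless

    K = config.n_profile_clusters
    cluster = np.zeros(n, dtype=int)
    if K > 1:
        others = np.arange(K - 1)
        for i in range(n):
            if helpless[i] and rng.random() < 0.8:
                cluster[i] = K - 1
            else:
                cluster[i] = rng.choice(others)
    offsets = _cluster_offsets(config)

    test_names = [t for t, _ in config.tests]
    test_index = {t: k for k, t in enumerate(test_names)}
    f = rng.standard_normal((n, len(test_names)))
    g = rng.standard_normal((n, 2))  # per-valence factors: [resilience, susceptibility]
    sign = np.where(np.asarray([m.valence for m in meta]) == "susceptibility", 1.0, -1.0)
    t_of_var = np.asarray([test_index[m.test] for m in meta])
    val_of_var = (sign > 0).astype(int)
    sb_sus = np.asarray([m.test == "SB" and m.valence == "susceptibility" for m in meta])

    X = (
        config.lambda_test * f[:, t_of_var]
        + config.lambda_sus * np.outer(s, sign)
        + config.lambda_val * g[:, val_of_var]
        + config.delta_H_sb * np.outer(helpless.astype(float), sb_sus.astype(float))
        + offsets[cluster]
        + config.noise_sd * rng.standard_normal((n, P))
    )
    dataset = BehavioralDataset(
        values=X,
        rat_ids=[f"rat{i:03d}" for i in range(n)],
        group=group,
        meta=meta,
    )
    truth = GroundTruth(susceptibility=s, helpless=helpless, profile_cluster=cluster)
    return dataset, truth


def shuffle_dataset(
    Z: "ZScoredMatrix | np.ndarray",
    seed: int | None | np.random.Generator = None,
    unit: str = "columns",
) -> "ZScoredMatrix | np.ndarray":
    """Shuffled-data null: destroy covariance, keep per-variable marginals.

    ``unit="columns"`` permutes each column independently across rows (the
    default null used throughout); ``unit="rows"`` permutes whole rows, i.e.
    shuffles observation labels while keeping each rat's profile intact.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = Z.values if isinstance(Z, ZScoredMatrix) else np.asarray(Z, dtype=float)
    if unit == "columns":
        out = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
    elif unit == "rows":
        out = X[rng.permutation(X.shape[0])]
    else:
        raise ValueError(f"unknown shuffle unit {unit!r}")
    if isinstance(Z, ZScoredMatrix):
        return ZScoredMatrix(values=out, columns=list(Z.columns), mean=Z.mean, sd=Z.sd)
    return out


def subsample_size(n: int, fraction: float) -> int:
    """Number of items kept: fraction·n rounded to nearest, ties up.

    A tiny epsilon guards against binary-float artifacts (0.7·45 evaluates to
    31.499999999999996 but means 31.5, which rounds up to 32).
    """
    return int(np.floor(fraction * n + 0.5 + 1e-9))


def subsample(
    data: "ZScoredMatrix | np.ndarray",
    fraction: float = 0.7,
    axis: str = "observations",
    seed: int | None | np.random.Generator = None,
) -> tuple["ZScoredMatrix | np.ndarray", np.ndarray]:
    """Uniform subsample without replacement along observations or variables.

    Returns the subset and the (sorted) selected indices so downstream code
    can match rows/columns back to the full data.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0,1], got {fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = data.values if isinstance(data, ZScoredMatrix) else np.asarray(data, dtype=float)
    if axis == "observations":
        n = X.shape[0]
    elif axis == "variables":
        n = X.shape[1]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    m = subsample_size(n, fraction)
    if m < 2:
        raise ValueError(f"subsample of {m} item(s) is too small")
    idx = np.sort(rng.choice(n, size=m, replace=False))
    sub = X[idx] if axis == "observations" else X[:, idx]
    if isinstance(data, ZScoredMatrix):
        cols = list(data.columns) if axis == "observations" else [data.columns[j] for j in idx]
        mean = data.mean if axis == "observations" else data.mean[idx]
        sd = data.sd if axis == "observations" else data.sd[idx]
        return ZScoredMatrix(values=sub, columns=cols, mean=mean, sd=sd), idx
    return sub, idx
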