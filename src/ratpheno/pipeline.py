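"""End-to-end orchestration of the behavioral-profiling analysis.

``run_pipeline`` executes the full sequence — univariate battery statistics,
helplessness classification, feature structure, PCA/VIF/LDA, individual
profile clustering — from a :class:`RunConfig`, writing tabular artifacts
and a JSON manifest to a run directory. Every stochastic stage draws its own
seed from the master seed through a fixed counter scheme, so a report is
bit-reproducible from its config and stage seeds are independent (changing
one stage's work does not perturb another's random stream).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core_data import BehavioralDataset, read_dataset, write_dataset, zscore
from .feature_structure import (
    clustering_reliability,
    cophenetic_coefficient,
    cut_tree,
    label_separation_test,
    sign_independent_pdist,
    spearman_matrix,
    ward_linkage,
)
from .individual_profiles import (
    classify_helplessness,
    cluster_correspondence,
    cluster_profiles,
    hier_profiles,
    hierarchy_scan,
    kmeans_best_of_restarts,
    select_k,
)
from .pca_patterns import (
    lda_cumulative_accuracy,
    pc_group_comparison,
    pc_reliability,
    pca,
    shuffled_variance_null,
    vif,
)
from .stats import battery_table, chi2_association
from .synthetic import REPRESENTATIVE_SIX, SyntheticConfig, generate_battery

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

_STAGES = (
    "simulate",
    "helplessness",
    "feature_reliability",
    "pca_null",
    "pc_reliability",
    "lda",
    "kmeans",
)


def stage_seed(master: int, stage: str) -> int:
    """Per-stage seed from the master seed (counter scheme, stable ordering)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([int(master), idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``values_path``/``meta_path`` point to an existing dataset, or
    ``simulate`` provides a generator config. Iteration counts default to the
    full-scale procedure (10⁴ feature-reliability iterations, 1000 LDA
    iterations, 10⁴ k-means restarts); ``RunConfig.fast()`` scales them down
    for quick runs.
    """

    out_dir: str | Path = "ratpheno_run"
    values_path: str | Path | None = None
    meta_path: str | Path | None = None
    simulate: SyntheticConfig | None = None
    seed: int = 0
    alpha: float = 0.05
    n_iter_reliability: int = 10_000
    n_iter_lda: int = 1000
    n_restarts_kmeans: int = 10_000
    n_iter_pca_null: int = 1000
    n_iter_pc_reliability: int = 100
    representative: Sequence[str] = REPRESENTATIVE_SIX
    k_range: Sequence[int] = tuple(range(2, 8))
    select_delta: float = 0.02

    def __post_init__(self) -> None:
        if self.simulate is None and (self.values_path is None or self.meta_path is None):
            raise ValueError(
                "config must provide either a simulate config or both values_path and meta_path"
            )
        for name in ("n_iter_reliability", "n_iter_lda", "n_restarts_kmeans",
                     "n_iter_pc_reliability"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_iter_pca_null < 100:
            raise ValueError("n_iter_pca_null must be >= 100")

    @classmethod
    def fast(cls, **kwargs: Any) -> "RunConfig":
        """Reduced-iteration configuration for quick or exploratory runs."""
        kwargs.setdefault("n_iter_reliability", 200)
        kwargs.setdefault("n_iter_lda", 50)
        kwargs.setdefault("n_restarts_kmeans", 50)
        kwargs.setdefault("n_iter_pca_null", 100)
        kwargs.setdefault("n_iter_pc_reliability", 25)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "tests" in sim:
                sim["tests"] = tuple(
                    (t, tuple((v, val) for v, val in vs)) for t, vs in sim["tests"]
                )
            raw["simulate"] = SyntheticConfig(**sim)
        return cls(**raw)


@dataclass
class RunReport:
    """Machine-readable record of a pipeline run."""

    config: dict
    stages: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps(_jsonify(dataclasses.asdict(self)), indent=2, sort_keys=True)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs before it are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis and write artifacts + manifest under ``out_dir``."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in _STAGES}
    cfg_dict = dataclasses.asdict(config)
    report = RunReport(config=_jsonify(cfg_dict), seeds=seeds)
    report.versions = {"ratpheno": __version__, "numpy": np.__version__, "pandas": pd.__version__}

    stage = "load"
    try:
        if config.simulate is not None:
            stage = "simulate"
            dataset, truth = generate_battery(config.simulate, seed=seeds["simulate"])
            write_dataset(dataset, out / "values.csv", out / "meta.csv")
            pd.DataFrame(
                {
                    "rat_id": dataset.rat_ids,
                    "susceptibility": truth.susceptibility,
                    "helpless": truth.helpless,
                    "profile_cluster": truth.profile_cluster,
                }
            ).to_csv(out / "ground_truth.csv", index=False)
            report.stages["simulate"] = {
                "n_rats": dataset.n_rats,
                "n_variables": dataset.n_variables,
                "n_latent_H": int(truth.helpless.sum()),
            }
        else:
            dataset = read_dataset(config.values_path, config.meta_path)

        stage = "univariate"
        table = battery_table(dataset)
        table.to_csv(out / "battery_stats.tsv", sep="\t", index=False)
        report.stages["univariate"] = {
            "n_significant": int((table["p"] < config.alpha).sum()),
            "n_variables": len(table),
        }

        stage = "helplessness"
        hn, hn_assign = classify_helplessness(
            dataset,
            n_restarts=config.n_restarts_kmeans,
            seed=seeds["helplessness"],
        )
        dataset.hn_label = hn
        hn_table = pd.crosstab(pd.Series(hn), pd.Series(dataset.group)).to_numpy()
        hn_chi2 = chi2_association(hn_table)
        report.stages["helplessness"] = {
            "n_H": int((hn == "H").sum()),
            "n_NH": int((hn == "NH").sum()),
            "k": hn_assign.k,
            "chi2": hn_chi2.chi2,
            "p": hn_chi2.p,
        }

        stage = "feature_structure"
        Z = zscore(dataset)
        corr = spearman_matrix(Z)
        corr.to_frame().to_csv(out / "spearman.tsv", sep="\t")
        tree = ward_linkage(Z.values.T, metric="sign_independent")
        tree_labels = list(Z.columns)
        d = sign_independent_pdist(Z.values.T)
        coph = cophenetic_coefficient(tree, d)
        cut2 = cut_tree(tree, 2)
        valence_chi2 = label_separation_test(cut2, dataset.valences)
        pd.DataFrame(
            tree.merges, columns=["node_a", "node_b", "height", "size"]
        ).to_csv(out / "variable_linkage.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"variable": tree_labels, "cluster": cut2.labels}
        ).to_csv(out / "variable_clusters.tsv", sep="\t", index=False)
        rel = clustering_reliability(
            Z, dataset.valences,
            n_iter=config.n_iter_reliability, alpha=config.alpha,
            seed=seeds["feature_reliability"],
        )
        rel_null = clustering_reliability(
            Z, dataset.valences,
            n_iter=config.n_iter_reliability, alpha=config.alpha,
            seed=seeds["feature_reliability"], shuffled=True,
        )
        report.stages["feature_structure"] = {
            "cophenetic": coph,
            "valence_chi2": valence_chi2.chi2,
            "valence_p": valence_chi2.p,
            "reliability_fraction_significant": rel.fraction_significant,
            "shuffled_fraction_significant": rel_null.fraction_significant,
        }

        stage = "pca"
        full = pca(Z)
        full.coefficients_frame().to_csv(out / "pca_coefficients.tsv", sep="\t")
        null = shuffled_variance_null(
            Z, n_iter=config.n_iter_pca_null, seed=seeds["pca_null"]
        )
        pcrel = pc_reliability(
            Z, n_iter=config.n_iter_pc_reliability, seed=seeds["pc_reliability"]
        )
        pcrel_null = pc_reliability(
            Z, n_iter=config.n_iter_pc_reliability, seed=seeds["pc_reliability"],
            shuffled=True,
        )
        group_tests = pc_group_comparison(full.scores, dataset.group)
        rep = [v for v in config.representative if v in dataset.variable_names]
        vif_table = vif(zscore(dataset.subset(rep))) if len(rep) >= 2 else None
        rep_pca = pca(zscore(dataset.subset(rep))) if len(rep) >= 2 else None
        if vif_table is not None:
            vif_table.to_csv(out / "vif.tsv", sep="\t", index=False)
        report.stages["pca"] = {
            "explained_pct": full.explained_pct,
            "n_above_null": null.n_flagged,
            "flags": null.flags,
            "pc1_reliability_coeff": float(pcrel.median_coeff[0]),
            "pc1_reliability_coeff_shuffled": float(pcrel_null.median_coeff[0]),
            "group_tests": group_tests,
            "representative_vif": None if vif_table is None else vif_table,
            "representative_explained_pct": None if rep_pca is None else rep_pca.explained_pct,
        }

        stage = "lda"
        lda = lda_cumulative_accuracy(
            full.scores, hn, n_iter=config.n_iter_lda, seed=seeds["lda"]
        )
        pd.DataFrame(
            {
                "k": lda.k_values,
                "accuracy": lda.mean_accuracy,
                "null_accuracy": lda.null_mean_accuracy,
                "p": lda.p,
            }
        ).to_csv(out / "lda_accuracy.tsv", sep="\t", index=False)
        report.stages["lda"] = {
            "k_values": lda.k_values,
            "accuracy": lda.mean_accuracy,
            "null_accuracy": lda.null_mean_accuracy,
            "p": lda.p,
        }

        stage = "profiles"
        rat_tree = ward_linkage(Z.values, metric="euclidean")
        scan = hierarchy_scan(rat_tree, dataset.group, k_range=config.k_range)
        scan.to_csv(out / "hierarchy_scan.tsv", sep="\t", index=False)
        sel = select_k(
            Z, config.k_range, mode="semi_supervised", groups=dataset.group,
            delta=config.select_delta, alpha=config.alpha,
            n_restarts=config.n_restarts_kmeans, seed=seeds["kmeans"],
        )
        k_used = sel.k if sel.k is not None else int(max(config.k_range))
        km = kmeans_best_of_restarts(
            Z, k_used, n_restarts=config.n_restarts_kmeans, seed=seeds["kmeans"]
        )
        hc = hier_profiles(Z, k_used + 1)  # one extra hierarchical stratum, as in a finer cut
        prof = cluster_profiles(Z, km, dataset.group)
        corr_ab = cluster_correspondence(km, hc)
        pd.DataFrame(
            {"rat_id": dataset.rat_ids, "kmeans": km.labels, "hier": hc.labels,
             "hn_label": hn, "group": dataset.group}
        ).to_csv(out / "profile_assignments.tsv", sep="\t", index=False)
        pd.DataFrame(
            prof.mean_z, index=prof.cluster_ids, columns=prof.variable_names
        ).to_csv(out / "cluster_profiles.tsv", sep="\t")
        report.stages["profiles"] = {
            "selected_k": sel.k,
            "k_used": k_used,
            "selection_table": sel.table,
            "kmeans_mean_silhouette": km.mean_silhouette,
            "correspondence_agreement": corr_ab.agreement,
            "cluster_sizes": prof.sizes,
        }
    except Exception as e:  # noqa: BLE001 — stage-tagged re-raise
        raise StageError(stage, e) from e

    report.wall_clock_s = time.monotonic() - t0
    (out / "manifest.json").write_text(report.to_json())
    return report
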