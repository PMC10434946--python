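"""End-to-end audits: generators → embedding chains → distortion metrics.

``run_audit`` drives a full audit from a single config (YAML-loadable):
produce or load a dataset, embed it along the requested chains, compute the
requested metrics for every (space, replicate) against the ambient
reference, and collect everything into a :class:`DistortionReport` whose
tables carry the geometric property each metric probes (local, global or
distance). Deterministic stages reproduce bit-for-bit from the same config
and seeds; stochastic embeddings record their per-replicate seeds.

Two targeted experiments are provided alongside the generic audit:

* ``mixing_experiment`` — synthetic two-batch data at a configurable batch
  shift; compares the distribution of per-cell same-batch neighbor
  fractions in ambient space with the same distribution measured in each
  2D chain (K-S statistic between the two distributions).
* ``swissroll_experiment`` — embeds Swiss-rolls of increasing tightness at
  several neighbor settings and scores neighbor scrambling (Jaccard
  dissimilarity) against the known intrinsic 2D coordinates.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AnnotationTable,
    DistortionReport,
    EmbeddingMatrix,
    ExpressionMatrix,
    ValidationError,
)
from . import harness, metrics, synthetic
from .harness import EmbedConfig, pipeline_embed, run_nonlinear_2d

logger = logging.getLogger("embaudit")

__all__ = ["AuditConfig", "run_audit", "mixing_experiment",
           "swissroll_experiment", "METRIC_PROPERTY"]

# Which necessary geometric property each metric probes.
METRIC_PROPERTY = {
    "jaccard": "local",
    "mixing": "local",
    "ranking": "global",
    "accuracy": "global",
    "ks": "global",
    "ratio": "distance",
}


@dataclass
class AuditConfig:
    """Validated configuration of a full audit run."""

    synthetic: Optional[dict] = None  # kwargs of default_mixture_spec
    counts_prefix: Optional[str] = None  # MTX prefix alternative
    labels_path: Optional[str] = None
    chains: Sequence[str] = ("ambient", "pca-50", "pca-50-umap")
    metrics: Sequence[str] = ("jaccard", "ranking")
    label_column: str = "type"
    mixing_column: str = "condition"
    k_jaccard: int = 30
    k_mixing: int = 30
    k_predict: int = 50
    test_fraction: float = 0.3
    metric_norm: str = "L2"
    n_replicates: int = 3
    n_hvg: Optional[int] = None
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValidationError("at least one chain is required")
        if not self.metrics:
            raise ValidationError("at least one metric is required")
        unknown = set(self.metrics) - set(METRIC_PROPERTY)
        if unknown:
            raise ValidationError(f"unknown metric(s): {sorted(unknown)}")
        if self.synthetic is None and self.counts_prefix is None:
            raise ValidationError("config needs a synthetic spec or input paths")

    @classmethod
    def from_yaml(cls, path) -> "AuditConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _load_inputs(config: AuditConfig) -> tuple[ExpressionMatrix, AnnotationTable]:
    if config.synthetic is not None:
        kwargs = dict(config.synthetic)
        kwargs.setdefault("seed", config.seed)
        spec = synthetic.default_mixture_spec(**kwargs)
        return synthetic.generate_mixture_counts(spec)
    from . import io as eio

    counts = eio.read_mtx(config.counts_prefix)
    if config.labels_path is None:
        raise ValidationError("labels_path required with counts_prefix")
    ann = eio.read_annotations(config.labels_path)
    missing = set(counts.cell_ids) - set(ann.cell_ids)
    if missing:
        raise ValidationError(f"{len(missing)} cells missing from annotations")
    return counts, ann.aligned_to(counts.cell_ids)


def _stage(report: DistortionReport, name: str, fn):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:
        raise RuntimeError(f"audit stage {name!r} failed: {exc}") from exc
    logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
    return result


def run_audit(config: AuditConfig) -> DistortionReport:
    """Run every requested metric for every embedded space vs ambient."""
    report = DistortionReport(config={
        f.name: getattr(config, f.name) for f in dataclasses.fields(config)})
    counts, ann = _stage(report, "inputs", lambda: _load_inputs(config))
    chains = list(config.chains)
    if "ambient" not in chains:
        chains = ["ambient"] + chains
    embed_cfg = EmbedConfig(chains=chains, n_hvg=config.n_hvg,
                            metric=config.metric_norm,
                            n_replicates=config.n_replicates, seed=config.seed)
    spaces = _stage(report, "embed", lambda: pipeline_embed(counts, embed_cfg))
    ambient = spaces["ambient"][0]
    ann = ann.aligned_to(ambient.cell_ids)  # lognormalize may drop empty cells
    norm = config.metric_norm

    ref_index = None
    if "jaccard" in config.metrics:
        ref_index = _stage(report, "ambient-knn",
                           lambda: metrics.knn_index(ambient, config.k_jaccard,
                                                     norm, source_space="ambient"))
    ref_tdm = None
    if "ranking" in config.metrics:
        ref_tdm = _stage(report, "ambient-typedist",
                         lambda: metrics.type_distance_matrix(
                             ambient, ann.labels(config.label_column), norm))

    rows: dict[str, list] = {m: [] for m in config.metrics}
    for name in chains:
        if name == "ambient":
            continue
        for emb in spaces[name]:
            rep = emb.provenance.get("replicate", 0)
            tag = dict(space=name, replicate=rep,
                       seed=emb.provenance.get("seed", config.seed))
            if "jaccard" in config.metrics:
                idx = metrics.knn_index(emb, config.k_jaccard, norm,
                                        source_space=name)
                j = metrics.jaccard_neighbor_distance(ref_index, idx)
                rows["jaccard"].append({**tag, "mean": j.mean(),
                                        "median": float(np.median(j))})
            if "mixing" in config.metrics:
                labels = ann.labels(config.mixing_column)
                idx = metrics.knn_index(emb, config.k_mixing, norm,
                                        source_space=name)
                fr_emb = metrics.mixing_fractions(idx, labels)
                fr_amb = metrics.mixing_fractions(
                    metrics.knn_index(ambient, config.k_mixing, norm), labels)
                ks = metrics._ks_statistic(fr_amb, fr_emb)
                rows["mixing"].append({**tag, "mean": fr_emb.mean(),
                                       "ambient_mean": fr_amb.mean(),
                                       "ks_vs_ambient": ks})
            if "ranking" in config.metrics:
                tdm = metrics.type_distance_matrix(
                    emb, ann.labels(config.label_column), norm)
                rho = metrics.type_ranking_correlation(ref_tdm, tdm)
                rows["ranking"].append({**tag, "median": float(np.median(rho)),
                                        "mean": rho.mean()})
            if "accuracy" in config.metrics:
                acc = metrics.knn_label_predict(
                    emb, ann.labels(config.label_column),
                    config.test_fraction, config.k_predict, norm,
                    seed=config.seed)
                rows["accuracy"].append({**tag, "accuracy": acc})
            if "ks" in config.metrics:
                stat, _, _ = metrics.inter_intra_ks(
                    emb, ann.labels(config.label_column), norm,
                    seed=config.seed)
                rows["ks"].append({**tag, "ks": stat})
            if "ratio" in config.metrics:
                dists = metrics.pairwise_dists(ambient, metric=norm)
                near, far = metrics.near_far_targets(dists, seed=config.seed)
                groups = metrics.find_equidistant_groups(
                    dists, near, 0.01, limit=200, regime="near")
                if len(groups):
                    folds, _ = metrics.ratio_distortion(groups, ambient, emb, norm)
                    rows["ratio"].append({**tag, "median_fold": float(np.median(folds)),
                                          "n_groups": len(groups)})
                else:
                    rows["ratio"].append({**tag, "median_fold": np.nan,
                                          "n_groups": 0})
    for m in config.metrics:
        df = pd.DataFrame(rows[m])
        df.insert(0, "property", METRIC_PROPERTY[m])
        report.add(m, df)
    if config.outdir:
        report.write(config.outdir)
    return report


def mixing_experiment(
    shift_sd: float,
    n_cells: int = 2000,
    n_genes: int = 1000,
    n_types: int = 10,
    chains: Sequence[str] = ("pca-50-umap",),
    k: int = 30,
    affected_fraction: float = 1.0,
    metric: str = "L2",
    seed: int = 0,
    figure_path: Optional[str] = None,
) -> DistortionReport:
    """Two-batch mixing audit at a configurable batch shift.

    Generates a mixture, splits cells into two batches at random, applies an
    additive log-space batch shift of scale ``shift_sd``, and compares the
    per-cell same-batch neighbor fraction distribution in ambient space with
    the one measured in each embedded chain. The K-S statistic between the
    ambient and embedded distributions quantifies how much the embedding
    distorts the apparent extent of mixing.
    """
    spec = synthetic.default_mixture_spec(n_cells, n_genes, n_types, seed=seed)
    counts, ann = synthetic.generate_mixture_counts(spec)
    rng = np.random.default_rng(seed + 1)
    batch = np.where(rng.random(n_cells) < 0.5, "batchA", "batchB").astype(object)
    ann.table["batch"] = batch
    ann.table["condition"] = batch
    counts = synthetic.add_batch_effect(counts, ann, shift_sd,
                                        affected_fraction, seed=seed + 2)

    embed_cfg = EmbedConfig(chains=["ambient", *chains], metric=metric,
                            n_replicates=1, seed=seed)
    spaces = pipeline_embed(counts, embed_cfg)
    ambient = spaces["ambient"][0]
    labels = ann.aligned_to(ambient.cell_ids).labels("batch")

    amb_frac = metrics.mixing_fractions(
        metrics.knn_index(ambient, k, metric), labels)
    rows = []
    dists = {"ambient": amb_frac}
    for name in chains:
        emb = spaces[name][0]
        frac = metrics.mixing_fractions(metrics.knn_index(emb, k, metric), labels)
        dists[name] = frac
        rows.append({"space": name, "shift_sd": shift_sd,
                     "ambient_mean": amb_frac.mean(), "embedded_mean": frac.mean(),
                     "ks_vs_ambient": metrics._ks_statistic(amb_frac, frac)})
    report = DistortionReport(config={"experiment": "mixing", "shift_sd": shift_sd,
                                      "n_cells": n_cells, "k": k, "seed": seed})
    report.add("mixing_summary", pd.DataFrame(rows).assign(property="local"))
    report.add("mixing_fractions", pd.DataFrame(dists))
    if figure_path:
        _plot_mixing(dists, figure_path)
    return report


def _plot_mixing(dists: dict, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    names = [n for n in dists if n != "ambient"]
    fig, axes = plt.subplots(1, max(len(names), 1), squeeze=False,
                             figsize=(4 * max(len(names), 1), 3))
    bins = np.linspace(0, 1, 21)
    for ax, name in zip(axes[0], names):
        ax.hist(dists["ambient"], bins=bins, alpha=0.6, label="ambient",
                color="tab:blue")
        ax.hist(dists[name], bins=bins, alpha=0.6, label=name,
                color="tab:orange")
        ax.set_xlabel("same-batch neighbor fraction")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def swissroll_experiment(
    turns_list: Sequence[float] = (1.0, 2.0, 3.0),
    neighbor_params: Sequence[int] = (10, 50),
    n_points: int = 600,
    noise_sd: float = 0.05,
    k: int = 30,
    seeds: Sequence[int] = (0, 1, 2),
    metric: str = "L2",
) -> DistortionReport:
    """Neighbor scrambling of embedded Swiss-rolls of increasing tightness.

    For each (turns, seed) a roll is generated and embedded with UMAP at
    each neighbor setting; the score is the mean Jaccard dissimilarity of
    k-NN sets between the embedding and the known intrinsic 2D coordinates
    (arc length × height) of the roll.
    """
    rows = []
    for turns in turns_list:
        for seed in seeds:
            pts3d, intrinsic = synthetic.generate_swiss_roll(
                n_points, turns=turns, noise_sd=noise_sd, seed=seed)
            ref = metrics.knn_index(intrinsic, k, metric)
            for npar in neighbor_params:
                emb = run_nonlinear_2d(pts3d, "umap", int(npar), metric, seed)
                idx = metrics.knn_index(emb.coords, k, metric)
                j = metrics.jaccard_neighbor_distance(ref, idx)
                rows.append({"turns": turns, "n_neighbors": int(npar),
                             "seed": seed, "mean_jaccard": j.mean(),
                             "median_jaccard": float(np.median(j))})
    report = DistortionReport(config={"experiment": "swissroll",
                                      "n_points": n_points, "k": k,
                                      "noise_sd": noise_sd})
    report.add("swissroll", pd.DataFrame(rows).assign(property="local"))
    return report
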