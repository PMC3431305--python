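"""Config-driven orchestration of the full profiling workflow.

One :func:`run_pipeline` call executes read -> replicate averaging ->
presence filter -> mean-intensity filter -> Pareto scaling -> PCA ->
OPLS-DA per configured class comparison -> dendrogram + cluster metrics
-> S-plot + jackknife selection -> adduct annotation, writing a run
directory of CSV/TSV reports. The run is a pure function of
(input files, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import biomarkers, chemometrics, clustering
from .feature_table import (FeatureTable, average_replicates,
                            filter_mean_intensity, filter_presence,
                            pareto_scale, read_feature_table)

logger = logging.getLogger(__name__)


@dataclass
class ComparisonSpec:
    """One discriminant model: which observations, which labels."""

    name: str
    level: str = "class"                    # "class" or "subclass"
    include: list[str] | None = None        # restrict to these class labels
    collapse: dict[str, str] | None = None  # label -> merged label
    n_pred: int | str = "auto"
    n_orth: int | str = "auto"


@dataclass
class PipelineConfig:
    table_path: str | None = None
    presence_frac: float = 0.8
    min_mean: float = 1.0
    folds: int = 7
    seed: int = 0
    comparisons: list[ComparisonSpec] = field(default_factory=lambda: [
        ComparisonSpec("three_class"),
        ComparisonSpec("durum_vs_bread",
                       collapse={"HBW": "BW", "SBW": "BW"}),
        ComparisonSpec("hard_vs_soft", include=["HBW", "SBW"]),
    ])
    splot_comparisons: list[str] = field(
        default_factory=lambda: ["durum_vs_bread", "hard_vs_soft"])
    min_abs_cov: float | None = None        # None -> 95th-percentile default
    min_abs_pcorr: float | None = None
    annotation_db: str | None = None        # None -> bundled compound table
    tol_ppm: float = 10.0
    out_dir: str = "run"


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    comps = [ComparisonSpec(**c) for c in raw.pop("comparisons", [])]
    cfg = PipelineConfig(**raw)
    if comps:
        cfg.comparisons = comps
    return cfg


def _labels_for(ft: FeatureTable, comp: ComparisonSpec
                ) -> tuple[np.ndarray, np.ndarray]:
    """(row mask, labels) for one comparison on the averaged table."""
    labels = (ft.subclass_labels if comp.level == "subclass"
              else ft.class_labels).copy()
    mask = np.ones(len(labels), dtype=bool)
    if comp.include is not None:
        mask = np.isin(ft.class_labels, comp.include)
    labels = labels[mask]
    if comp.collapse:
        labels = np.array([comp.collapse.get(l, l) for l in labels],
                          dtype=object)
    return mask, labels


def run_pipeline(cfg: PipelineConfig,
                 table: FeatureTable | None = None) -> Path:
    """Execute the whole workflow; returns the run directory path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("metaboprof")
    root.addHandler(fh)
    try:
        return _run(cfg, table, out)
    finally:
        root.removeHandler(fh)
        fh.close()


def _run(cfg: PipelineConfig, table: FeatureTable | None, out: Path) -> Path:
    if table is None:
        if cfg.table_path is None:
            raise ValueError("config has no table_path and no table was given")
        logger.info("stage=read path=%s", cfg.table_path)
        table = read_feature_table(cfg.table_path)
    logger.info("stage=read n_obs=%d n_features=%d", table.n_obs,
                table.n_features)

    averaged = average_replicates(table)
    logger.info("stage=average n_lines=%d", averaged.n_obs)

    filtered, rep1 = filter_presence(averaged, cfg.presence_frac)
    filtered, rep2 = filter_mean_intensity(filtered, cfg.min_mean)
    pd.DataFrame([
        {"stage": r.stage_name, "n_before": r.n_before, "n_removed": r.n_removed,
         "n_retained": r.n_retained,
         "removed_fraction": round(r.removed_fraction, 4)}
        for r in (rep1, rep2)
    ]).to_csv(out / "filter_report.tsv", sep="\t", index=False)

    X, scaler = pareto_scale(filtered)
    logger.info("stage=scale n_features=%d", X.shape[1])

    pca = chemometrics.fit_pca(X, n_components=min(7, X.shape[0] - 1))
    ell = chemometrics.hotelling_ellipse(pca.scores[:, :2])
    pd.DataFrame({
        "line_id": filtered.line_ids, "class": filtered.class_labels,
        "t1": pca.scores[:, 0], "t2": pca.scores[:, 1],
        "hotelling_t2": ell.t2_values, "outlier": ell.outliers,
    }).to_csv(out / "pca_scores.csv", index=False)
    logger.info("stage=pca r2x_cum=%.3f outliers=%d", pca.r2x_cum,
                int(ell.outliers.sum()))

    summary_rows = []
    fisher_rows = []
    models: dict[str, chemometrics.OplsdaModel] = {}
    model_data: dict[str, tuple[np.ndarray, np.ndarray, FeatureTable]] = {}
    for comp in cfg.comparisons:
        mask, labels = _labels_for(filtered, comp)
        sub = filtered.select_observations(mask)
        Xs, _ = pareto_scale(sub)
        logger.info("stage=oplsda model=%s n_obs=%d seed=%d", comp.name,
                    Xs.shape[0], cfg.seed)
        model = chemometrics.fit_oplsda(
            Xs, labels, n_pred=comp.n_pred, n_orth=comp.n_orth,
            k_folds=cfg.folds, seed=cfg.seed)
        models[comp.name] = model
        model_data[comp.name] = (Xs, labels, sub)

        pred, _ = chemometrics.classify(model, Xs)
        conf = chemometrics.misclassification_table(labels, pred,
                                                    model.class_levels)
        p_fisher = chemometrics.fisher_exact_probability(conf)
        summary_rows.append(chemometrics.model_summary_row(
            comp.name, model, conf.n_misclassified))
        fisher_rows.append({"model": comp.name, "fisher_exact_p": p_fisher})
        conf.to_dataframe().to_csv(out / f"confusion_{comp.name}.csv")

        ncol = min(2, model.n_pred)
        scores = pd.DataFrame({
            "line_id": sub.line_ids, "label": labels,
        })
        for a in range(ncol):
            scores[f"tp{a + 1}"] = model.Tp[:, a]
        if model.n_orth:
            scores["to1"] = model.To[:, 0]
        scores.to_csv(out / f"scores_{comp.name}.csv", index=False)

        dend = clustering.single_linkage(model.Tp[:, :ncol],
                                         leaf_labels=list(sub.line_ids))
        (out / f"dendrogram_{comp.name}.nwk").write_text(dend.to_newick())
        dend.merges_dataframe().to_csv(out / f"merges_{comp.name}.csv",
                                       index=False)
        metrics = [clustering.cluster_metrics(dend, node)
                   for node in range(dend.n_leaves, 2 * dend.n_leaves - 1)]
        pd.DataFrame([{"cluster": m.cluster_id, "compactness": m.compactness,
                       "distinctness": m.distinctness} for m in metrics]
                     ).to_csv(out / f"cluster_metrics_{comp.name}.csv",
                              index=False)

    pd.DataFrame(summary_rows).to_csv(out / "model_summary.tsv", sep="\t",
                                      index=False)
    pd.DataFrame(fisher_rows).to_csv(out / "fisher_probabilities.csv",
                                     index=False)

    # biomarker selection on the designated two-class comparisons
    for comp_name in cfg.splot_comparisons:
        if comp_name not in models:
            continue
        model = models[comp_name]
        Xs, labels, sub = model_data[comp_name]
        points = biomarkers.splot(model.Tp[:, 0], Xs, sub.feature_ids)
        intervals = biomarkers.jackknife_cov_ci(
            Xs, labels, k=cfg.folds, seed=cfg.seed,
            n_pred=model.n_pred, n_orth=model.n_orth,
            feature_ids=sub.feature_ids, class_levels=model.class_levels)
        selected = biomarkers.select_discriminatory(
            points, intervals, cfg.min_abs_cov, cfg.min_abs_pcorr)
        logger.info("stage=biomarkers selected=%d", len(selected))

        by_id = {iv.feature_id: iv for iv in intervals}
        meta = {f.feature_id: f for f in sub.features}
        # direction: class with the higher mean score on t1 side of the ion
        lvl_means = {lev: model.Tp[labels == lev, 0].mean()
                     for lev in model.class_levels}
        pos_class = max(lvl_means, key=lvl_means.get)
        neg_class = min(lvl_means, key=lvl_means.get)
        sel_df = pd.DataFrame([{
            "feature_id": p.feature_id,
            "rt": meta[p.feature_id].rt, "mz": meta[p.feature_id].mz,
            "cov": p.cov, "pcorr": p.pcorr,
            "ci_lo": by_id[p.feature_id].lo, "ci_hi": by_id[p.feature_id].hi,
            "direction": pos_class if p.cov > 0 else neg_class,
        } for p in selected])
        sel_df.to_csv(out / f"selected_ions_{comp_name}.csv", index=False)
        pd.DataFrame([{"feature_id": p.feature_id, "cov": p.cov,
                       "pcorr": p.pcorr} for p in points]
                     ).to_csv(out / f"splot_points_{comp_name}.csv", index=False)

        db = ann.read_compound_db(cfg.annotation_db)
        rows = []
        for _, r in sel_df.iterrows():
            hits = ann.best_hits(ann.annotate(r["mz"], db, tol=cfg.tol_ppm))
            for h in hits:
                rows.append({
                    "Ion Identifier": r["feature_id"], "Ion RT": r["rt"],
                    "Ion m/z": r["mz"],
                    "Adduct": None if h.is_nc else h.adduct.name,
                    "Adduct Mass": None if h.is_nc else round(h.neutral_mass, 4),
                    "Dppm": None if h.is_nc else int(round(abs(h.dppm))),
                    "Tentative Identity": None if h.is_nc else h.compound.name,
                    "Empirical Formula": None if h.is_nc
                    else str(h.compound.formula),
                    "Class": "NC" if h.is_nc else h.compound.lipid_category,
                    "Overexpressed In": r["direction"],
                    "Broad Class": h.broad_class,
                })
        pd.DataFrame(rows).to_csv(out / f"annotation_report_{comp_name}.csv",
                                  index=False)
        logger.info("stage=annotation model=%s hits=%d", comp_name, len(rows))

    logger.info("stage=done out=%s", out)
    return out
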