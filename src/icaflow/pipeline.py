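"""Configuration-driven driver chaining every analysis stage.

QC -> low-expression filter -> per-feature moderated linear models ->
differential list -> PCA with component-count estimation -> rank-1
deflation -> FastICA -> decile contributors -> stage-dependent
hypergeometric enrichment -> network and manifest reports.

Two branches are executed: the *global* stage enriches the differential
gene list against each database's full universe; the *independent*
stage runs ICA on the differential-gene matrix (after deflation, with
one fewer component) and enriches each component's contributors against
the differential background.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dgea import (
    build_design,
    ebayes_moderate,
    fit_linear_models,
    hierarchical_order,
    select_differential,
    select_strong_effects,
)
from .decomposition import (
    contributor_overlap,
    default_k_max,
    deflate_first_component,
    estimate_ncp,
    fit_pca,
    run_fastica,
    select_contributors,
)
from .enrichment import run_enrichment, stagewise_backgrounds
from .io import (
    DataError,
    ExpressionMatrix,
    read_annotation,
    read_expression_matrix,
    read_gene_sets,
    read_tr_targets,
)
from .qc import compute_rle, filter_low_expressed, pca_outlier_screen
from .reporting import (
    build_network,
    write_enrichment_table,
    write_manifest,
    write_network,
)

__all__ = ["PipelineConfig", "run_pipeline", "gene_level_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline inputs and tunables; only the paths are required."""

    expression: str = ""
    sample_sheet: str = ""
    annotation: str = ""
    gene_sets: list[str] = field(default_factory=list)
    tr_targets: str = ""
    tr_type_filter: str = "transcription factor binding site"
    out_dir: str = "icaflow_out"
    alpha: float = 0.05
    filter_fraction: float = 12.0 / 28.0  # min_samples = round(fraction * m)
    min_samples: int | None = None        # overrides filter_fraction when set
    # the screening op defaults to 3.0; the driver flags only gross
    # deviations since strong biological modes make sample scores heavy-tailed
    z_cut: float = 5.0
    K_max: int | None = None
    ncp_method: str = "gcv"
    deflate: bool = True
    k_override: int | None = None
    seed: int = 0
    tolerance: float = 1e-4
    max_iter: int = 1000
    strong_effect_convention: str = "signed"
    standardize_heatmap: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DataError("alpha must lie in (0, 1)")
        if self.tolerance <= 0:
            raise DataError("tolerance must be > 0")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def gene_level_matrix(
    expr: ExpressionMatrix, feature_to_gene: dict[str, str]
) -> tuple[np.ndarray, list[str]]:
    """Collapse single-annotation features to genes (mean over features).

    Returns a genes x samples array and the gene ids, in first-seen
    feature order; features absent from the mapping are ignored.
    """
    groups: dict[str, list[int]] = {}
    for i, feat in enumerate(expr.feature_ids):
        gene = feature_to_gene.get(feat)
        if gene is not None:
            groups.setdefault(gene, []).append(i)
    if not groups:
        raise DataError("no feature maps to a gene")
    gene_ids = list(groups)
    values = np.vstack([expr.values[rows].mean(axis=0) for rows in groups.values()])
    return values, gene_ids


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write all reports; returns the manifest."""
    cfg = config
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    artifacts: list[str] = []

    def stage(name):
        logger.info("stage: %s", name)

    # ------------------------------------------------------------ input
    stage("read")
    try:
        expr = read_expression_matrix(cfg.expression, cfg.sample_sheet)
        annotation = read_annotation(cfg.annotation)
        databases = {Path(p).stem: read_gene_sets(p) for p in cfg.gene_sets}
        if cfg.tr_targets:
            databases["tr_targets"] = read_tr_targets(
                cfg.tr_targets, cfg.tr_type_filter
            ).as_gene_set_db()
    except DataError as exc:
        raise DataError(f"[read] {exc}") from exc
    counts["samples_in"] = expr.m_samples
    counts["features_in"] = expr.n_features

    # --------------------------------------------------------------- qc
    stage("qc")
    expr = expr.subset_samples([s.sample_id for s in expr.samples if s.included])
    rle = compute_rle(expr)
    screen = pca_outlier_screen(expr, z_cut=cfg.z_cut)
    keep = [sid for sid, flag in zip(screen.sample_ids, screen.outlier_flag)
            if not flag]
    dropped = sorted(set(screen.sample_ids) - set(keep))
    if dropped:
        logger.warning("QC dropped samples: %s", dropped)
    expr = expr.subset_samples(keep)
    counts["samples_kept"] = expr.m_samples
    qc_frame = rle.to_frame().join(screen.to_frame(), rsuffix="_pca")
    qc_frame.to_csv(out_dir / "qc_report.tsv", sep="\t")
    artifacts.append("qc_report.tsv")

    # ------------------------------------------------------------ filter
    stage("filter")
    min_samples = (
        cfg.min_samples if cfg.min_samples is not None
        else int(round(cfg.filter_fraction * expr.m_samples))
    )
    try:
        expr = filter_low_expressed(expr, min_samples)
    except DataError as exc:
        raise DataError(f"[filter] {exc}") from exc
    counts["min_samples"] = min_samples
    counts["features_filtered"] = expr.n_features

    # -------------------------------------------------------------- dgea
    stage("dgea")
    try:
        design = build_design(expr.samples)
        fit = ebayes_moderate(fit_linear_models(expr, design))
        diff = select_differential(fit, "distance", annotation, alpha=cfg.alpha)
        diff_gender = select_differential(fit, "gender", annotation, alpha=cfg.alpha)
    except DataError as exc:
        raise DataError(f"[dgea] {exc}") from exc
    counts["dgea"] = {"distance": diff.counts, "gender": diff_gender.counts}
    counts["prior"] = {"d0": fit.d0 if np.isfinite(fit.d0) else "inf",
                       "s0_squared": fit.s0_squared}
    diff.table.to_csv(out_dir / "differential_distance.tsv", sep="\t", index=False,
                      float_format="%.6g")
    diff_gender.table.to_csv(out_dir / "differential_gender.tsv", sep="\t",
                             index=False, float_format="%.6g")
    artifacts += ["differential_distance.tsv", "differential_gender.tsv"]
    if len(diff.table) >= 2:
        strong = select_strong_effects(diff, cfg.strong_effect_convention)
        counts["strong_effects"] = len(strong)
        if len(strong) >= 2:
            row_order, col_order = hierarchical_order(
                expr, strong, standardize=cfg.standardize_heatmap
            )
            pd.DataFrame({"feature_id": row_order}).to_csv(
                out_dir / "strong_effect_order.tsv", sep="\t", index=False
            )
            artifacts.append("strong_effect_order.tsv")

    # ------------------------------------------------- decomposition
    stage("decomposition")
    gene_of = {f: g for f, g in zip(diff.table["feature_id"], diff.table["gene_id"])
               if g}
    if len(gene_of) < 20:
        raise DataError(
            f"[decomposition] only {len(gene_of)} annotated differential features; "
            "too few for decomposition"
        )
    diff_expr = expr.subset_features(list(gene_of))
    gene_values, gene_ids = gene_level_matrix(diff_expr, gene_of)
    X = gene_values.T  # samples x genes
    counts["diff_genes_matrix"] = len(gene_ids)

    auto_max = default_k_max(*X.shape)
    K_max = min(cfg.K_max, min(X.shape) - 1) if cfg.K_max else auto_max
    k_gcv, _ = estimate_ncp(X, "gcv", K_max)
    k_smooth, _ = estimate_ncp(X, "smooth", K_max)
    counts["ncp"] = {"gcv": k_gcv, "smooth": k_smooth, "method": cfg.ncp_method}
    k_est = k_gcv if cfg.ncp_method == "gcv" else k_smooth
    k = cfg.k_override if cfg.k_override is not None else max(k_est, 2)
    counts["k_components"] = k

    pca = fit_pca(X)
    counts["pc1_variance_fraction"] = float(pca.variance_fraction[0])
    if cfg.deflate:
        deflation = deflate_first_component(X, pca)
        ica_input, k_ica = deflation.X_hat, max(k - 1, 1)
    else:
        ica_input, k_ica = X, k
    counts["k_ica"] = k_ica
    ica = run_fastica(ica_input, k_ica, seed=cfg.seed, tolerance=cfg.tolerance,
                      max_iter=cfg.max_iter, gene_ids=gene_ids)
    counts["ica_converged"] = bool(ica.converged)
    sets = select_contributors(ica)
    counts["contributors_per_ic"] = {s.component: len(s) for s in sets}
    if len(sets) >= 2:
        overlap, unique = contributor_overlap(sets)
        counts["contributor_unique"] = unique
    pd.DataFrame(ica.S, index=[s.sample_id for s in expr.samples],
                 columns=[f"C{j+1}" for j in range(k_ica)]).to_csv(
        out_dir / "ica_sources.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame(ica.A.T, index=gene_ids,
                 columns=[f"C{j+1}" for j in range(k_ica)]).to_csv(
        out_dir / "ica_mixing.tsv", sep="\t", float_format="%.6g")
    artifacts += ["ica_sources.tsv", "ica_mixing.tsv"]
    for s in sets:
        name = f"contributors_{s.component}.txt"
        (out_dir / name).write_text("\n".join(s.genes) + "\n")
        artifacts.append(name)

    # -------------------------------------------------------- enrichment
    stage("enrichment")
    regulation = diff.regulation_map()
    enrich_counts: dict = {}
    global_rows_first_db = None
    for db_name, db in databases.items():
        try:
            query = stagewise_backgrounds(diff.genes, None, db, alpha=cfg.alpha)
            rows = run_enrichment(query, regulation)
        except DataError as exc:
            raise DataError(f"[enrichment:{db_name}] {exc}") from exc
        if global_rows_first_db is None:
            global_rows_first_db = [r for r in rows if r.significant]
        artifacts.append(write_enrichment_table(rows, out_dir, f"enrichment_global_{db_name}"))
        enrich_counts[db_name] = {"global": int(sum(r.significant for r in rows))}
        for s in sets:
            try:
                q = stagewise_backgrounds(diff.genes, s.gene_set, db, alpha=cfg.alpha)
                ic_rows = run_enrichment(q, regulation)
            except DataError as exc:
                logger.warning("enrichment skipped for %s/%s: %s",
                               db_name, s.component, exc)
                continue
            artifacts.append(write_enrichment_table(
                ic_rows, out_dir, f"enrichment_{s.component}_{db_name}"))
            enrich_counts[db_name][s.component] = int(sum(r.significant for r in ic_rows))
    counts["enrichment_significant"] = enrich_counts

    # ----------------------------------------------------------- network
    stage("reporting")
    net = build_network(global_rows_first_db or [], regulation)
    counts["network"] = {
        "terms": net.n_terms, "genes": net.n_genes,
        "edges": net.n_edges, "components": net.n_components,
    }
    if net.n_edges:
        artifacts += write_network(net, out_dir, "network_global")

    manifest = {
        "package": "icaflow",
        "version": __version__,
        "numpy": np.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "counts": counts,
        "artifacts": sorted(artifacts),
    }
    write_manifest(manifest, out_dir)
    # subset chain sanity: filtered >= differential >= contributors per IC
    assert counts["features_filtered"] >= counts["dgea"]["distance"]["features"]
    assert all(
        counts["dgea"]["distance"]["distinct_genes"] >= c
        for c in counts["contributors_per_ic"].values()
    )
    return manifest
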