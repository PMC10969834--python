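"""End-to-end orchestration of the circular-comparison analysis.

One config drives: simulation -> surrogate-variable-adjusted DE ->
significance/fold filters -> chromosome, gene-set and imprinted-gene
enrichment -> delta-beta DM calling -> methylation enrichment -> chrX
window scans for both modalities -> co-localization -> clustering, PCA
and the NMF tissue scores. Everything is written under one output
directory with a machine-readable JSON summary and a manifest recording
the config and seed; a rerun from the manifest reproduces the summary.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ConfigError, ExpressionMatrix, MethylationMatrix
from .diffexpr import (
    estimate_surrogate_variables,
    filter_significant,
    group_similarity,
    pairwise_compare,
    test_differential_expression,
)
from .enrichment import chromosome_enrichment, genes_with_dm_cpg, geneset_overlap, imprinted_enrichment
from .io import (
    read_gmt,
    read_symbol_list,
    windows_to_bed,
    write_annotation_tsv,
    write_json,
    write_matrix_tsv,
)
from .methylation import call_dmcg, delta_beta, methylome_similarity
from .multivariate import correlation_cluster, pca, separation_score
from .positional import colocalize, window_scan
from .scores import fit_nmf, score_samples, train_tissue_score_model
from .synthetic import (
    NSC_ORIGINS,
    SyntheticConfig,
    generate_annotation,
    generate_expression,
    generate_methylation,
    generate_reference,
)

log = logging.getLogger("circlex")


@dataclass
class PipelineConfig:
    """Thresholds and stage settings for one pipeline run."""

    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)
    alpha: float = 0.01
    fold: float = 2.0
    delta_beta_threshold: float = 0.2
    pairwise_alpha: float = 0.05
    window_bp: int = 10_000_000
    step_bp: int = 1_000_000
    scan_alpha: float = 0.05
    score_k: int = 8
    score_holdout: float = 0.2
    n_nsc_like: int = 30
    gmt_path: str | None = None
    imprinted_path: str | None = None
    seed: int = 0
    outdir: str = "circlex_out"

    def __post_init__(self) -> None:
        for name in ("alpha", "pairwise_alpha", "scan_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if not 0 < self.delta_beta_threshold < 1:
            raise ConfigError("delta_beta_threshold must lie in (0, 1)")
        if self.fold < 1:
            raise ConfigError("fold must be >= 1")
        if not 0 < self.score_holdout < 1:
            raise ConfigError("score_holdout must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim = raw.pop("simulate", {})
        if isinstance(sim, dict):
            sim = SyntheticConfig(**sim)
        return cls(simulate=sim, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulate"] = self.simulate.to_dict()
        return d


def _seeded(config: PipelineConfig, tag: int) -> int:
    # named substreams per stage, all below 2**31
    return int(np.random.SeedSequence([config.seed, tag]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the JSON-ready summary dict."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    files: dict[str, str] = {}

    def stage(name):
        log.info("stage %s (t+%.1fs)", name, time.time() - t0)

    def fail(name, exc):
        raise ConfigError(f"pipeline stage '{name}' failed: {exc}") from exc

    # --- simulate -----------------------------------------------------
    stage("simulate")
    sim = SyntheticConfig(**{**config.simulate.to_dict(), "seed": _seeded(config, 1)})
    ann = generate_annotation(sim)
    expr, truth = generate_expression(sim, ann)
    meth, truth = generate_methylation(sim, ann)
    annotation = pd.concat([ann.genes, ann.cpgs])

    write_matrix_tsv(expr.values, outdir / "expression.tsv")
    write_matrix_tsv(meth.values, outdir / "methylation.tsv")
    expr.metadata.to_csv(outdir / "samples.tsv", sep="\t")
    write_annotation_tsv(ann.genes, outdir / "genes.tsv")
    write_annotation_tsv(ann.cpgs, outdir / "cpgs.tsv")
    write_json(truth.to_dict(), outdir / "ground_truth.json")
    files.update(
        expression="expression.tsv",
        methylation="methylation.tsv",
        samples="samples.tsv",
        genes="genes.tsv",
        cpgs="cpgs.tsv",
        ground_truth="ground_truth.json",
    )

    # --- differential expression with SVA -----------------------------
    stage("diffexpr")
    nsc = expr.subset_samples(expr.metadata.index[expr.metadata["lineage"] == "NSC"])
    labels = nsc.metadata["origin"]
    design = np.column_stack([np.ones(len(labels)), (labels == "iPSC-NSC").to_numpy(float)])
    svs = estimate_surrogate_variables(nsc, design, seed=_seeded(config, 2))
    de = test_differential_expression(nsc, labels, svs, reference="ESC-NSC", treatment="iPSC-NSC")
    sig, fold = filter_significant(de, alpha=config.alpha, fold_change=config.fold)
    de_out = de.join(ann.genes[["chromosome", "position"]])
    write_matrix_tsv(de_out, outdir / "de_table.tsv")
    files["de_table"] = "de_table.tsv"

    chrom = ann.genes["chromosome"]
    summary["stages"]["diffexpr"] = {
        "n_sv": svs.n_sv,
        "n_significant": int(len(sig)),
        "n_fold": int(len(fold)),
        "n_significant_chrX": int((chrom.loc[sig] == "chrX").sum()),
        "n_fold_chrX": int((chrom.loc[fold] == "chrX").sum()),
        "sensitivity_planted": (
            float(np.mean([g in set(sig) for g in truth.affected_genes]))
            if truth.affected_genes
            else None
        ),
    }

    # --- chromosome enrichment (expression) ---------------------------
    stage("enrichment")
    enr = chromosome_enrichment(sig, ann.genes, directions=de.loc[sig, "direction"])
    write_matrix_tsv(enr, outdir / "chromosome_enrichment_expression.tsv")
    files["chromosome_enrichment_expression"] = "chromosome_enrichment_expression.tsv"
    x_row = enr.loc["chrX"] if "chrX" in enr.index else None
    summary["stages"]["enrichment"] = {
        "chrX_p": float(x_row["p"]) if x_row is not None else None,
        "chrX_adjusted_p": float(x_row["adjusted_p"]) if x_row is not None else None,
        "chrX_k_up": int(x_row.get("k_up", 0)) if x_row is not None else None,
        "chrX_k_down": int(x_row.get("k_down", 0)) if x_row is not None else None,
        "min_p_chromosome": str(enr["p"].idxmin()),
    }

    if config.gmt_path:
        sets = read_gmt(config.gmt_path)
        symbols = ann.genes.loc[sig, "gene_symbol"]
        res = geneset_overlap(symbols, sets, ann.genes["gene_symbol"])
        summary["stages"]["geneset"] = [
            {"set": r.set_name, "k": r.k, "p": r.p, "adjusted_p": r.adjusted_p} for r in res
        ]

    # --- pairwise line comparisons ------------------------------------
    stage("pairwise")
    pairs = []
    meta = nsc.metadata
    for bg in sorted(meta["background"].unique()):
        esc_ids = meta.index[(meta["background"] == bg) & (meta["origin"] == "ESC-NSC")]
        ipsc_lines = meta.loc[
            (meta["background"] == bg) & (meta["origin"] == "iPSC-NSC"), "line"
        ].unique()
        for line in sorted(ipsc_lines):
            line_ids = meta.index[meta["line"] == line]
            if len(line_ids) >= 2 and len(esc_ids) >= 2:
                pairs.append((str(line), list(line_ids), list(esc_ids)))
    pw = pairwise_compare(nsc, pairs, ann.genes, alpha=config.pairwise_alpha)
    summary["stages"]["pairwise"] = {
        r.name: {"n_significant": r.counts["n_significant"], "x_enrichment_p": r.x_enrichment_p}
        for r in pw
    }

    # --- group similarity ---------------------------------------------
    esc_ids = meta.index[meta["origin"] == "ESC-NSC"]
    ipsc_ids = meta.index[meta["origin"] == "iPSC-NSC"]
    summary["stages"]["similarity"] = {
        "expression_all": group_similarity(nsc, esc_ids, ipsc_ids),
        "expression_autosomal": group_similarity(nsc, esc_ids, ipsc_ids, ann.genes, "autosomal"),
        "expression_chrX": group_similarity(nsc, esc_ids, ipsc_ids, ann.genes, "chrX"),
    }

    # --- methylation ---------------------------------------------------
    stage("methylation")
    mmeta = meth.metadata
    dm = delta_beta(meth, mmeta["origin"], reference="ESC-NSC", treatment="iPSC-NSC")
    called, hyper, hypo = call_dmcg(dm, threshold=config.delta_beta_threshold)
    write_matrix_tsv(dm, outdir / "dm_table.tsv")
    files["dm_table"] = "dm_table.tsv"
    dm_dirs = dm.loc[called, "direction"]
    menr = chromosome_enrichment(called, ann.cpgs, directions=dm_dirs)
    write_matrix_tsv(menr, outdir / "chromosome_enrichment_methylation.tsv")
    files["chromosome_enrichment_methylation"] = "chromosome_enrichment_methylation.tsv"

    m_esc = mmeta.index[mmeta["origin"] == "ESC-NSC"]
    m_ipsc = mmeta.index[mmeta["origin"] == "iPSC-NSC"]
    planted = set(truth.dm_cpgs)
    summary["stages"]["methylation"] = {
        "n_called": int(len(called)),
        "n_hyper": int(len(hyper)),
        "n_hypo": int(len(hypo)),
        "n_called_chrX": int((ann.cpgs.loc[called, "chromosome"] == "chrX").sum()),
        "chrX_p": float(menr.loc["chrX", "p"]) if "chrX" in menr.index else None,
        "similarity_autosomal": methylome_similarity(meth, m_esc, m_ipsc, ann.cpgs, "autosomal"),
        "similarity_chrX": methylome_similarity(meth, m_esc, m_ipsc, ann.cpgs, "chrX"),
        "sensitivity_planted": (
            float(np.mean([c in set(called) for c in planted])) if planted else None
        ),
    }

    if config.imprinted_path:
        imprinted = read_symbol_list(config.imprinted_path)
        q = genes_with_dm_cpg(called, ann.cpgs)
        p_imp, hit = imprinted_enrichment(q, imprinted, ann.genes["gene_symbol"])
        summary["stages"]["imprinted"] = {"p": p_imp, "overlap": hit}

    # --- positional scans and co-localization --------------------------
    stage("positional")
    gx = ann.genes[ann.genes["chromosome"] == "chrX"]
    cx = ann.cpgs[ann.cpgs["chromosome"] == "chrX"]
    de_hits_x = gx.loc[gx.index.intersection(sig), "position"]
    dm_hits_x = cx.loc[cx.index.intersection(called), "position"]
    win_e = window_scan(
        de_hits_x, gx["position"], "chrX", config.window_bp, config.step_bp, alpha=config.scan_alpha
    )
    win_m = window_scan(
        dm_hits_x, cx["position"], "chrX", config.window_bp, config.step_bp, alpha=config.scan_alpha
    )
    write_matrix_tsv(win_e, outdir / "windows_expression.tsv")
    write_matrix_tsv(win_m, outdir / "windows_methylation.tsv")
    windows_to_bed(win_e, outdir / "windows_expression.bed")
    windows_to_bed(win_m, outdir / "windows_methylation.bed")
    files.update(
        windows_expression="windows_expression.tsv",
        windows_methylation="windows_methylation.tsv",
    )
    coloc = colocalize(win_e, win_m)
    coloc.regions.to_csv(outdir / "colocalized_regions.tsv", sep="\t", index=False)
    files["colocalized_regions"] = "colocalized_regions.tsv"
    summary["stages"]["positional"] = {
        "n_enriched_expression": int(win_e["enriched"].sum()),
        "n_enriched_methylation": int(win_m["enriched"].sum()),
        "n_colocalized_regions": int(len(coloc.regions)),
        "colocalized_regions": coloc.regions.to_dict("records"),
    }

    # --- clustering / PCA / separation ---------------------------------
    stage("multivariate")
    # three components: the design has three sample-level axes
    # (experiment batch, genetic background, ESC/iPSC origin)
    origin_labels = meta["origin"].tolist()
    pca_auto = pca(nsc.values, ann.genes, "autosomal", n_components=3)
    pca_x = pca(nsc.values, ann.genes, "chrX", n_components=3)
    sep = {
        "origin_autosomal": separation_score(pca_auto.scores, origin_labels),
        "origin_chrX": separation_score(pca_x.scores, origin_labels),
        "background_autosomal": separation_score(
            pca_auto.scores, meta["background"].astype(str).tolist()
        ),
    }
    dend_auto = correlation_cluster(
        nsc.values.loc[(ann.genes["chromosome"] != "chrX").to_numpy()]
    )
    (outdir / "dendrogram_autosomal.nwk").write_text(dend_auto.to_newick() + "\n")
    files["dendrogram_autosomal"] = "dendrogram_autosomal.nwk"
    pca_x.scores.to_csv(outdir / "pca_chrX.tsv", sep="\t")

    # methylation clustering: X CpGs split ESC-NSC vs iPSC-NSC, autosomal do not
    def origin_pure_split(values) -> bool:
        top_a, top_b = correlation_cluster(values).top_split()
        return all(mmeta.loc[list(g), "origin"].nunique() == 1 for g in (top_a, top_b))

    x_cpg = (ann.cpgs["chromosome"] == "chrX").to_numpy()
    summary["stages"]["multivariate"] = {
        "separation_scores": sep,
        "meth_chrX_split_by_origin": origin_pure_split(meth.values.loc[x_cpg]),
        "meth_autosomal_split_by_origin": origin_pure_split(meth.values.loc[~x_cpg]),
    }

    # --- tissue scores --------------------------------------------------
    stage("scores")
    ref_seed = _seeded(config, 3)
    ref, ref_labels = generate_reference(
        k_signatures=config.score_k, n_nsc_like=config.n_nsc_like, seed=ref_seed
    )
    rng = np.random.default_rng(_seeded(config, 4))
    core = ref_labels[ref_labels != "nsc_like"]
    holdout = rng.random(len(core)) < config.score_holdout
    train_ids = core.index[~holdout]
    test_ids = core.index[holdout]

    train_vals = ref[train_ids]
    shift = float(train_vals.to_numpy().min())
    V = train_vals.to_numpy(float) - shift
    cache = fit_nmf(V, k=config.score_k, seed=ref_seed)
    model_p = train_tissue_score_model(
        train_vals, ref_labels[train_ids], "pluripotent", k=config.score_k, seed=ref_seed, _nmf_cache=cache
    )
    model_n = train_tissue_score_model(
        train_vals, ref_labels[train_ids], "brain", k=config.score_k, seed=ref_seed, _nmf_cache=cache
    )
    score_ids = list(test_ids) + list(ref_labels.index[ref_labels == "nsc_like"])
    scored = score_samples(ref[score_ids], model_p, model_n)
    scored["label"] = ref_labels[score_ids]
    scored.to_csv(outdir / "scores.tsv", sep="\t")
    files["scores"] = "scores.tsv"

    from .scores import auroc  # local to keep the public surface tidy

    test_scores = scored.loc[list(test_ids)]
    summary["stages"]["scores"] = {
        "holdout_pluripotent_auroc": auroc(
            test_scores["pluripotency_score"], test_scores["label"] == "pluripotent"
        ),
        "holdout_brain_auroc": auroc(
            test_scores["neurality_score"], test_scores["label"] == "brain"
        ),
        "n_train": int(len(train_ids)),
        "n_test": int(len(test_ids)),
    }

    # --- manifest -------------------------------------------------------
    files["manifest"] = "manifest.json"
    summary["files"] = files
    manifest = {"config": config.to_dict(), "seed": config.seed, "version": __version__}
    write_json(manifest, outdir / "manifest.json")
    write_json(summary, outdir / "summary.json")
    log.info("pipeline done in %.1fs", time.time() - t0)
    return summary
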