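"""Seeded generators for the circular-reprogramming study design.

The simulator emulates the structure of an isogenic comparison between
ESC-derived and iPSC-derived neural stem cells (NSCs): two genetic
backgrounds, per-experiment batch effects, a lineage axis (pluripotent vs
NSC), an X-chromosome-specific upregulation in iPSC-derived samples that
is clustered in genomic regions, bimodal splitting of X CpG methylation
(ESC beta ~0.5 going to ~0.8 / ~0.2 in iPSC-derived cells), and a labeled
reference cohort (pluripotent / brain / other) for score training.

Every generator is a pure function of ``(config, seed)``: the same inputs
give bit-identical outputs. Independent random substreams are derived per
operation so that, e.g., the methylation draw does not shift when the
expression model changes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .containers import (
    ConfigError,
    ExpressionMatrix,
    GroundTruth,
    MethylationMatrix,
)
from .genome import AUTOSOMES, CHRX, CHROM_LENGTHS

NSC_ORIGINS = ("ESC-NSC", "iPSC-NSC")
PLURI_ORIGINS = ("ESC", "iPSC")
IPSC_DERIVED = ("iPSC", "iPSC-NSC")

# substream tags so each generator owns an independent RNG
_STREAM_ANNOTATION = 1
_STREAM_EXPRESSION = 2
_STREAM_METHYLATION = 3
_STREAM_REFERENCE = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the simulated study.

    Scale defaults (~10,500 genes, ~20,000 CpGs, 24 samples) keep the full
    pipeline in the minutes range on a single CPU while preserving the
    statistical structure of a genome-scale array experiment.
    """

    n_genes_autosomal: int = 10_000
    n_genes_x: int = 500
    n_cpgs_autosomal: int = 19_000
    n_cpgs_x: int = 1_000
    n_backgrounds: int = 2
    n_batches: int = 3
    replicates_per_line: int = 3
    n_ipsc_nsc_lines: int = 3
    effect_x_log2: float = 1.0
    frac_x_affected: float = 0.12
    n_x_clusters: int = 3
    x_cluster_width: int = 10_000_000
    lineage_sd: float = 1.0
    batch_sd: float = 0.5
    background_sd: float = 0.7
    noise_sd: float = 0.25
    beta_noise_sd: float = 0.05
    dm_hyper_target: float = 0.8
    dm_hypo_target: float = 0.2
    frac_x_cpg_dm: float = 0.10
    n_dm_clusters: int = 2
    dm_in_cluster_frac: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes_autosomal": self.n_genes_autosomal,
            "n_cpgs_autosomal": self.n_cpgs_autosomal,
            "n_backgrounds": self.n_backgrounds,
            "n_batches": self.n_batches,
            "replicates_per_line": self.replicates_per_line,
            "n_ipsc_nsc_lines": self.n_ipsc_nsc_lines,
            "n_x_clusters": self.n_x_clusters,
            "x_cluster_width": self.x_cluster_width,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be > 0 (got {v})")
        if self.n_genes_x < 0 or self.n_cpgs_x < 0:
            raise ConfigError("X feature counts must be >= 0")
        if self.n_dm_clusters < 0 or self.n_dm_clusters > self.n_x_clusters:
            raise ConfigError("n_dm_clusters must lie in [0, n_x_clusters]")
        for name in ("lineage_sd", "batch_sd", "background_sd", "noise_sd", "beta_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("frac_x_affected", "frac_x_cpg_dm", "dm_in_cluster_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("dm_hyper_target", "dm_hypo_target"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_x_clusters * self.x_cluster_width > CHROM_LENGTHS[CHRX]:
            raise ConfigError("X cluster intervals exceed the chromosome length")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnnotationSet:
    """Gene and CpG annotation plus the planted positional ground truth."""

    genes: pd.DataFrame
    cpgs: pd.DataFrame
    truth: GroundTruth


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), stream]))


def _sample_complement(rng: np.random.Generator, length: int, intervals, size: int) -> np.ndarray:
    """Uniform 1-based positions on [1, length] outside the given intervals."""
    intervals = sorted(intervals)
    segments = []
    cursor = 1
    for start, end in intervals:
        if start > cursor:
            segments.append((cursor, start))
        cursor = max(cursor, end)
    if cursor <= length:
        segments.append((cursor, length + 1))
    lens = np.array([e - s for s, e in segments], dtype=float)
    if lens.sum() <= 0:
        raise ConfigError("cluster intervals cover the whole chromosome")
    if size == 0:
        return np.empty(0, dtype=np.int64)
    which = rng.choice(len(segments), size=size, p=lens / lens.sum())
    out = np.empty(size, dtype=np.int64)
    for i, seg in enumerate(which):
        s, e = segments[seg]
        out[i] = rng.integers(s, e)
    return out


def generate_annotation(config: SyntheticConfig) -> AnnotationSet:
    """Place genes and CpGs on chromosomes; plant clustered X effects.

    Affected X genes are confined to ``n_x_clusters`` disjoint intervals
    of width ``x_cluster_width`` on chrX; unaffected X genes are drawn
    from the complement so the planted intervals contain exactly the
    affected genes. Differentially-methylated X CpGs are preferentially
    placed inside the first ``n_dm_clusters`` of those intervals to
    create co-localization ground truth.
    """
    rng = _rng(config.seed, _STREAM_ANNOTATION)
    x_len = CHROM_LENGTHS[CHRX]

    # disjoint clusters: one uniform placement inside each equal segment
    seg_len = x_len // config.n_x_clusters
    if config.x_cluster_width > seg_len:
        raise ConfigError("x_cluster_width too large for the requested cluster count")
    clusters = []
    for i in range(config.n_x_clusters):
        lo = i * seg_len + 1
        hi = (i + 1) * seg_len - config.x_cluster_width + 1
        start = int(rng.integers(lo, hi + 1))
        clusters.append((start, start + config.x_cluster_width))

    # autosomal genes: chromosomes weighted by length, uniform positions
    auto_lens = np.array([CHROM_LENGTHS[c] for c in AUTOSOMES], dtype=np.int64)
    auto_idx = rng.choice(len(AUTOSOMES), size=config.n_genes_autosomal, p=auto_lens / auto_lens.sum())
    auto_pos = rng.integers(1, auto_lens[auto_idx] + 1)

    n_affected = int(round(config.frac_x_affected * config.n_genes_x))
    affected_cluster = rng.integers(0, config.n_x_clusters, size=n_affected)
    cl_start = np.array([c[0] for c in clusters], dtype=np.int64)
    cl_end = np.array([c[1] for c in clusters], dtype=np.int64)
    affected_pos = rng.integers(cl_start[affected_cluster], cl_end[affected_cluster])
    other_pos = _sample_complement(rng, x_len, clusters, config.n_genes_x - n_affected)

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes_autosomal + config.n_genes_x)]
    chrom = [AUTOSOMES[i] for i in auto_idx] + [CHRX] * config.n_genes_x
    position = np.concatenate([auto_pos, affected_pos, other_pos])
    genes = pd.DataFrame(
        {
            "chromosome": chrom,
            "position": position,
            "gene_symbol": gene_ids,
        },
        index=pd.Index(gene_ids, name="feature_id"),
    )
    affected_genes = gene_ids[config.n_genes_autosomal : config.n_genes_autosomal + n_affected]

    # CpGs
    cauto_idx = rng.choice(len(AUTOSOMES), size=config.n_cpgs_autosomal, p=auto_lens / auto_lens.sum())
    cauto_pos = rng.integers(1, auto_lens[cauto_idx] + 1)
    n_dm = int(round(config.frac_x_cpg_dm * config.n_cpgs_x))
    dm_clusters = clusters[: config.n_dm_clusters]
    n_in = int(round(config.dm_in_cluster_frac * n_dm)) if dm_clusters else 0
    if n_in:
        in_cluster_idx = rng.integers(0, len(dm_clusters), size=n_in)
        dm_in_pos = rng.integers(cl_start[in_cluster_idx], cl_end[in_cluster_idx])
    else:
        dm_in_pos = np.empty(0, dtype=np.int64)
    dm_out_pos = _sample_complement(rng, x_len, clusters, n_dm - n_in)
    cx_rest = rng.integers(1, x_len + 1, size=config.n_cpgs_x - n_dm)

    cpg_ids = [f"cg{i:06d}" for i in range(config.n_cpgs_autosomal + config.n_cpgs_x)]
    cchrom = [AUTOSOMES[i] for i in cauto_idx] + [CHRX] * config.n_cpgs_x
    cpos = np.concatenate([cauto_pos, dm_in_pos, dm_out_pos, cx_rest])
    dm_cpgs = cpg_ids[config.n_cpgs_autosomal : config.n_cpgs_autosomal + n_dm]

    cpgs = pd.DataFrame(
        {"chromosome": cchrom, "position": cpos},
        index=pd.Index(cpg_ids, name="feature_id"),
    )
    cpgs["gene_symbol"] = _nearest_gene_symbol(cpgs, genes)

    truth = GroundTruth(
        x_cluster_intervals=clusters,
        dm_cluster_intervals=list(dm_clusters),
        affected_genes=list(affected_genes),
        dm_cpgs=list(dm_cpgs),
    )
    return AnnotationSet(genes=genes, cpgs=cpgs, truth=truth)


def _nearest_gene_symbol(cpgs: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Assign each CpG the symbol of the nearest gene on its chromosome."""
    out = np.full(len(cpgs), None, dtype=object)
    cpg_chrom = cpgs["chromosome"].to_numpy()
    cpg_pos = cpgs["position"].to_numpy()
    for chrom, g in genes.groupby("chromosome"):
        mask = cpg_chrom == chrom
        if not mask.any() or len(g) == 0:
            continue
        g = g.sort_values("position")
        gp = g["position"].to_numpy()
        sym = g["gene_symbol"].to_numpy()
        pos = cpg_pos[mask]
        right = np.clip(np.searchsorted(gp, pos), 0, len(gp) - 1)
        left = np.clip(right - 1, 0, len(gp) - 1)
        pick = np.where(np.abs(gp[right] - pos) <= np.abs(gp[left] - pos), right, left)
        out[mask] = sym[pick]
    return out


def _sample_table(config: SyntheticConfig) -> pd.DataFrame:
    """Study layout: per background one parental ESC line, one iPSC line,
    one ESC-derived NSC line and ``n_ipsc_nsc_lines`` re-differentiated
    iPSC-NSC lines, each hybridized in ``replicates_per_line`` replicates
    spread over the experiment batches."""
    rows = []

    def add(bg: int, origin: str, line: str) -> None:
        for rep in range(config.replicates_per_line):
            rows.append(
                {
                    "sample_id": f"bg{bg}_{line}_r{rep}",
                    "origin": origin,
                    "line": f"bg{bg}_{line}",
                    "lineage": "NSC" if origin.endswith("NSC") else "pluripotent",
                    "background": bg,
                    "batch": rep % config.n_batches,
                    "ipsc_derived": origin in IPSC_DERIVED,
                }
            )

    for bg in range(config.n_backgrounds):
        add(bg, "ESC", "ESC")
        add(bg, "iPSC", "iPSC")
        add(bg, "ESC-NSC", "ESC-NSC")
        for l in range(config.n_ipsc_nsc_lines):
            add(bg, "iPSC-NSC", f"iPSC-NSC-l{l}")
    return pd.DataFrame(rows).set_index("sample_id")


def generate_expression(
    config: SyntheticConfig, annotation: AnnotationSet
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate log2 expression under the additive study-design model.

    Per gene g and sample i:

        y_gi = mu_g + bg_g * background_i + batch_g * batch_i
               + lin_g * lineage_i + delta * 1[i iPSC-derived, g affected-X]
               + eps_gi

    with mu_g ~ N(7, 1.5), per-gene random coefficients drawn with the
    configured sds (so confounding is heterogeneous across genes, the
    setting surrogate-variable analysis is meant for), delta =
    ``effect_x_log2`` and eps ~ N(0, noise_sd).
    """
    rng = _rng(config.seed, _STREAM_EXPRESSION)
    meta = _sample_table(config)
    genes = annotation.genes
    n_g, n_s = len(genes), len(meta)

    mu = rng.normal(7.0, 1.5, size=n_g)
    bg_coef = rng.normal(0.0, config.background_sd, size=n_g)
    batch_coef = rng.normal(0.0, config.batch_sd, size=n_g)
    lin_coef = rng.normal(0.0, config.lineage_sd, size=n_g)

    background = meta["background"].to_numpy(float)
    batch = meta["batch"].to_numpy(float)
    lineage = (meta["lineage"] == "NSC").to_numpy(float)
    ipsc = meta["ipsc_derived"].to_numpy(float)
    affected = genes.index.isin(annotation.truth.affected_genes).astype(float)

    y = (
        mu[:, None]
        + bg_coef[:, None] * background[None, :]
        + batch_coef[:, None] * batch[None, :]
        + lin_coef[:, None] * lineage[None, :]
        + config.effect_x_log2 * affected[:, None] * ipsc[None, :]
        + rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    )
    values = pd.DataFrame(y, index=genes.index.rename(None), columns=meta.index)
    return ExpressionMatrix(values, meta), annotation.truth


def generate_methylation(
    config: SyntheticConfig, annotation: AnnotationSet
) -> tuple[MethylationMatrix, GroundTruth]:
    """Simulate beta values for the NSC samples.

    Non-DM CpGs draw a baseline from the trimodal mixture {0.1, 0.5, 0.9}
    shared by both groups. Planted DM X CpGs sit at beta 0.5 in ESC-NSCs
    and at ``dm_hyper_target`` or ``dm_hypo_target`` (half each) in
    iPSC-NSCs. Gaussian noise on the beta scale, clipped to [0, 1].
    """
    rng = _rng(config.seed, _STREAM_METHYLATION)
    meta = _sample_table(config)
    meta = meta[meta["lineage"] == "NSC"]
    cpgs = annotation.cpgs
    n_c, n_s = len(cpgs), len(meta)

    baseline = rng.choice([0.1, 0.5, 0.9], size=n_c)
    mean = np.tile(baseline[:, None], (1, n_s))

    dm_ids = annotation.truth.dm_cpgs
    dm_mask = cpgs.index.isin(dm_ids)
    ipsc = meta["ipsc_derived"].to_numpy(bool)

    n_dm = len(dm_ids)
    hyper = np.zeros(n_dm, dtype=bool)
    hyper[: n_dm // 2] = True
    hyper = hyper[rng.permutation(n_dm)]
    directions = {cid: ("hyper" if h else "hypo") for cid, h in zip(dm_ids, hyper)}

    dm_rows = np.where(dm_mask)[0]
    row_of = {cid: r for cid, r in zip(cpgs.index[dm_mask], dm_rows)}
    for cid in dm_ids:
        r = row_of[cid]
        mean[r, :] = 0.5
        target = config.dm_hyper_target if directions[cid] == "hyper" else config.dm_hypo_target
        mean[r, ipsc] = target

    beta = np.clip(mean + rng.normal(0.0, config.beta_noise_sd, size=(n_c, n_s)), 0.0, 1.0)
    values = pd.DataFrame(beta, index=cpgs.index.rename(None), columns=meta.index)
    truth = annotation.truth
    truth.dm_directions = directions
    return MethylationMatrix(values, meta), truth


def generate_reference(
    n_pluripotent: int = 98,
    n_brain: int = 34,
    n_other: int = 200,
    k_signatures: int = 8,
    n_genes: int = 2_000,
    n_nsc_like: int = 0,
    mixing_noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Labeled reference cohort for score training.

    Samples are non-negative mixtures of ``k_signatures`` non-negative
    gene signatures; class-specific mixing-weight means (pluripotent on
    signature 0, brain on signature 1, 'other' spread over the rest) make
    the classes linearly separable in component space. The 98/34/200
    defaults mirror a pluripotent / brain / other cohort at reduced
    scale. ``n_nsc_like`` adds samples mixing the pluripotent and brain
    signatures, emulating neural stem cells part-way along the
    pluripotent-to-neural path.

    Returns the expression DataFrame (genes x samples) and a label
    Series (pluripotent / brain / other / nsc_like).
    """
    for name, v in {
        "n_pluripotent": n_pluripotent,
        "n_brain": n_brain,
        "n_other": n_other,
    }.items():
        if v <= 0:
            raise ConfigError(f"{name} must be > 0")
    if k_signatures < 3:
        raise ConfigError("k_signatures must be >= 3")
    if n_nsc_like < 0 or mixing_noise_sd < 0:
        raise ConfigError("n_nsc_like and mixing_noise_sd must be >= 0")

    rng = _rng(seed, _STREAM_REFERENCE)
    W = rng.gamma(shape=2.0, scale=1.0, size=(n_genes, k_signatures))

    base = 0.3
    mean_pluri = np.full(k_signatures, base)
    mean_pluri[0] = 5.0
    mean_brain = np.full(k_signatures, base)
    mean_brain[1] = 5.0

    cols, labels = [], []

    def add(n, mean_fn, label):
        for j in range(n):
            m = mean_fn(j)
            h = np.clip(m + rng.normal(0.0, mixing_noise_sd, size=k_signatures), 0.0, None)
            cols.append(W @ h)
            labels.append(label)

    add(n_pluripotent, lambda j: mean_pluri, "pluripotent")
    add(n_brain, lambda j: mean_brain, "brain")

    def other_mean(j):
        m = np.full(k_signatures, base)
        comp = 2 + (j % max(k_signatures - 2, 1))
        m[comp] = 3.0
        return m

    add(n_other, other_mean, "other")

    def nsc_mean(j):
        a = 0.3 + 0.4 * rng.random()
        return a * mean_pluri + (1.0 - a) * mean_brain

    add(n_nsc_like, nsc_mean, "nsc_like")

    sample_ids = [f"ref{i:04d}" for i in range(len(cols))]
    values = pd.DataFrame(
        np.column_stack(cols),
        index=pd.Index([f"RG{i:05d}" for i in range(n_genes)]),
        columns=sample_ids,
    )
    return values, pd.Series(labels, index=sample_ids, name="label")
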