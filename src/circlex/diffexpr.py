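"""Surrogate-variable-adjusted differential expression.

The workhorse comparison is iPSC-derived NSCs versus ESC-derived NSCs:
per-gene ordinary least squares on [intercept, group, surrogate
variables], two-sided t test on the group coefficient, Benjamini-Hochberg
correction across genes, and a fold-change filter on the group-mean
log2 difference.

Surrogate variables are estimated with a two-step procedure: (1) remove
the primary design by per-gene least squares, (2) SVD the residual matrix
and keep the leading right singular vectors whose variance fraction beats
a permutation (parallel-analysis) threshold. This targets batch-like
structure that is shared across many genes but not modeled explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CirclexError, ConfigError, ExpressionMatrix
from .enrichment import hypergeometric_upper


@dataclass
class SurrogateVariables:
    """Retained surrogate variables (samples x n_sv, unit-norm columns)."""

    sv: np.ndarray
    variance_fractions: np.ndarray
    thresholds: np.ndarray

    @property
    def n_sv(self) -> int:
        return self.sv.shape[1]


def _residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Per-gene least-squares residuals of values (genes x n) on design (n x p)."""
    coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    return values - (design @ coef).T


def _variance_fractions(resid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose resid'resid; return variance fractions and vectors."""
    gram = resid.T @ resid
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    total = evals.sum()
    fracs = evals / total if total > 0 else np.zeros_like(evals)
    return fracs, evecs[:, order]


def estimate_surrogate_variables(
    expr: ExpressionMatrix | pd.DataFrame,
    primary_design: np.ndarray,
    n_permutations: int = 20,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SurrogateVariables:
    """Residual-SVD surrogate variables with a parallel-analysis cutoff.

    Component j is retained if its residual variance fraction exceeds the
    (1 - alpha) quantile of the j-th variance fraction across
    ``n_permutations`` row-wise independently permuted residual matrices;
    retention stops at the first component that fails.
    """
    values = expr.values.to_numpy(float) if isinstance(expr, ExpressionMatrix) else np.asarray(expr, float)
    X = np.asarray(primary_design, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if values.shape[1] != n:
        raise ConfigError("design rows must match sample count")
    if np.linalg.matrix_rank(X) < p:
        raise ConfigError("primary design is rank deficient")
    if n < p + 2:
        raise ConfigError("need at least design columns + 2 samples")
    if n_permutations < 1:
        raise ConfigError("n_permutations must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must lie in (0, 1)")

    resid = _residualize(values, X)
    fracs, vecs = _variance_fractions(resid)

    rng = np.random.default_rng(seed)
    perm_fracs = np.empty((n_permutations, len(fracs)))
    for b in range(n_permutations):
        # permute the raw rows, then residualize, so the null has the same
        # rank n - p structure as the observed residual matrix
        permuted = _residualize(rng.permuted(values, axis=1), X)
        perm_fracs[b], _ = _variance_fractions(permuted)
    thresholds = np.quantile(perm_fracs, 1.0 - alpha, axis=0)

    n_keep = 0
    max_sv = max(n - p - 1, 0)
    while n_keep < max_sv and fracs[n_keep] > thresholds[n_keep]:
        n_keep += 1
    return SurrogateVariables(
        sv=vecs[:, :n_keep].copy(),
        variance_fractions=fracs[:n_keep].copy(),
        thresholds=thresholds[: max(n_keep, 1)].copy(),
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjustment, monotone, capped at 1, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ConfigError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _group_vectors(labels, reference: str | None, treatment: str | None):
    labels = pd.Series(labels)
    levels = sorted(labels.unique().tolist())
    if len(levels) != 2:
        raise ConfigError(f"exactly two groups required, got {levels}")
    if reference is None and treatment is None:
        reference, treatment = levels
    elif treatment is None:
        treatment = [l for l in levels if l != reference][0]
    elif reference is None:
        reference = [l for l in levels if l != treatment][0]
    if {reference, treatment} != set(levels):
        raise ConfigError("reference/treatment do not match the labels")
    return labels, reference, treatment


def test_differential_expression(
    expr: ExpressionMatrix,
    group_labels,
    svs: SurrogateVariables | None = None,
    reference: str | None = None,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Per-gene OLS of expression on [1, group, SVs]; BH across genes.

    Returns a DataFrame indexed by gene with columns ``log2_fold_change``
    (treatment minus reference group mean), ``t``, ``p_value``,
    ``adjusted_p``, ``direction`` and ``zero_variance``. With no SVs this
    is exactly the equal-variance two-sample t test.
    """
    labels, reference, treatment = _group_vectors(group_labels, reference, treatment)
    Y = expr.values.to_numpy(float)
    n = Y.shape[1]
    if len(labels) != n:
        raise ConfigError("group labels must match the sample count")
    g = (labels == treatment).to_numpy(float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ConfigError("each group needs at least 2 samples")

    cols = [np.ones(n), g]
    if svs is not None and svs.n_sv > 0:
        cols.extend(svs.sv.T)
    X = np.column_stack(cols)
    p_cols = X.shape[1]
    df = n - p_cols
    if df <= 0:
        raise ConfigError("non-positive residual degrees of freedom")

    xtx_inv = np.linalg.inv(X.T @ X)
    coef = Y @ X @ xtx_inv.T  # genes x p
    resid = Y - coef @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    se = np.sqrt(np.clip(sigma2 * xtx_inv[1, 1], 0.0, None))

    zero_var = se <= 0
    t = np.zeros(len(Y))
    np.divide(coef[:, 1], se, out=t, where=~zero_var)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[zero_var] = 1.0
    t[zero_var] = 0.0

    lfc = Y[:, g == 1].mean(axis=1) - Y[:, g == 0].mean(axis=1)
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "t": t,
            "p_value": p,
            "adjusted_p": benjamini_hochberg(p),
            "direction": direction,
            "zero_variance": zero_var,
        },
        index=expr.gene_ids,
    )


def filter_significant(
    de: pd.DataFrame, alpha: float = 0.01, fold_change: float = 2.0
) -> tuple[pd.Index, pd.Index]:
    """Significant genes (adjusted_p < alpha) and the >= fold-change subset."""
    if fold_change < 1:
        raise ConfigError("fold_change must be >= 1")
    sig = de.index[de["adjusted_p"] < alpha]
    lfc_cut = np.log2(fold_change)
    fold = de.index[(de["adjusted_p"] < alpha) & (de["log2_fold_change"].abs() >= lfc_cut)]
    return sig, fold


@dataclass
class PairwiseResult:
    name: str
    table: pd.DataFrame
    significant: pd.Index
    x_enrichment_p: float
    counts: dict = field(default_factory=dict)


def pairwise_compare(
    expr: ExpressionMatrix,
    pairs: list[tuple[str, list, list]],
    annotation: pd.DataFrame,
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """Per-line comparisons: equal-variance t test, BH, chrX enrichment.

    ``pairs`` holds (name, iPSC-derived sample ids, matched ESC-derived
    sample ids); each side needs >= 2 samples. The chrX enrichment p is
    the hypergeometric upper tail of the significant set against the
    measured-gene universe.
    """
    results = []
    universe = expr.gene_ids
    missing_ann = universe.difference(annotation.index)
    if len(missing_ann):
        raise ConfigError(f"annotation missing genes: {list(missing_ann)[:5]}")
    chrom = annotation.loc[universe, "chromosome"]
    n_x = int((chrom == "chrX").sum())

    for name, ipsc_ids, esc_ids in pairs:
        for side in (ipsc_ids, esc_ids):
            unknown = set(side) - set(expr.sample_ids)
            if unknown:
                raise ConfigError(f"pair '{name}': unknown sample ids {sorted(unknown)}")
            if len(side) < 2:
                raise ConfigError(f"pair '{name}': each side needs >= 2 samples")
        a = expr.values[list(ipsc_ids)].to_numpy(float)
        b = expr.values[list(esc_ids)].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        zero = ~np.isfinite(t)
        t = np.where(zero, 0.0, t)
        p = np.where(zero, 1.0, p)
        adj = benjamini_hochberg(p)
        lfc = a.mean(axis=1) - b.mean(axis=1)
        table = pd.DataFrame(
            {
                "log2_fold_change": lfc,
                "t": t,
                "p_value": p,
                "adjusted_p": adj,
                "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
                "zero_variance": zero,
            },
            index=universe,
        )
        sig = universe[adj < alpha]
        k_x = int((chrom.loc[sig] == "chrX").sum())
        p_x = hypergeometric_upper(k_x, n_x, len(sig), len(universe))
        results.append(
            PairwiseResult(
                name=name,
                table=table,
                significant=sig,
                x_enrichment_p=p_x,
                counts={"n_significant": len(sig), "n_chrX": k_x},
            )
        )
    return results


def group_similarity(
    expr: ExpressionMatrix,
    group_a,
    group_b,
    annotation: pd.DataFrame | None = None,
    subset: str = "all",
) -> float:
    """Pearson correlation of the two group-mean log2 profiles.

    ``subset`` restricts the genes to 'all', 'autosomal' or 'chrX'
    (annotation required for the latter two).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ConfigError("both groups must be non-empty")
    values = expr.values
    if subset != "all":
        if annotation is None:
            raise ConfigError("annotation required for chromosome subsets")
        chrom = annotation.loc[values.index, "chromosome"]
        mask = chrom == "chrX" if subset == "chrX" else chrom != "chrX"
        values = values.loc[mask.to_numpy()]
        if values.empty:
            raise ConfigError(f"no genes in subset '{subset}'")
    ma = values[group_a].mean(axis=1).to_numpy()
    mb = values[group_b].mean(axis=1).to_numpy()
    if np.std(ma) == 0 or np.std(mb) == 0:
        raise CirclexError("zero-variance group-mean profile; correlation undefined")
    return float(np.corrcoef(ma, mb)[0, 1])
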