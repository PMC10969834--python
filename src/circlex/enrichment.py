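"""Hypergeometric enrichment of feature sets against annotation categories.

All tests are one-sided upper-tail (overrepresentation): given a universe
of N measured features of which K fall in a category, and a query of n
features with k category members, the p-value is P(X >= k) for
X ~ Hypergeometric(N, K, n). The universe is always the set of measured
features, not a genome-wide count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ConfigError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ConfigError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # survival function of k-1; scipy evaluates the tail in log space internally
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def chromosome_enrichment(
    query_features,
    annotation: pd.DataFrame,
    directions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-chromosome overrepresentation of a query feature set.

    The universe is every annotated feature. If ``directions`` maps query
    features to e.g. up/down (or hyper/hypo), separate tests of each
    directional subset are added, BH-corrected within their own family.
    Returns one row per chromosome present in the annotation.
    """
    from .diffexpr import benjamini_hochberg  # local import; circular at module load

    query = pd.Index(query_features)
    missing = query.difference(annotation.index)
    if len(missing):
        raise ConfigError(f"query features missing from annotation: {list(missing)[:5]}")
    chrom = annotation["chromosome"]
    chroms = sorted(chrom.unique().tolist())
    N = len(annotation)
    n = len(query)
    q_chrom = chrom.loc[query]

    rows = {}
    for c in chroms:
        K = int((chrom == c).sum())
        k = int((q_chrom == c).sum())
        rows[c] = {"k": k, "K": K, "n": n, "N": N, "p": hypergeometric_upper(k, K, n, N)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "chromosome"
    out["adjusted_p"] = benjamini_hochberg(out["p"].to_numpy())

    if directions is not None:
        directions = pd.Series(directions)
        extra = directions.index.difference(query)
        if len(extra):
            raise ConfigError("directions given for features outside the query")
        for label in sorted(directions.unique().tolist()):
            sub = directions.index[directions == label]
            sub_chrom = chrom.loc[sub]
            ks, ps = [], []
            for c in chroms:
                K = int(out.loc[c, "K"])
                k = int((sub_chrom == c).sum())
                ks.append(k)
                ps.append(hypergeometric_upper(k, K, len(sub), N))
            out[f"k_{label}"] = ks
            out[f"p_{label}"] = ps
            out[f"adjusted_p_{label}"] = benjamini_hochberg(np.asarray(ps))
    return out


@dataclass
class OverlapResult:
    set_name: str
    overlap: list
    k: int
    K: int
    n: int
    N: int
    p: float
    adjusted_p: float | None = None


def geneset_overlap(
    query_genes,
    gene_sets,
    universe,
) -> list[OverlapResult]:
    """Hypergeometric overlap of a query with one or more gene sets.

    Symbols are compared case-insensitively. ``gene_sets`` is either a
    single iterable of symbols or a mapping {set name: symbols} (as read
    from a GMT file); with multiple sets, BH is applied across sets.
    """
    from .diffexpr import benjamini_hochberg

    def norm(items):
        return {str(s).upper() for s in items}

    uni = norm(universe)
    if not uni:
        raise ConfigError("empty universe")
    q = norm(query_genes) & uni
    if isinstance(gene_sets, dict):
        named = gene_sets
    else:
        named = {"gene_set": gene_sets}

    results = []
    for name, members in named.items():
        s = norm(members) & uni
        hit = sorted(q & s)
        p = hypergeometric_upper(len(hit), len(s), len(q), len(uni))
        results.append(
            OverlapResult(set_name=name, overlap=hit, k=len(hit), K=len(s), n=len(q), N=len(uni), p=p)
        )
    adj = benjamini_hochberg(np.array([r.p for r in results]))
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    return results


def genes_with_dm_cpg(called_cpgs, cpg_annotation: pd.DataFrame) -> list[str]:
    """Map called CpGs to their annotated gene symbols (deduplicated)."""
    called = pd.Index(called_cpgs)
    missing = called.difference(cpg_annotation.index)
    if len(missing):
        raise ConfigError(f"CpGs missing from annotation: {list(missing)[:5]}")
    symbols = cpg_annotation.loc[called, "gene_symbol"].dropna()
    return sorted(set(symbols))


def imprinted_enrichment(
    genes_with_dm, imprinted_list, universe
) -> tuple[float, list[str]]:
    """Gene-level hypergeometric test for imprinted-gene overrepresentation.

    A gene counts once regardless of how many DM CpGs map to it.
    """
    uni = {str(s).upper() for s in universe}
    if not uni:
        raise ConfigError("empty universe")
    q = {str(s).upper() for s in genes_with_dm} & uni
    imp = {str(s).upper() for s in imprinted_list} & uni
    hit = sorted(q & imp)
    p = hypergeometric_upper(len(hit), len(imp), len(q), len(uni))
    return p, hit
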