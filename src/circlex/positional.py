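"""Windowed local-enrichment scan and cross-modality co-localization.

A sliding window moves along one chromosome; in each window the number
of hit features (DE genes or DM CpGs) among the measured features is
tested one-sided against the chromosome-wide hit rate with a binomial
test, BH-corrected across windows. Regions enriched in both expression
and methylation are reported as co-localized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError
from .diffexpr import benjamini_hochberg
from .genome import CHROM_LENGTHS


def window_scan(
    hit_positions,
    all_positions,
    chromosome: str,
    window_bp: int = 10_000_000,
    step_bp: int = 1_000_000,
    chrom_length: int | None = None,
    alpha: float = 0.05,
    min_hits: int = 3,
) -> pd.DataFrame:
    """Binomial sliding-window scan for locally clustered hits.

    Windows are 1-based half-open [start, start + window_bp) starting at
    1 and advancing by ``step_bp`` (a final clipped window covers the
    chromosome end). Per window, k hits out of m features are tested
    against the global rate rho = |hits| / |features| with the binomial
    upper tail; BH across windows; a window is ``enriched`` when the
    adjusted p is below ``alpha`` and k >= ``min_hits``.
    """
    hits = np.asarray(sorted(hit_positions), dtype=np.int64)
    feats = np.asarray(sorted(all_positions), dtype=np.int64)
    if feats.size == 0:
        raise ConfigError(f"no features on {chromosome}")
    if window_bp <= 0 or step_bp <= 0 or window_bp < step_bp:
        raise ConfigError("require window_bp >= step_bp > 0")
    # hits must be a sub-multiset of the feature positions
    fi = 0
    for h in hits:
        fi = np.searchsorted(feats, h, side="left")
        if fi >= feats.size or feats[fi] != h:
            raise ConfigError(f"hit position {h} not among the feature positions")
    length = int(chrom_length) if chrom_length is not None else CHROM_LENGTHS.get(chromosome, int(feats.max()))
    rho = hits.size / feats.size

    starts = list(range(1, max(length - window_bp + 1, 1) + 1, step_bp))
    last = length - window_bp + 1
    if last >= 1 and starts[-1] != last:
        starts.append(last)

    rows = []
    for s in starts:
        e = min(s + window_bp, length + 1)
        m = int(np.searchsorted(feats, e) - np.searchsorted(feats, s))
        k = int(np.searchsorted(hits, e) - np.searchsorted(hits, s))
        if m == 0 or rho >= 1.0:
            p = 1.0
        else:
            p = float(stats.binom.sf(k - 1, m, rho)) if k > 0 else 1.0
        rows.append({"chromosome": chromosome, "start": s, "end": e, "k": k, "m": m, "p": p})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = benjamini_hochberg(out["p"].to_numpy())
    out["enriched"] = (out["adjusted_p"] < alpha) & (out["k"] >= min_hits)
    return out


@dataclass
class CoLocalization:
    """Overlapping enriched windows across two scans plus merged regions."""

    pairs: pd.DataFrame  # one row per overlapping (window A, window B) pair
    regions: pd.DataFrame  # merged union interval per connected component


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return max(a_start, b_start) < min(a_end, b_end)


def colocalize(windows_a: pd.DataFrame, windows_b: pd.DataFrame) -> CoLocalization:
    """Pair enriched windows from two scans that overlap by >= 1 bp.

    Overlapping pairs are grouped into connected components; each
    component is reported as one merged region spanning the union of its
    windows. Both inputs must be on the same chromosome.
    """
    chroms = set(windows_a["chromosome"]) | set(windows_b["chromosome"])
    if len(chroms) > 1:
        raise ConfigError(f"mixed chromosomes in co-localization: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else None

    ea = windows_a[windows_a["enriched"]].reset_index(drop=True)
    eb = windows_b[windows_b["enriched"]].reset_index(drop=True)

    pair_rows = []
    for i, wa in ea.iterrows():
        for j, wb in eb.iterrows():
            if _overlaps(wa["start"], wa["end"], wb["start"], wb["end"]):
                pair_rows.append(
                    {
                        "chromosome": chrom,
                        "a_start": int(wa["start"]),
                        "a_end": int(wa["end"]),
                        "b_start": int(wb["start"]),
                        "b_end": int(wb["end"]),
                        "overlap_start": int(max(wa["start"], wb["start"])),
                        "overlap_end": int(min(wa["end"], wb["end"])),
                    }
                )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["chromosome", "a_start", "a_end", "b_start", "b_end", "overlap_start", "overlap_end"],
    )

    # merge the union extents of overlapping pairs into maximal regions
    intervals = sorted(
        (min(r["a_start"], r["b_start"]), max(r["a_end"], r["b_end"])) for r in pair_rows
    )
    merged = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    regions = pd.DataFrame(
        [{"chromosome": chrom, "start": s, "end": e} for s, e in merged],
        columns=["chromosome", "start", "end"],
    )
    return CoLocalization(pairs=pairs, regions=regions)
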