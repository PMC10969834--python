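"""Delta-beta differential methylation calling and methylome similarity.

The calling criterion is purely the difference of group-mean beta values:
a CpG is differentially methylated when |delta beta| exceeds a threshold
(0.2 by default), with the sign convention iPSC-derived minus
ESC-derived (positive = hypermethylated after reprogramming). No
per-CpG variance test is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CirclexError, ConfigError, MethylationMatrix
from .diffexpr import _group_vectors


def delta_beta(
    meth: MethylationMatrix,
    group_labels,
    reference: str | None = None,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Per-CpG difference of group means (treatment minus reference).

    Missing beta values are ignored CpG-wise; a CpG whose group is
    entirely missing is flagged in ``incomplete``.
    """
    labels, reference, treatment = _group_vectors(group_labels, reference, treatment)
    if len(labels) != meth.values.shape[1]:
        raise ConfigError("group labels must match the sample count")
    vals = meth.values.to_numpy(float)
    mask_t = (labels == treatment).to_numpy()
    mask_r = (labels == reference).to_numpy()
    if mask_t.sum() < 1 or mask_r.sum() < 1:
        raise ConfigError("each group needs at least 1 sample")

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-NaN groups are legitimate here; they surface as `incomplete`
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_t = np.nanmean(vals[:, mask_t], axis=1)
        mean_r = np.nanmean(vals[:, mask_r], axis=1)
    incomplete = np.isnan(mean_t) | np.isnan(mean_r)
    db = mean_t - mean_r
    return pd.DataFrame(
        {
            "mean_reference": mean_r,
            "mean_treatment": mean_t,
            "delta_beta": db,
            "direction": np.where(db > 0, "hyper", np.where(db < 0, "hypo", "none")),
            "incomplete": incomplete,
        },
        index=meth.cpg_ids,
    )


def call_dmcg(
    dm: pd.DataFrame, threshold: float = 0.2
) -> tuple[pd.Index, pd.Index, pd.Index]:
    """Call CpGs with |delta beta| strictly greater than the threshold.

    Returns (called, hyper, hypo); hyper and hypo partition the called
    set. Incomplete CpGs (a group entirely missing) are never called.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigError("threshold must lie in (0, 1)")
    ok = ~dm["incomplete"] if "incomplete" in dm else pd.Series(True, index=dm.index)
    db = dm["delta_beta"]
    called = dm.index[ok & (db.abs() > threshold)]
    hyper = dm.index[ok & (db > threshold)]
    hypo = dm.index[ok & (db < -threshold)]
    return called, hyper, hypo


def methylome_similarity(
    meth: MethylationMatrix,
    group_a,
    group_b,
    annotation: pd.DataFrame | None = None,
    subset: str = "all",
) -> float:
    """Pearson correlation of group-mean beta vectors over a CpG subset."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ConfigError("both groups must be non-empty")
    values = meth.values
    if subset != "all":
        if annotation is None:
            raise ConfigError("annotation required for chromosome subsets")
        chrom = annotation.loc[values.index, "chromosome"]
        mask = chrom == "chrX" if subset == "chrX" else chrom != "chrX"
        values = values.loc[mask.to_numpy()]
        if values.empty:
            raise ConfigError(f"no CpGs in subset '{subset}'")
    ma = values[group_a].mean(axis=1).to_numpy()
    mb = values[group_b].mean(axis=1).to_numpy()
    if np.std(ma) == 0 or np.std(mb) == 0:
        raise CirclexError("zero-variance group-mean beta vector; correlation undefined")
    return float(np.corrcoef(ma, mb)[0, 1])
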