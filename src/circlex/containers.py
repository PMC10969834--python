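"""In-memory containers shared by all analysis modules.

Matrices are plain pandas DataFrames (features as rows, samples as
columns) bundled with a per-sample metadata table. Annotation is a
DataFrame indexed by feature id with ``chromosome``, ``position`` and
``gene_symbol`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CHROMOSOMES


class CirclexError(Exception):
    """Base error for this package."""


class ConfigError(CirclexError):
    """Invalid configuration or precondition violation."""


REQUIRED_METADATA = ("origin", "background", "batch")


def _check_ids(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()[:5]
        raise ConfigError(f"duplicate {what} ids: {dup}")


@dataclass
class ExpressionMatrix:
    """log2 intensities, genes x samples, plus per-sample metadata.

    ``metadata`` is indexed by sample id and must carry at least the
    columns ``origin`` (e.g. ESC, iPSC, ESC-NSC, iPSC-NSC), ``background``
    (genetic background code) and ``batch`` (experiment code).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_ids(self.values.index, "gene")
        _check_ids(self.values.columns, "sample")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ConfigError("expression values must be finite")
        missing = self.values.columns.difference(self.metadata.index)
        if len(missing):
            raise ConfigError(f"metadata missing for samples: {list(missing)[:5]}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ConfigError(f"metadata lacks required column '{col}'")
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.metadata.loc[list(sample_ids)])


@dataclass
class MethylationMatrix:
    """Beta values in [0, 1], CpGs x samples, plus per-sample metadata."""

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_ids(self.values.index, "cpg")
        _check_ids(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ConfigError("beta values must lie in [0, 1]")
        missing = self.values.columns.difference(self.metadata.index)
        if len(missing):
            raise ConfigError(f"metadata missing for samples: {list(missing)[:5]}")
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.values[list(sample_ids)], self.metadata.loc[list(sample_ids)])


def validate_annotation(annotation: pd.DataFrame, allowed_chromosomes=CHROMOSOMES) -> pd.DataFrame:
    """Validate a feature annotation table (indexed by feature id).

    Requires unique ids, positions >= 1 and chromosomes from the declared
    set. Returns the table unchanged.
    """
    _check_ids(annotation.index, "feature")
    for col in ("chromosome", "position"):
        if col not in annotation.columns:
            raise ConfigError(f"annotation lacks required column '{col}'")
    if (annotation["position"] < 1).any():
        raise ConfigError("annotation positions must be >= 1")
    bad = set(annotation["chromosome"]) - set(allowed_chromosomes)
    if bad:
        raise ConfigError(f"unknown chromosomes in annotation: {sorted(bad)}")
    return annotation


@dataclass
class GroundTruth:
    """Planted effects returned alongside each simulated dataset."""

    x_cluster_intervals: list[tuple[int, int]] = field(default_factory=list)
    dm_cluster_intervals: list[tuple[int, int]] = field(default_factory=list)
    affected_genes: list[str] = field(default_factory=list)
    dm_cpgs: list[str] = field(default_factory=list)
    dm_directions: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "x_cluster_intervals": [list(t) for t in self.x_cluster_intervals],
            "dm_cluster_intervals": [list(t) for t in self.dm_cluster_intervals],
            "affected_genes": list(self.affected_genes),
            "dm_cpgs": list(self.dm_cpgs),
            "dm_directions": dict(self.dm_directions),
        }
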