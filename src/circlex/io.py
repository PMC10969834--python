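"""Readers and writers for the plain-text interchange formats.

Matrices travel as TSV with the feature id in the first column and one
column per sample; annotation as a 4-column TSV (feature_id, chromosome,
position, gene_symbol); gene sets as GMT; enriched windows as BED
(0-based half-open; internal coordinates are 1-based half-open).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ConfigError, validate_annotation


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return meta


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    ann.index = ann.index.astype(str)
    return validate_annotation(ann)


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = annotation.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def annotation_to_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write features as BED: 0-based half-open single-base intervals."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for fid, row in annotation.iterrows():
            start = int(row["position"]) - 1
            fh.write(f"{row['chromosome']}\t{start}\t{start + 1}\t{fid}\n")


def windows_to_bed(windows: pd.DataFrame, path: str | Path) -> None:
    """Write enriched scan windows as BED (1-based half-open -> 0-based)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for _, row in windows[windows["enriched"]].iterrows():
            fh.write(
                f"{row['chromosome']}\t{int(row['start']) - 1}\t{int(row['end']) - 1}\t"
                f"k={int(row['k'])};adj_p={row['adjusted_p']:.3g}\n"
            )


def read_bed_windows(path: str | Path) -> pd.DataFrame:
    """Read a windows BED back into the internal 1-based representation."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ConfigError(f"malformed BED line: {line!r}")
        rows.append(
            {
                "chromosome": parts[0],
                "start": int(parts[1]) + 1,
                "end": int(parts[2]) + 1,
                "enriched": True,
            }
        )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "enriched"])


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> symbol... (one set per line)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ConfigError(f"malformed GMT line (need name, desc, >=1 gene): {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_symbol_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
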