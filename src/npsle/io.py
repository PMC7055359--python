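"""File formats: TSV count matrices, CSV metadata/behavior tables, plain-text
gene lists, YAML/JSON configs. All readers validate shape and identifiers and
report the offending row/column on failure; writer/reader pairs round-trip
losslessly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .expression import CountMatrix
from .signatures import normalize_ids

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_gene_list",
    "write_gene_list",
    "read_behavior",
    "write_behavior",
    "read_config",
    "write_config",
]


def _check_missing(df: pd.DataFrame, path) -> None:
    if df.isna().any().any():
        mask = df.isna()
        row = mask.any(axis=1).idxmax()
        col = mask.loc[row].idxmax()
        raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")


def read_counts(path, metadata_path=None) -> CountMatrix | pd.DataFrame:
    """Read a gene x sample count TSV (gene rows, header of sample ids).

    With ``metadata_path`` (CSV with sample_id and group columns) a
    CountMatrix is returned; otherwise the bare DataFrame.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    _check_missing(df, path)
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns {non_numeric}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifiers {dups[:5]}")
    if metadata_path is None:
        return df
    groups = read_metadata(metadata_path)
    return CountMatrix(df, groups)


def write_counts(matrix, path) -> None:
    df = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="gene")


def read_metadata(path) -> pd.Series:
    """Sample metadata CSV with ``sample_id`` and ``group`` columns."""
    meta = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"{path}: metadata must have a {col!r} column")
    _check_missing(meta[["sample_id", "group"]], path)
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id entries")
    return pd.Series(meta["group"].values, index=meta["sample_id"].values, name="group")


def write_metadata(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, index=False
    )


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one identifier per line.

    Identifiers differing only by case are deduplicated with a warning; the
    first-seen spelling is kept.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = normalize_ids(ln for ln in lines if ln)
    return list(ids.values())


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_behavior(path) -> pd.DataFrame:
    """Behavior battery CSV: animal_id, group, one column per subtest."""
    df = pd.read_csv(path)
    if "animal_id" not in df.columns:
        raise ValueError(f"{path}: behavior table must have an 'animal_id' column")
    if df["animal_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate animal_id entries")
    df = df.set_index("animal_id")
    for col in df.columns:
        if col == "group":
            continue
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric subtest column {col!r}")
    return df


def write_behavior(battery: pd.DataFrame, path) -> None:
    battery.to_csv(path, index_label="animal_id")


def read_config(path) -> dict:
    """YAML or JSON configuration (by extension; YAML parses JSON too)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
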