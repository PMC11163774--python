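"""TSV/GMT/JSON file plumbing with schema validation and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_table_tsv",
    "write_table_tsv",
    "sha256_file",
    "write_manifest",
]

SAMPLE_ANNOTATION_COLUMNS = (
    "sample_id", "type", "ARID1A", "PIK3CA", "TP53", "ATM", "KRAS", "stage", "batch",
)
PROBE_ANNOTATION_COLUMNS = ("probe_id", "chrom", "pos", "region_class", "gene")
DEPENDENCY_COLUMNS = ("gene", "cell_line", "score", "source")


class SchemaError(ValueError):
    """An input file violating the expected schema; names file and column."""


def read_matrix_tsv(path, index_name: str = "id") -> pd.DataFrame:
    """Matrix TSV: first column = row ids, header row = sample/column ids."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: cannot parse as TSV matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: matrix has no data columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate row id {dup!r}")
    df.index.name = index_name
    return df


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_table_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    """Column-oriented TSV with a required-column check."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover
        raise SchemaError(f"{path}: cannot parse as TSV table: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def write_table_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    stage: str,
    params: Mapping,
    seed: int | None,
    inputs: Iterable = (),
    outputs: Iterable = (),
) -> None:
    """JSON manifest: stage name, parameters, seed, input hashes, outputs."""
    from . import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in dict(params).items()},
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(v):
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    if isinstance(v, Mapping):
        return {str(k): _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple, set)):
        return [_jsonable(x) for x in v]
    return str(v)
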