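"""Table I/O with schema validation, and run manifests.

All tables are tidy/long TSV or CSV with units encoded in column names
(``time_h``, ``conc_M``); manifests are JSON records of the parameters,
seed, package version and input checksums that produced an output, so any
deterministic result can be reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

__all__ = ["TableSchema", "read_table", "write_table", "write_manifest"]


@dataclass(frozen=True)
class TableSchema:
    """Column requirements for one table kind."""

    required: tuple[str, ...]
    numeric: tuple[str, ...] = ()
    optional: tuple[str, ...] = field(default_factory=tuple)


SCHEMAS: dict[str, TableSchema] = {
    "trace": TableSchema(("time_h", "od"), ("time_h", "od"), ("tube", "well", "dilution")),
    "growth_curve": TableSchema(("time_h", "od"), ("time_h", "od"), ("well",)),
    "cts": TableSchema(("sample_id", "primer_set", "ct"), ("ct",), ("replicate",)),
    "standards": TableSchema(
        ("primer_set", "log10_quantity", "ct"), ("log10_quantity", "ct"), ()
    ),
    "competition": TableSchema(
        ("channel", "timepoint", "count"), ("count",), ("assay_id", "control")
    ),
    "progress_curve": TableSchema(("time_s", "a340"), ("time_s", "a340"), ()),
    "rates": TableSchema(("conc_M", "rate"), ("conc_M", "rate"), ("replicate",)),
    "allosteric": TableSchema(("conc_M", "v_over_v0"), ("conc_M", "v_over_v0"), ("replicate",)),
}


def _delimiter(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(
    path: str | Path, schema: TableSchema | str | None = None, sep: str | None = None
) -> pd.DataFrame:
    """Read a TSV/CSV table and validate it against a schema.

    ``schema`` is a :class:`TableSchema` or the name of a registered one.
    Missing required columns raise with the column named; unparseable
    numerics raise with the first offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    df = pd.read_csv(path, sep=_delimiter(path, sep))
    if schema is not None:
        for col in schema.required:
            if col not in df.columns:
                raise ValueError(f"{path.name}: missing required column {col!r}")
        for col in schema.numeric:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # header + 1-based
                raise ValueError(
                    f"{path.name}: unparseable numeric in column {col!r} at line {row}"
                )
            df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str | None = None) -> Path:
    """Write a table as TSV (default) or CSV by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter(path, sep), index=False)
    return path


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_path: str | Path,
    parameters: Mapping[str, Any],
    seed: int | None = None,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write a JSON run manifest beside an output file."""
    from . import __version__

    out_path = Path(out_path)
    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": dict(parameters),
        "inputs": {str(p): sha256_file(p) for p in inputs if Path(p).exists()},
    }
    path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
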