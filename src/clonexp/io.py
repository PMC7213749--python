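"""Tab-separated interchange formats and flat-text configuration.

Count tables follow the clonotype-export convention of repertoire pipelines:
UTF-8 TSV with one header row (``clone_id``, ``count_1``, ``count_2``),
optional ``#``-prefixed metadata lines, one row per clonotype.  Foreign
headers are accommodated by a column-mapping option.  Configuration and fit
parameters round-trip through a flat ``key = <json>`` text format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import PairTable

__all__ = [
    "read_pair_table",
    "write_pair_table",
    "read_config",
    "write_config",
]

_COLUMNS = ("clone_id", "count_1", "count_2")


def read_pair_table(path, columns: dict | None = None) -> PairTable:
    """Read a clonotype count-pair TSV into a :class:`PairTable`.

    ``columns`` optionally maps the canonical names (``clone_id``,
    ``count_1``, ``count_2``) to the file's actual header names.  Rows with
    both counts zero, negative or non-integer counts, and duplicate clone
    ids are rejected with the offending line identified.
    """
    path = Path(path)
    mapping = {name: name for name in _COLUMNS}
    if columns:
        mapping.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [v for v in mapping.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; found {list(df.columns)}")
    df = df.rename(columns={v: k for k, v in mapping.items()})

    for col in ("count_1", "count_2"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != np.floor(converted))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: malformed {col} value {df[col].iloc[row]!r} at data row {row + 1}"
            )
        if (converted < 0).any():
            row = int(np.flatnonzero((converted < 0).to_numpy())[0])
            raise ValueError(f"{path}: negative count at data row {row + 1}")
        df[col] = converted.astype(np.int64)

    zero = (df["count_1"] + df["count_2"]) == 0
    if zero.any():
        row = int(np.flatnonzero(zero.to_numpy())[0])
        raise ValueError(
            f"{path}: row {row + 1} has count_1 = count_2 = 0; pair tables hold "
            "observed clones only (every row needs n + n' > 0)"
        )
    if df["clone_id"].duplicated().any():
        dup = df["clone_id"][df["clone_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate clone_id {dup!r}")
    return PairTable(df["clone_id"].to_numpy(object), df["count_1"].to_numpy(), df["count_2"].to_numpy())


def write_pair_table(table: PairTable, path, metadata: dict | None = None) -> None:
    """Write a :class:`PairTable` as TSV with optional ``#`` metadata lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        meta = dict(metadata or {})
        meta.setdefault("n_reads_1", table.n_reads[0])
        meta.setdefault("n_reads_2", table.n_reads[1])
        for key, value in meta.items():
            fh.write(f"# {key} = {json.dumps(value)}\n")
        out = table.df.rename(columns={"n": "count_1", "n_prime": "count_2"})
        out.to_csv(fh, sep="\t", index=False)


def write_config(config: dict, path) -> None:
    """Serialize a flat key-value mapping as ``key = <json>`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in config.items():
            if isinstance(value, (np.floating, np.integer)):
                value = value.item()
            fh.write(f"{key} = {json.dumps(value)}\n")


def read_config(path) -> dict:
    """Parse a ``key = <json>`` configuration file (lossless round-trip)."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: malformed config line {lineno}: {line!r}")
            key, _, raw = line.partition("=")
            out[key.strip()] = json.loads(raw.strip())
    return out
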