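"""Shared TSV/JSON I/O and run provenance."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_matrix_tsv", "write_matrix_tsv", "write_provenance"]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labeled numeric matrix from TSV, validating rectangularity.

    Raises a descriptive error naming the first offending line for
    ragged rows or non-numeric cells.  Mixed line endings are accepted.
    """
    path = Path(path)
    lines = path.read_text().replace("\r\n", "\n").replace("\r", "\n")
    rows = [ln.split("\t") for ln in lines.split("\n") if ln.strip() != ""]
    if len(rows) < 2:
        raise ValueError(f"{path}: need a header and at least one data row")
    width = len(rows[0])
    for k, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(
                f"{path}: line {k} has {len(row)} fields, expected {width}"
            )
    header = rows[0][1:]
    index, data = [], []
    for k, row in enumerate(rows[1:], start=2):
        index.append(row[0])
        try:
            data.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {k}: {exc}") from None
    return pd.DataFrame(data, index=index, columns=header)


def write_matrix_tsv(
    df: pd.DataFrame | np.ndarray, path: str | Path
) -> None:
    if isinstance(df, np.ndarray):
        df = pd.DataFrame(
            df,
            index=[f"r{i}" for i in range(df.shape[0])],
            columns=[f"c{j}" for j in range(df.shape[1])],
        )
    df.to_csv(path, sep="\t")


def write_provenance(path: str | Path, config: dict, seed: int) -> None:
    """Record run configuration, seed and package version next to outputs."""
    from . import __version__

    payload = {
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "python": platform.python_version(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
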