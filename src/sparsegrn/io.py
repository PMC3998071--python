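"""Expression-matrix I/O and run configuration."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["ExpressionFormatError", "read_expression", "write_expression", "load_config"]

log = logging.getLogger("sparsegrn")


class ExpressionFormatError(ValueError):
    """Raised on malformed expression files."""


def _delimiter(path) -> str:
    suffix = Path(path).suffix.lower()
    return "\t" if suffix in {".tsv", ".tab", ".txt"} else ","


def read_expression(path) -> tuple[np.ndarray, list[str]]:
    """Read a K-by-n expression matrix (header row = gene names).

    Delimiter is inferred from the extension (.tsv/.tab/.txt = tab, else
    comma).  Requires at least 2 numeric data rows.
    """
    sep = _delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, header=0)
    except pd.errors.ParserError as exc:
        raise ExpressionFormatError(f"could not parse {path}: {exc}") from exc
    if df.shape[0] < 2:
        raise ExpressionFormatError(
            f"{path}: need at least 2 time points, found {df.shape[0]}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ExpressionFormatError(
            f"{path}: non-numeric or missing value at data row {r}, "
            f"column {df.columns[c]!r}"
        )
    genes = [str(c) for c in df.columns]
    Y = numeric.to_numpy(dtype=float)
    log.info("read expression matrix: K=%d time points, n=%d genes", *Y.shape)
    return Y, genes


def write_expression(path, Y: np.ndarray, genes: Optional[Sequence[str]] = None) -> None:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    genes = list(genes) if genes is not None else [f"g{i+1}" for i in range(Y.shape[1])]
    pd.DataFrame(Y, columns=genes).to_csv(path, sep=_delimiter(path), index=False)


def load_config(path) -> dict:
    """Load algorithm settings from a YAML or JSON file."""
    text = Path(path).read_text()
    if Path(path).suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
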