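"""Readers for lifetime data files.

Two dialects: plain text (one value per row, or several whitespace-
separated values per row) and CSV with a named column.  Non-positive or
unparseable rows are dropped with a warning, or rejected outright under
``strict=True``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .sample import LifetimeSample

__all__ = ["read_lifetimes"]

logger = logging.getLogger("wextropy")


def read_lifetimes(path, column: str | None = None, strict: bool = False) -> LifetimeSample:
    """Read a positive lifetime sample from a text or CSV file.

    Parameters
    ----------
    path : path-like
    column : str, optional
        When given, the file is parsed as CSV (header row required) and
        the named column is used.
    strict : bool
        Reject the file if any row is unparseable or non-positive instead
        of dropping such rows.
    """
    path = Path(path)
    if not path.exists():
        raise DomainError(f"no such file: {path}")

    if column is not None:
        frame = pd.read_csv(path)
        if column not in frame.columns:
            raise DomainError(f"column {column!r} not found in {path}")
        raw = pd.to_numeric(frame[column], errors="coerce").to_numpy(dtype=float)
    else:
        tokens: list[str] = []
        for line in path.read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.replace(",", " ").split())
        raw = np.array([_parse(t) for t in tokens], dtype=float)

    if raw.size == 0:
        raise DomainError(f"{path} contains no data")
    bad = ~np.isfinite(raw) | (raw <= 0)
    n_bad = int(bad.sum())
    if n_bad:
        if strict:
            raise DomainError(
                f"{path}: {n_bad} row(s) are non-positive or unparseable"
            )
        logger.warning("%s: dropped %d non-positive/unparseable row(s)", path, n_bad)
    values = raw[~bad]
    if values.size == 0:
        raise DomainError(f"{path}: no positive values remain after validation")
    return LifetimeSample(values)


def _parse(token: str) -> float:
    try:
        # tolerate unicode minus from copy-pasted tables
        return float(token.replace("−", "-"))
    except ValueError:
        return float("nan")
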