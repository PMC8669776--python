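"""Reading p-value inputs and writing result tables.

Inputs are plain text (one p-value per line) or delimited CSV/TSV with a
named column; ``NA`` tokens and empty fields are treated as missing and
handled by the set's NA policy.  Result tables are written with the method,
threshold and pi0 recorded as commented header lines, so a file is
self-describing and round-trips losslessly through :func:`read_results`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .adjust import FDRResult
from .transforms import RawPValueSet

__all__ = ["read_pvalues", "write_results", "read_results"]

_NA_TOKENS = {"", "NA", "NaN", "nan", "na"}


def read_pvalues(
    path,
    column: str | None = None,
    na_policy: str = "remove",
    ties_method: str = "random",
    tie_seed: int | None = None,
) -> RawPValueSet:
    """Read raw p-values from a text or delimited file.

    Without ``column`` the file is read as one value per line; with it, the
    file is parsed as CSV (TSV for ``.tsv``/``.tab``) and that column is
    used.  Parse and range errors name the offending line.
    """
    path = os.fspath(path)
    if column is not None:
        sep = "\t" if path.endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep)
        if column not in df.columns:
            raise ValueError(f"column {column!r} not found in {path}; has {list(df.columns)}")
        vals = pd.to_numeric(df[column], errors="coerce").to_numpy(dtype=float)
        raw_na = df[column].isna().to_numpy()
        unparseable = np.isnan(vals) & ~raw_na
        if unparseable.any():
            row = int(np.flatnonzero(unparseable)[0])
            raise ValueError(
                f"{path}: unparseable value {df[column].iloc[row]!r} in column "
                f"{column!r} at data row {row + 1}"
            )
        bad = (~np.isnan(vals)) & ((vals < 0.0) | (vals > 1.0))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: p-value out of [0, 1] at data row {row + 1}: {vals[row]!r}"
            )
        return RawPValueSet(vals, na_policy=na_policy, ties_method=ties_method, tie_seed=tie_seed)

    vals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if tok in _NA_TOKENS:
                vals.append(np.nan)
                continue
            try:
                v = float(tok)
            except ValueError:
                raise ValueError(f"{path}: unparseable value {tok!r} on line {lineno}") from None
            if not np.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}: p-value out of [0, 1] on line {lineno}: {v!r}")
            vals.append(v)
    return RawPValueSet(
        np.asarray(vals, dtype=float),
        na_policy=na_policy,
        ties_method=ties_method,
        tie_seed=tie_seed,
    )


def write_results(
    result: FDRResult,
    path,
    fmt: str = "csv",
    sort_results: bool = False,
    just_fdr: bool = False,
) -> None:
    """Write an :class:`FDRResult` as a delimited table with a metadata header.

    Columns (in order): feature, raw_p, adjusted_p, fdr, lower_bound_fdr (when
    present), reject.  ``sort_results`` orders rows by the FDR column;
    ``just_fdr`` writes the FDR vector alone.  Numbers are written at full
    precision.
    """
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"format must be 'csv' or 'tsv', got {fmt!r}")
    sep = "," if fmt == "csv" else "\t"
    df = result.to_frame(sort_results=sort_results, just_fdr=just_fdr)
    with open(path, "w") as fh:
        fh.write(f"# method: {result.method}\n")
        fh.write(f"# threshold: {result.threshold!r}\n")
        fh.write(f"# pi0: {result.pi0!r}\n")
        fh.write(f"# pi0_method: {result.pi0_method}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_results(path, fmt: str = "csv") -> pd.DataFrame:
    """Read back a table written by :func:`write_results` (header skipped)."""
    sep = "," if fmt == "csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#")
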