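"""Delimited-text reading and writing for series.

Two layouts are supported:

* ``columns`` -- one column per univariate series, header row of labels
  (CSV or TSV);
* ``features`` -- a feature-by-time table, feature IDs in the first
  column (one multivariate series per file).

Missing values are encoded as empty cells or ``NA`` and become NaN; the
test engines refuse series with NaNs until gaps are filled. Floats are
written with 17 significant digits so a write/read round trip is exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TTSError
from .series import Series


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "tsv"):
            raise TTSError(f"unknown format {fmt!r}")
        return "," if fmt == "csv" else "\t"
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_series(
    path, column: str | None = None, layout: str = "columns", fmt: str | None = None
) -> Series:
    """Read one series from a delimited file.

    With ``layout="columns"``, ``column`` selects which column (default:
    the first). With ``layout="features"`` the whole table becomes one
    multivariate series.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    try:
        if layout == "columns":
            df = pd.read_csv(
                path, sep=sep, na_values=["NA", ""], float_precision="round_trip",
                skip_blank_lines=False,
            )
            name = column if column is not None else df.columns[0]
            if name not in df.columns:
                raise TTSError(f"no column {name!r} in {path.name}")
            vals = pd.to_numeric(df[name], errors="raise").to_numpy(dtype=float)
            return Series(vals, label=str(name))
        if layout == "features":
            df = pd.read_csv(
                path, sep=sep, na_values=["NA", ""], index_col=0,
                float_precision="round_trip",
            )
            vals = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
            return Series(
                vals,
                label=path.stem,
                feature_ids=tuple(str(i) for i in df.index),
            )
        raise TTSError(f"unknown layout {layout!r}")
    except (pd.errors.ParserError, ValueError) as exc:
        raise TTSError(f"could not parse {path}: {exc}") from exc


def write_series(s: Series, path, fmt: str | None = None) -> None:
    """Write a series; univariate as one labelled column, multivariate as
    a feature-by-time table."""
    path = Path(path)
    sep = _sep_for(path, fmt)
    if s.is_univariate:
        df = pd.DataFrame({s.label or "value": s.as_1d()})
        df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    else:
        df = pd.DataFrame(
            s.values,
            index=pd.Index(s.feature_ids, name="feature"),
            columns=[f"t{i}" for i in range(s.n)],
        )
        df.to_csv(path, sep=sep, float_format="%.17g")


def write_pair(x: Series, y: Series, path, fmt: str | None = None) -> None:
    """Write two univariate series side by side with a time column."""
    path = Path(path)
    sep = _sep_for(path, fmt)
    df = pd.DataFrame(
        {
            "time": np.arange(x.n),
            x.label or "x": x.as_1d(),
            y.label or "y": y.as_1d(),
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
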