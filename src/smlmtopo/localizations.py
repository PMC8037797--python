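"""Localization tables: the in-memory container for SMLM point data.

A single-molecule localization microscopy (SMLM) acquisition yields one row
per registered blink event: the camera frame it appeared in, its fitted
position (nm), the localization precision of the fit (nm), and the colour
channel.  Everything downstream — distance histograms, cluster detection,
persistence barcodes — consumes this table, so it is the package's central
data structure.  Coordinates are 2D (the analyses operate on projections),
in nanometres, origin at the field corner with y increasing upward.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Mandatory columns of a localization table, in canonical order.
COLUMNS = ("frame", "x_nm", "y_nm", "precision_nm", "channel")


class FormatError(ValueError):
    """Raised when a localization file violates the expected table layout."""


@dataclass
class LocalizationTable:
    """Per-event localization records for one nucleus / field of view.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain the columns ``frame, x_nm, y_nm, precision_nm, channel``.
        Extra columns are preserved untouched.
    meta : dict
        Free-form per-table metadata (nucleus id, field spec, provenance).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        xy = self.data[["x_nm", "y_nm"]].to_numpy(dtype=float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise FormatError("non-finite coordinates in localization table")
        prec = self.data["precision_nm"].to_numpy(dtype=float)
        if prec.size and not np.all(prec > 0):
            raise FormatError("localization precision must be positive")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of coordinates in nm."""
        return self.data[["x_nm", "y_nm"]].to_numpy(dtype=float)

    def subset(self, index) -> "LocalizationTable":
        """Row subset (positional indices or boolean mask) as a new table."""
        return LocalizationTable(self.data.iloc[np.asarray(index)].reset_index(drop=True),
                                 dict(self.meta))

    @classmethod
    def from_arrays(cls, x_nm, y_nm, *, frame=None, precision_nm=10.0,
                    channel="A", meta=None) -> "LocalizationTable":
        """Build a table from coordinate arrays, filling defaults elsewhere."""
        x = np.asarray(x_nm, dtype=float).ravel()
        y = np.asarray(y_nm, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        n = x.size
        df = pd.DataFrame({
            "frame": np.zeros(n, dtype=int) if frame is None else np.asarray(frame),
            "x_nm": x,
            "y_nm": y,
            "precision_nm": np.broadcast_to(np.asarray(precision_nm, dtype=float), n).copy(),
            "channel": np.broadcast_to(np.asarray(channel, dtype=object), n).copy(),
        })
        return cls(df, meta or {})


def read_localizations(path, *, sep=None, column_map=None) -> LocalizationTable:
    """Read a delimited-text localization table.

    Comma- or tab-delimited with a mandatory header; lines starting with
    ``#`` are comments.  ``column_map`` renames foreign column names onto the
    canonical ones, e.g. ``{"x [nm]": "x_nm"}`` for ThunderSTORM-style
    exports.  Missing mandatory columns raise :class:`FormatError` naming the
    column; a non-numeric coordinate raises an error citing the line number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw_lines = fh.readlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw_lines)
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise FormatError(f"{path}: no header line found")
    header_lineno, header = lines[0]
    if sep is None:
        sep = "\t" if "\t" in header else ","
    text = "".join(ln for _, ln in lines)
    try:
        df = pd.read_csv(_io.StringIO(text), sep=sep, dtype={"channel": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse table: {exc}") from exc
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ("x_nm", "y_nm", "precision_nm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size:
            # +1 for the header row of the parsed block; report the file line
            lineno = lines[1 + bad[0]][0] if 1 + bad[0] < len(lines) else header_lineno
            raise FormatError(f"{path}: non-numeric value in column '{col}' at line {lineno}")
        if coerced.isna().any():
            raise FormatError(f"{path}: missing value in column '{col}'")
        df[col] = coerced
    return LocalizationTable(df, {"path": str(path)})


def write_localizations(table: LocalizationTable, path, *, sep=",") -> None:
    """Write a table as delimited text with a small comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# smlmtopo localization table; coordinates in nm,"
                 " origin at field corner, y up\n")
        for k, v in table.meta.items():
            if isinstance(v, (str, int, float, bool)):
                fh.write(f"# {k}: {v}\n")
        table.data.to_csv(fh, sep=sep, index=False)


def write_labels(labels, path, *, sep=",") -> None:
    """Write ground-truth event labels as `event_index,label` sidecar text."""
    labels = np.asarray(labels)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("event_index" + sep + "label\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i}{sep}{lab}\n")


def read_labels(path, *, sep=",") -> np.ndarray:
    df = pd.read_csv(path, sep=sep, comment="#")
    return df["label"].to_numpy()
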