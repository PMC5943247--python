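"""Reading and writing localization tables.

Three CSV dialects are supported:

* ``native`` — this package's own format, header
  ``x_nm,y_nm,frame,sigma_nm,intensity`` (the two optional columns are
  omitted when absent). Coordinates are written with 1e-4 nm precision so
  a write -> read round trip is exact and idempotent.
* ``thunderstorm`` — ThunderSTORM export, headers like ``"frame"``,
  ``"x [nm]"``, ``"y [nm]"``, ``"uncertainty [nm]"``,
  ``"intensity [photon]"``; units already nm.
* ``quickpalm`` — QuickPALM-style particle table with pixel-unit columns
  (``X (px)``, ``Y (px)``, ``Frame Number``, ``Intensity``); requires a
  ``pixel_size`` (nm per camera pixel) to convert to nm.

Dialect auto-detection is by exact header match only; a header matching
no known dialect (or more than one) raises rather than guessing, and an
explicit ``column_map`` always wins.
"""

from __future__ import annotations

import os
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .table import LocalizationTable, CANONICAL_COLUMNS, OPTIONAL_COLUMNS

NATIVE_COLUMNS = {"x": "x_nm", "y": "y_nm", "frame": "frame",
                  "sigma": "sigma_nm", "intensity": "intensity"}

# canonical name -> known header spellings, per dialect
DIALECTS: Dict[str, Dict[str, str]] = {
    "native": NATIVE_COLUMNS,
    "thunderstorm": {"x": "x [nm]", "y": "y [nm]", "frame": "frame",
                     "sigma": "uncertainty [nm]", "intensity": "intensity [photon]"},
    "quickpalm": {"x": "X (px)", "y": "Y (px)", "frame": "Frame Number",
                  "intensity": "Intensity"},
}

# dialects whose coordinates are in camera pixels, not nm
PIXEL_UNIT_DIALECTS = {"quickpalm"}

_PRECISION = 4  # decimal places (nm) in native output; 1e-4 nm = 0.1 pm


class FormatError(ValueError):
    """A file does not conform to the requested or detected dialect."""


def detect_dialect(columns) -> str:
    """Identify the dialect from a header; ambiguity or no match raises."""
    cols = set(columns)
    hits = [name for name, cmap in DIALECTS.items()
            if {cmap["x"], cmap["y"], cmap["frame"]} <= cols]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise FormatError(
            f"header {sorted(cols)} matches no known dialect; "
            "pass dialect= or column_map= explicitly")
    raise FormatError(
        f"header matches several dialects {hits}; pass dialect= explicitly")


def read_localizations(
    path,
    dialect: Optional[str] = None,
    frame_time: float = 0.06,
    pixel_size: Optional[float] = None,
    column_map: Optional[Dict[str, str]] = None,
    sep: str = ",",
) -> LocalizationTable:
    """Read a localization CSV into a :class:`LocalizationTable`.

    Parameters
    ----------
    dialect
        One of ``native``, ``thunderstorm``, ``quickpalm``; auto-detected
        from the header when omitted and no ``column_map`` is given.
    frame_time
        Seconds per camera frame; detection times derive from it.
    pixel_size
        nm per camera pixel; mandatory for pixel-unit dialects.
    column_map
        Explicit mapping from canonical names (``x``, ``y``, ``frame``,
        optionally ``sigma``, ``intensity``) to file headers; overrides
        dialect detection. Units are taken to be nm unless ``pixel_size``
        is supplied, in which case x/y are converted from pixels.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep=sep, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no header line")
    raw.columns = [str(c).strip().strip('"') for c in raw.columns]

    in_pixels = False
    if column_map is not None:
        cmap = dict(column_map)
        in_pixels = pixel_size is not None
        dialect = dialect or "native"
    else:
        if dialect is None:
            dialect = detect_dialect(raw.columns)
        if dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {dialect!r}")
        cmap = DIALECTS[dialect]
        in_pixels = dialect in PIXEL_UNIT_DIALECTS

    for canon in ("x", "y", "frame"):
        if canon not in cmap or cmap[canon] not in raw.columns:
            raise FormatError(
                f"{path}: mandatory column {cmap.get(canon, canon)!r} "
                f"({canon}) not found in header")
    if in_pixels and pixel_size is None:
        raise ValueError(f"dialect {dialect!r} stores pixel units; pixel_size is required")

    out = pd.DataFrame()
    used = []
    for canon in CANONICAL_COLUMNS:
        header = cmap.get(canon)
        if header is None or header not in raw.columns:
            continue
        col = raw[header]
        try:
            col = pd.to_numeric(col)
        except (ValueError, TypeError) as exc:
            bad = col[pd.to_numeric(col, errors="coerce").isna() & col.notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value in column {header!r} at line {line}") from exc
        out[canon] = col
        used.append(header)
    if in_pixels:
        out["x"] = out["x"] * pixel_size
        out["y"] = out["y"] * pixel_size
        if "sigma" in out.columns:
            out["sigma"] = out["sigma"] * pixel_size
    # extra columns ride along untouched
    for header in raw.columns:
        if header not in used:
            out[header] = raw[header]
    out["frame"] = out["frame"].astype(np.int64)
    return LocalizationTable(out, frame_time=frame_time, pixel_size=pixel_size,
                             source_dialect=dialect or "native")


def write_localizations(table: LocalizationTable, path) -> None:
    """Write the native-dialect CSV.

    Only canonical columns present in the table are written (unknown
    extras are dropped); floats are quantized to 1e-4 nm so that
    ``read(write(t))`` equals ``t`` exactly for tables at that precision.
    """
    cols, header = [], []
    for canon in CANONICAL_COLUMNS:
        if canon in ("x", "y", "frame") or canon in table.data.columns:
            cols.append(canon)
            header.append(NATIVE_COLUMNS[canon])
    df = table.data[cols].copy()
    df.columns = header
    df.to_csv(path, index=False, float_format=f"%.{_PRECISION}f")
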