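"""The localization table: one record per single-molecule detection.

A :class:`LocalizationTable` is the universal currency of the toolkit. It
wraps a :class:`pandas.DataFrame` with the canonical columns

=========== ======================================================
``x``       position, nm
``y``       position, nm
``frame``   1-based camera frame index
``sigma``   localization uncertainty, nm (optional)
``intensity`` photon count (optional)
=========== ======================================================

plus acquisition metadata (``frame_time`` in seconds per frame and,
where relevant, the camera ``pixel_size`` in nm). Detection times are
derived, ``t = (frame - 1) * frame_time``, with time zero at the start
of frame 1. Unknown extra columns survive a read but are dropped on
native write.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ("x", "y", "frame", "sigma", "intensity")
OPTIONAL_COLUMNS = ("sigma", "intensity")


@dataclass
class LocalizationTable:
    data: pd.DataFrame
    frame_time: float = 0.06
    pixel_size: Optional[float] = None
    source_dialect: str = "native"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        for col in ("x", "y", "frame"):
            if col not in self.data.columns:
                raise ValueError(f"localization table is missing mandatory column {col!r}")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        df = self.data
        if len(df):
            x = df["x"].to_numpy(float)
            y = df["y"].to_numpy(float)
            if not (np.isfinite(x).all() and np.isfinite(y).all()):
                raise ValueError("x and y must be finite")
            frames = df["frame"].to_numpy()
            if (frames < 1).any():
                raise ValueError("frame indices must be >= 1 (1-based)")
            if "sigma" in df.columns and not (df["sigma"].to_numpy(float) > 0).all():
                raise ValueError("sigma must be positive where present")
        self.data = df.reset_index(drop=True)
        self.data["frame"] = self.data["frame"].astype(np.int64)

    # -- accessors -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(float)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def frame(self) -> np.ndarray:
        return self.data["frame"].to_numpy(np.int64)

    @property
    def t(self) -> np.ndarray:
        """Detection times in seconds, zero at the start of frame 1."""
        return (self.frame - 1) * self.frame_time

    @property
    def sigma(self) -> Optional[np.ndarray]:
        if "sigma" in self.data.columns:
            return self.data["sigma"].to_numpy(float)
        return None

    @property
    def intensity(self) -> Optional[np.ndarray]:
        if "intensity" in self.data.columns:
            return self.data["intensity"].to_numpy(float)
        return None

    def with_data(self, data: pd.DataFrame) -> "LocalizationTable":
        return replace(self, data=data.reset_index(drop=True))

    def equals(self, other: "LocalizationTable") -> bool:
        """Field-by-field equality including metadata and column set."""
        if self.frame_time != other.frame_time:
            return False
        a, b = self.data, other.data
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        return bool(a.reset_index(drop=True).equals(b.reset_index(drop=True)))


def crop_roi(table: LocalizationTable, roi) -> LocalizationTable:
    """Keep records whose (x, y) lie inside ``roi``.

    Record order and all metadata are preserved; an empty result is valid.
    """
    if len(table) == 0:
        return table.with_data(table.data)
    mask = roi.contains(table.x, table.y)
    return table.with_data(table.data.loc[np.asarray(mask, bool)])


def filter_localizations(
    table: LocalizationTable,
    max_sigma: Optional[float] = None,
    frame_range: Optional[Tuple[int, int]] = None,
    min_intensity: Optional[float] = None,
) -> Tuple[LocalizationTable, int]:
    """Quality-control filter; returns (filtered table, number removed).

    Records failing any supplied criterion are removed; with no criteria
    supplied this is the identity. All thresholds are inclusive bounds.
    """
    for name, v in (("max_sigma", max_sigma), ("min_intensity", min_intensity)):
        if v is not None and v < 0:
            raise ValueError(f"{name} must be nonnegative")
    mask = np.ones(len(table), dtype=bool)
    if max_sigma is not None:
        if table.sigma is None:
            raise ValueError("max_sigma filter requires a sigma column")
        mask &= table.sigma <= max_sigma
    if frame_range is not None:
        lo, hi = frame_range
        mask &= (table.frame >= lo) & (table.frame <= hi)
    if min_intensity is not None:
        if table.intensity is None:
            raise ValueError("min_intensity filter requires an intensity column")
        mask &= table.intensity >= min_intensity
    removed = int((~mask).sum())
    return table.with_data(table.data.loc[mask]), removed
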