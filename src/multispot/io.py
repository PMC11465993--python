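"""Format I/O: ThunderSTORM-dialect localization CSV, TIFF stacks, configs.

The localization dialect uses the header
``frame,"x [nm]","y [nm]","sigma [nm]","intensity [photon]"``; recognized
columns are mapped to internal names (``x_nm``, ``y_nm``, ...) and any
extra columns are carried through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "LocalizationTable",
    "read_localizations",
    "write_localizations",
    "read_stack",
    "write_stack",
]

# ThunderSTORM column name <-> internal name
_DIALECT = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "sigma [nm]": "sigma_nm",
    "intensity [photon]": "photons",
    "id": "spot",
}
_REVERSE = {v: k for k, v in _DIALECT.items()}
_MANDATORY = ("frame", "x_nm", "y_nm")


@dataclass
class LocalizationTable:
    """Frame-indexed emitter coordinates in nm.

    Thin wrapper around a DataFrame with at least ``frame``, ``x_nm``,
    ``y_nm`` columns; coordinates must be finite and frame indices >= 0.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["frame", "x_nm", "y_nm"]))

    def __post_init__(self) -> None:
        for col in _MANDATORY:
            if col not in self.df.columns:
                raise ValueError(f"localization table missing column {col!r}")
        if len(self.df):
            if not np.all(np.isfinite(self.df[["x_nm", "y_nm"]].to_numpy(dtype=float))):
                raise ValueError("coordinates must be finite")
            if (self.df["frame"] < 0).any():
                raise ValueError("frame indices must be >= 0")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "LocalizationTable":
        if not rows:
            return cls()
        return cls(pd.DataFrame(rows))

    def __len__(self) -> int:
        return len(self.df)

    def coords(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm"]].to_numpy(dtype=float)


def read_localizations(path) -> LocalizationTable:
    """Read a ThunderSTORM-dialect CSV; unknown columns are preserved."""
    df = pd.read_csv(path)
    df = df.rename(columns={c: _DIALECT.get(c, c) for c in df.columns})
    missing = [m for m in _MANDATORY if m not in df.columns]
    if missing:
        names = ", ".join(_REVERSE.get(m, m) for m in missing)
        raise ValueError(f"localization file {path} missing mandatory column(s): {names}")
    return LocalizationTable(df)


def write_localizations(table: LocalizationTable, path) -> None:
    """Write a localization table using ThunderSTORM column headers."""
    df = table.df.rename(columns={c: _REVERSE.get(c, c) for c in table.df.columns})
    df.to_csv(path, index=False)


def read_stack(path) -> np.ndarray:
    """Read a (multi-page) TIFF as a (n_frames, h, w) float array."""
    arr = tifffile.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(frames, path) -> None:
    """Write an image sequence as a multi-page float32 TIFF."""
    arr = np.asarray(frames, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    tifffile.imwrite(path, arr)


def load_yaml(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    return data or {}


def dump_yaml(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
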