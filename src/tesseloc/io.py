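"""Reading and writing localization tables.

Localization tables are delimited text files with one localization per
row.  Coordinates are always interpreted in nanometres.  Recognized
column headers (case-insensitive) are ``x``, ``y``, ``z``, ``frame`` and
``intensity``, plus the ThunderSTORM variants ``x [nm]``, ``y [nm]``,
``z [nm]`` and ``frame``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: canonical name -> regex matching accepted header spellings (lowercased)
_HEADER_PATTERNS = {
    "x": r"^x(\s*\[nm\])?$",
    "y": r"^y(\s*\[nm\])?$",
    "z": r"^z(\s*\[nm\])?$",
    "frame": r"^frame$",
    "intensity": r"^(intensity(\s*\[photon[s]?\])?|photons)$",
}


@dataclasses.dataclass
class LocalizationSet:
    """One channel's localization point cloud.

    Parameters
    ----------
    coords
        Array of shape ``(n, dim)`` with coordinates in nm; ``dim`` is 2
        or 3.
    frames
        Optional per-localization acquisition frame index (non-negative
        integers).
    channel_id
        Short label identifying the channel (e.g. ``"A"``).
    """

    coords: np.ndarray
    frames: Optional[np.ndarray] = None
    channel_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise FormatError(
                f"coords must have shape (n, 2) or (n, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("coordinates must all be finite")
        if self.frames is not None:
            self.frames = np.asarray(self.frames)
            if self.frames.shape != (self.n,):
                raise FormatError("frames must have one entry per localization")
            if np.any(self.frames < 0):
                raise FormatError("frame indices must be non-negative")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def drop_duplicates(self) -> "LocalizationSet":
        """Return a copy without exact duplicate coordinate rows.

        Duplicate seeds make the Voronoi diagram degenerate, so they are
        removed (keeping the first occurrence, preserving row order)
        before tessellation.  A warning is logged when rows are dropped.
        """
        _, first = np.unique(self.coords, axis=0, return_index=True)
        if first.size == self.n:
            return self
        keep = np.sort(first)
        logger.warning(
            "channel %r: dropped %d exact duplicate localization(s)",
            self.channel_id,
            self.n - keep.size,
        )
        frames = self.frames[keep] if self.frames is not None else None
        return LocalizationSet(self.coords[keep], frames, self.channel_id)

    def transformed(self, coords: np.ndarray) -> "LocalizationSet":
        """Copy with new coordinates, keeping frames and channel tag."""
        return LocalizationSet(coords, self.frames, self.channel_id)


def _canonical_columns(columns) -> dict:
    mapping = {}
    for col in columns:
        low = str(col).strip().lower().replace('"', "")
        for name, pat in _HEADER_PATTERNS.items():
            if re.match(pat, low):
                mapping.setdefault(name, col)
                break
    return mapping


def read_localizations(
    path, dialect: str = "auto", channel_id: str = ""
) -> LocalizationSet:
    """Read a delimited-text localization table.

    Parameters
    ----------
    path
        Input file.  Delimiter (comma, tab or semicolon) is sniffed
        automatically; decimal separator must be a point.
    dialect
        ``"auto"``, ``"xyz-csv"`` or ``"thunderstorm"``.  All dialects
        share the same case-insensitive header matching, so the value is
        informational.
    channel_id
        Label stored on the returned set.

    Returns
    -------
    LocalizationSet
        Dimensionality is 3 when a ``z`` column is present, else 2.
    """
    if dialect not in ("auto", "xyz-csv", "thunderstorm"):
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = max(",;\t", key=header.count)
    # round_trip parsing keeps coordinates bit-exact through write/read
    df = pd.read_csv(path, sep=sep, skipinitialspace=True,
                     float_precision="round_trip")
    mapping = _canonical_columns(df.columns)
    for required in ("x", "y"):
        if required not in mapping:
            raise FormatError(
                f"{path}: missing required column {required!r} "
                f"(found: {list(df.columns)})"
            )
    names = ["x", "y"] + (["z"] if "z" in mapping else [])
    cols = []
    for name in names:
        raw = df[mapping[name]]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column "
                f"{mapping[name]!r}, data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise FormatError(f"{path}: empty cell in column {mapping[name]!r}, data row {row}")
        cols.append(numeric.to_numpy(dtype=float))
    coords = np.column_stack(cols)
    frames = None
    if "frame" in mapping:
        frames = pd.to_numeric(df[mapping["frame"]], errors="coerce")
        if frames.isna().any():
            row = int(np.flatnonzero(frames.isna().to_numpy())[0])
            raise FormatError(f"{path}: bad frame value at data row {row}")
        frames = frames.to_numpy(dtype=np.int64)
    return LocalizationSet(coords, frames, channel_id)


def write_localizations(locs: LocalizationSet, path) -> None:
    """Write a :class:`LocalizationSet` as a plain CSV (x, y[, z][, frame])."""
    cols = {"x": locs.coords[:, 0], "y": locs.coords[:, 1]}
    if locs.dim == 3:
        cols["z"] = locs.coords[:, 2]
    if locs.frames is not None:
        cols["frame"] = locs.frames
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_result(result, labels, out_prefix) -> tuple[Path, Path]:
    """Write an analysis run to ``<prefix>.summary.json`` and ``<prefix>.locs.csv``.

    The JSON summary holds the four coefficients, the five-class counts
    and the run parameters; the CSV holds one row per localization of
    both channels with its class label and pair-density coordinates.
    Coordinates round-trip losslessly through :func:`read_localizations`.

    Returns the two paths written.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    summary_path = out_prefix.with_suffix(".summary.json")
    table_path = out_prefix.with_suffix(".locs.csv")

    summary = result.summary_dict()
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")

    frames = []
    for tag, locs, own, partner, lab in (
        ("A", result.locs_A, labels.x_A, labels.y_A, labels.labels_A),
        ("B", result.locs_B, labels.y_B, labels.x_B, labels.labels_B),
    ):
        cols = {
            "channel": np.repeat(tag, locs.n),
            "x": locs.coords[:, 0],
            "y": locs.coords[:, 1],
        }
        if locs.dim == 3:
            cols["z"] = locs.coords[:, 2]
        if locs.frames is not None:
            cols["frame"] = locs.frames
        cols["density_own"] = own
        cols["density_partner"] = partner
        cols["class"] = lab
        frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(
        table_path, index=False, float_format="%.17g"
    )
    return summary_path, table_path
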