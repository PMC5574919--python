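"""Image and table I/O.

Images are carried as plain 2-D numpy arrays of non-negative intensities
(uint8, uint16 or float), the scikit-image convention; binary masks are
boolean arrays of the same shape.  Coordinates are (row, col), 0-based,
origin at the top-left; bounding rectangles are half-open
``[r0, r1) x [c0, c1)``.

A field of view is three co-registered grayscale channels: blue (DAPI
nuclear counterstain), green (γH2AX, the DSB marker) and red (53BP1, the
DDR protein).  Channel roles are always mapped explicitly — there is no
positional or filename guessing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .exceptions import DimensionError, FormatError

CHANNEL_ROLES = ("blue", "green", "red")

#: a channel source: a path, or (path, page) into a multi-page TIFF
ChannelRef = Union[str, Path, tuple]


def _check_grid(arr: np.ndarray, name: str = "grid") -> np.ndarray:
    if arr.ndim != 2:
        raise FormatError(f"{name}: expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise FormatError(f"{name}: empty image")
    if np.issubdtype(arr.dtype, np.floating) and np.any(arr < 0):
        raise FormatError(f"{name}: negative intensities")
    return arr


@dataclass
class FieldImage:
    """One field of view: three equally sized grayscale channels."""

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    field_id: str = ""
    well_id: str = ""

    def __post_init__(self) -> None:
        for role in CHANNEL_ROLES:
            _check_grid(getattr(self, role), role)
        shapes = {role: getattr(self, role).shape for role in CHANNEL_ROLES}
        if len(set(shapes.values())) != 1:
            raise DimensionError(f"channel dimensions differ: {shapes}")

    @property
    def shape(self) -> tuple:
        return self.blue.shape

    def channel(self, role: str) -> np.ndarray:
        if role not in CHANNEL_ROLES:
            raise KeyError(f"unknown channel role {role!r}")
        return getattr(self, role)


def _read_channel(ref: ChannelRef) -> np.ndarray:
    """Read one grayscale plane from a TIFF file or a page of one."""
    if isinstance(ref, tuple):
        path, page = ref
        page = int(page)
        with tifffile.TiffFile(os.fspath(path)) as tif:
            if len(tif.pages) > 1:
                if page >= len(tif.pages):
                    raise FormatError(f"{path}: no page {page} ({len(tif.pages)} pages)")
                arr = tif.pages[page].asarray()
            else:  # planes stored as one multi-sample/volumetric page
                stack = tif.asarray()
                if stack.ndim == 2 and page == 0:
                    arr = stack
                elif stack.ndim == 3 and page < stack.shape[0]:
                    arr = stack[page]
                else:
                    raise FormatError(f"{path}: no page {page} (shape {stack.shape})")
        name = f"{path}[page {page}]"
    else:
        arr = tifffile.imread(os.fspath(ref))
        name = str(ref)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise FormatError(f"{name}: not a single grayscale plane (shape {arr.shape})")
    return _check_grid(arr, name)


def read_field(
    channel_map: Mapping[str, ChannelRef],
    field_id: str = "",
    well_id: str = "",
) -> FieldImage:
    """Read a three-channel field given an explicit role → file(/page) map.

    Parameters
    ----------
    channel_map
        Mapping with keys ``"blue"``, ``"green"``, ``"red"``; each value is a
        TIFF path or a ``(path, page)`` tuple into a multi-page TIFF.
        8- and 16-bit integer data are preserved losslessly.

    Raises
    ------
    DimensionError
        If the three channels do not share identical dimensions.
    FormatError
        If an input is not a single grayscale plane.
    """
    missing = [r for r in CHANNEL_ROLES if r not in channel_map]
    if missing:
        raise KeyError(f"channel_map missing roles: {missing}")
    grids = {role: _read_channel(channel_map[role]) for role in CHANNEL_ROLES}
    shapes = {role: g.shape for role, g in grids.items()}
    if len(set(shapes.values())) != 1:
        raise DimensionError(f"channel dimensions differ: {shapes}")
    return FieldImage(field_id=field_id, well_id=well_id, **grids)


def write_field(field_image: FieldImage, paths: Mapping[str, Union[str, Path]]) -> None:
    """Write each channel of a field to its own grayscale TIFF."""
    for role in CHANNEL_ROLES:
        if role in paths:
            tifffile.imwrite(os.fspath(paths[role]), field_image.channel(role))


# ---------------------------------------------------------------------------
# measurement tables

MEASUREMENT_COLUMNS = [
    "well_id",
    "field_id",
    "group",
    "nucleus_id",
    "channel",
    "foci_count",
    "foci_area_px",
    "foci_intensity_sum",
    "ra",
    "coloc_count",
    "coloc_area_px",
    "flags",
]


def write_measurements(records: Sequence, destination: Union[str, Path]) -> None:
    """Write per-nucleus, per-channel measurements to CSV.

    One row per nucleus x channel; rows are sorted deterministically by
    (well_id, field_id, nucleus_id, channel).  Undefined ratios are written
    as empty cells.  An empty record list yields a header-only file.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "well_id": rec.well_id,
                "field_id": rec.field_id,
                "group": rec.group,
                "nucleus_id": rec.nucleus_id,
                "channel": rec.channel,
                "foci_count": rec.foci_count,
                "foci_area_px": rec.foci_area_px,
                "foci_intensity_sum": rec.foci_intensity_sum,
                "ra": rec.ra,
                "coloc_count": rec.coloc_count,
                "coloc_area_px": rec.coloc_area_px,
                "flags": ";".join(rec.flags) if rec.flags else "",
            }
        )
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["well_id", "field_id", "nucleus_id", "channel"], kind="mergesort"
        ).reset_index(drop=True)
    df.to_csv(destination, index=False)


def read_measurements(path: Union[str, Path]) -> pd.DataFrame:
    """Read a measurements CSV written by :func:`write_measurements`."""
    df = pd.read_csv(path, dtype={"well_id": str, "field_id": str, "group": str, "flags": str})
    df["flags"] = df["flags"].fillna("")
    return df
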