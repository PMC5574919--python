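"""Per-nucleus foci metrics and the co-localization ratio.

Three competing per-nucleus metrics quantify foci formation: the foci count
(the conventional readout), the total foci area in pixels, and the
integrated foci intensity

    I_sum = Σ_{(i,j) ∈ S} I(i,j)

summed over the foci support S.  Intensity is additive under the optical
projection, so I_sum stays accurate when dense foci overlap and merge,
which is exactly where counting fails.

Recruitment of the DDR protein (red, 53BP1) to DSB sites (green, γH2AX) is
quantified by the co-localization ratio

    Ra = Σ_{(i,j) ∈ S_G} I_R(i,j)  /  Σ_{(i,j) ∈ S_G} I_G(i,j)

where S_G is the green foci support and both intensities come from the
extracted foci images (zero off-support), so the denominator equals the
total green foci intensity.  Two channels co-localize at a pixel when both
extracted intensities are positive there.

The percentage difference between two measurements,
``|d1 − d2| / min(d1, d2) × 100``, measures a metric's sensitivity to a
known contrast between two cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import List, Tuple

import numpy as np
from skimage import measure as skmeasure

from .exceptions import DimensionError
from .foci import FociImage


@dataclass
class NucleusMeasurement:
    """Foci metrics of one nucleus in one channel.

    ``ra`` and the ``coloc_*`` fields quantify red-in-green co-localization
    and are populated on red-channel records; NaN marks an undefined ratio
    (empty green support), which excludes the nucleus from Ra statistics.
    """

    nucleus_id: int
    channel: str  # "green" | "red"
    foci_count: int
    foci_area_px: int
    foci_intensity_sum: float
    ra: float = math.nan
    coloc_count: float = math.nan
    coloc_area_px: float = math.nan
    flags: List[str] = dc_field(default_factory=list)
    well_id: str = ""
    field_id: str = ""
    group: str = ""


def _label_support(foci: FociImage, connectivity: int) -> np.ndarray:
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    return skmeasure.label(foci.support, connectivity=1 if connectivity == 4 else 2)


def _filtered_support(foci: FociImage, connectivity: int, min_focus_px: int):
    """Label map and kept-label list after the minimum-focus-size filter."""
    labels = _label_support(foci, connectivity)
    if labels.max() == 0:
        return labels, []
    areas = np.bincount(labels.ravel())
    kept = [lab for lab in range(1, labels.max() + 1) if areas[lab] >= min_focus_px]
    return labels, kept


def count_foci(foci: FociImage, connectivity: int = 8, min_focus_px: int = 4) -> int:
    """Number of connected foci components with area >= ``min_focus_px``."""
    _, kept = _filtered_support(foci, connectivity, min_focus_px)
    return len(kept)


def total_foci_area(foci: FociImage, connectivity: int = 8, min_focus_px: int = 4) -> int:
    """Total foci area in pixels, after the minimum-focus-size filter."""
    labels, kept = _filtered_support(foci, connectivity, min_focus_px)
    if not kept:
        return 0
    areas = np.bincount(labels.ravel())
    return int(sum(areas[lab] for lab in kept))

def integrate_intensity(foci: FociImage) -> float:
    """Integrated foci intensity I_sum = Σ_{(i,j)∈S} I(i,j).

    Exact sum over the support with a wide accumulator (16-bit intensities
    over megapixel fields overflow 32-bit sums).
    """
    grid = foci.grid
    if np.issubdtype(grid.dtype, np.integer):
        return int(grid.sum(dtype=np.int64))
    return float(grid.sum(dtype=np.float64))


def coloc_ratio(green_foci: FociImage, red_foci: FociImage) -> float:
    """Co-localization ratio Ra = Σ_{S_G} I_R / Σ I_G.

    Both operands are extracted foci images of the same nucleus (identical
    bounding-rectangle frames).  Returns NaN when the green foci intensity
    is zero (undefined ratio; the nucleus is excluded from Ra statistics).
    """
    if green_foci.grid.shape != red_foci.grid.shape:
        raise DimensionError(
            f"foci image shapes differ: {green_foci.grid.shape} vs {red_foci.grid.shape}"
        )
    denominator = integrate_intensity(green_foci)
    if denominator <= 0:
        return math.nan
    numerator = red_foci.grid[green_foci.support].sum(dtype=np.float64)
    return float(numerator) / float(denominator)


def coloc_metrics(
    green_foci: FociImage,
    red_foci: FociImage,
    connectivity: int = 8,
    min_focus_px: int = 4,
) -> Tuple[int, int, float]:
    """Co-localized red foci count, co-localized area, and Ra.

    A red focus counts as co-localized when at least one of its pixels lies
    in the green foci support S_G; the co-localized area is
    ``|red support ∩ S_G|`` (over size-filtered red foci).
    """
    if green_foci.grid.shape != red_foci.grid.shape:
        raise DimensionError("foci image shapes differ")
    labels, kept = _filtered_support(red_foci, connectivity, min_focus_px)
    coloc_count = 0
    coloc_area = 0
    sg = green_foci.support
    for lab in kept:
        component = labels == lab
        overlap = int(np.count_nonzero(component & sg))
        if overlap > 0:
            coloc_count += 1
            coloc_area += overlap
    return coloc_count, coloc_area, coloc_ratio(green_foci, red_foci)


def percentage_difference(data1: float, data2: float) -> float:
    """Percentage difference ``|d1 − d2| / min(d1, d2) × 100``.

    Symmetric in its arguments.  Undefined (NaN) when min(d1, d2) <= 0.
    """
    low = min(data1, data2)
    if low <= 0:
        return math.nan
    return abs(data1 - data2) / low * 100.0


def measure_nucleus(
    nucleus_id: int,
    green_foci: FociImage,
    red_foci: FociImage,
    connectivity: int = 8,
    min_focus_px: int = 4,
    well_id: str = "",
    field_id: str = "",
    group: str = "",
) -> List[NucleusMeasurement]:
    """Green and red channel measurements for one nucleus.

    Ra and the co-localization count/area are attached to the red record
    (they quantify red recruitment into green foci).
    """
    green_rec = NucleusMeasurement(
        nucleus_id=nucleus_id,
        channel="green",
        foci_count=count_foci(green_foci, connectivity, min_focus_px),
        foci_area_px=total_foci_area(green_foci, connectivity, min_focus_px),
        foci_intensity_sum=integrate_intensity(green_foci),
        flags=list(green_foci.flags),
        well_id=well_id,
        field_id=field_id,
        group=group,
    )
    cc, ca, ra = coloc_metrics(green_foci, red_foci, connectivity, min_focus_px)
    red_flags = list(red_foci.flags)
    if math.isnan(ra):
        red_flags.append("ra_undefined")
    red_rec = NucleusMeasurement(
        nucleus_id=nucleus_id,
        channel="red",
        foci_count=count_foci(red_foci, connectivity, min_focus_px),
        foci_area_px=total_foci_area(red_foci, connectivity, min_focus_px),
        foci_intensity_sum=integrate_intensity(red_foci),
        ra=ra,
        coloc_count=cc,
        coloc_area_px=ca,
        flags=red_flags,
        well_id=well_id,
        field_id=field_id,
        group=group,
    )
    return [green_rec, red_rec]
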