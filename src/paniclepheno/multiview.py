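"""Conventional 2D comparison method: total multi-view pixel count.

The panicle's total pixel count is summed over all (typically 120)
pre-processed views.  Checkerboard squares that survive color
segmentation are rejected by shape: a region is dropped when it is both
compact (solidity > 0.7) and round (eccentricity < 0.95), or when its
area falls below 1000 pixels.  Solidity is region area over convex-hull
area; eccentricity is that of the same-second-moments ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

from .errors import ValidationError

#: paper-default shape filters for checkerboard-square rejection
SOLIDITY_MAX = 0.7
ECC_MIN = 0.95
MIN_AREA = 1000


@dataclass
class Region2D:
    """One 8-connected foreground region with its shape descriptors."""

    label: int
    area: int
    solidity: float
    eccentricity: float
    centroid: tuple[float, float]
    #: row/col coordinates of member pixels, (area, 2)
    coords: np.ndarray

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValidationError("region area must be >= 1")


def label_regions(mask: np.ndarray) -> list[Region2D]:
    """8-connected components of a binary mask with area, solidity and
    eccentricity (e = sqrt(1 - (minor/major)^2) of the second-central-
    moment ellipse).  An empty mask yields an empty list."""
    mask = np.asarray(mask, dtype=bool)
    labeled = _skmeasure.label(mask, connectivity=2)
    regions = []
    for props in _skmeasure.regionprops(labeled):
        regions.append(Region2D(
            label=props.label,
            area=int(props.area),
            solidity=float(props.solidity),
            eccentricity=float(props.eccentricity),
            centroid=tuple(props.centroid),
            coords=props.coords,
        ))
    return regions


def filter_panicle_regions(
    regions: Sequence[Region2D],
    solidity_max: float = SOLIDITY_MAX,
    ecc_min: float = ECC_MIN,
    min_area: int = MIN_AREA,
    *,
    exclusion_mode: Literal["and", "or"] = "and",
) -> list[Region2D]:
    """Drop checkerboard-square-like and tiny regions; keep the rest as is.

    A region is removed iff it looks like a square distractor -- by
    default compact AND round (``solidity > solidity_max`` and
    ``eccentricity < ecc_min``) -- or its area is below ``min_area``.
    ``exclusion_mode='or'`` removes regions that are compact OR round
    (a stricter variant that can also delete convex panicle branches).
    """
    kept = []
    for region in regions:
        compact = region.solidity > solidity_max
        round_ = region.eccentricity < ecc_min
        square_like = (compact and round_) if exclusion_mode == "and" \
            else (compact or round_)
        if square_like or region.area < min_area:
            continue
        kept.append(region)
    return kept


def region_table(
    masks: Iterable[np.ndarray],
    solidity_max: float = SOLIDITY_MAX,
    ecc_min: float = ECC_MIN,
    min_area: int = MIN_AREA,
    *,
    exclusion_mode: Literal["and", "or"] = "and",
) -> pd.DataFrame:
    """Per-image region audit: area, solidity, eccentricity and whether
    the region survived the square filter."""
    rows = []
    for i, mask in enumerate(masks):
        regions = label_regions(mask)
        kept_ids = {
            r.label
            for r in filter_panicle_regions(
                regions, solidity_max, ecc_min, min_area,
                exclusion_mode=exclusion_mode)
        }
        for r in regions:
            rows.append({
                "image": i, "region": r.label, "area": r.area,
                "solidity": r.solidity, "eccentricity": r.eccentricity,
                "kept": r.label in kept_ids,
            })
    return pd.DataFrame(
        rows, columns=["image", "region", "area", "solidity",
                       "eccentricity", "kept"])


def total_pixel_count(
    masks: Sequence[np.ndarray],
    solidity_max: float = SOLIDITY_MAX,
    ecc_min: float = ECC_MIN,
    min_area: int = MIN_AREA,
    *,
    exclusion_mode: Literal["and", "or"] = "and",
    expected_images: int | None = None,
    strict: bool = True,
) -> int:
    """Session total: per view, label regions, reject square-like and tiny
    ones, sum surviving areas; then sum over all views.

    ``expected_images`` (e.g. 120 from the manifest) is checked when
    given; a mismatch raises unless ``strict=False`` (warn and continue).
    """
    if expected_images is not None and len(masks) != expected_images:
        message = (f"session has {len(masks)} masks, manifest expects "
                   f"{expected_images}")
        if strict:
            raise ValidationError(message)
        import warnings

        warnings.warn(message, stacklevel=2)
    total = 0
    for mask in masks:
        kept = filter_panicle_regions(
            label_regions(mask), solidity_max, ecc_min, min_area,
            exclusion_mode=exclusion_mode)
        total += sum(r.area for r in kept)
    return int(total)
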