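"""End-point morphometry of flatbed-scanned mature panicles.

A harvested panicle is spread on a black scanner bed.  Segmentation uses
fixed HSV ranges (hue 0-0.3, saturation 0.2-1, value 0.5-1) that pass the
yellowish seeds and reject the black background.  Morphological opening
with a disk removes the thin branches connecting seeds, a minor-axis
floor rejects residual thin fragments, and each surviving region is
measured: major-axis length (seed length), minor-axis length (seed
width) and pixel area.  The panicle's projected surface area is the
foreground count before opening, so branch pixels still contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as _ndi
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph

from .errors import ValidationError
from .preprocess import SCAN_FOREGROUND, HSVThreshold, segment_background

#: defaults for a 600-dpi-scale scan
OPENING_RADIUS = 2
MIN_SEED_WIDTH = 8
MIN_SEED_AREA = 50


@dataclass
class SeedRecord:
    """One detected seed region."""

    seed_id: int
    length: float   # major-axis length, px
    width: float    # minor-axis length, px
    area: int       # pixel count
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValidationError("seed must satisfy length >= width > 0")
        if self.area < 1:
            raise ValidationError("seed area must be >= 1")


@dataclass
class ScanSummary:
    """Panicle-level scan traits.

    ``projected_surface_area`` counts foreground pixels of the raw
    segmentation (pre-opening); seed means are ``None`` when no seed was
    detected.
    """

    projected_seed_count: int
    projected_surface_area: int
    mean_seed_area: float | None
    mean_seed_length: float | None
    mean_seed_width: float | None
    seeds: list[SeedRecord]


def segment_scan(
    image: np.ndarray, thr: HSVThreshold = SCAN_FOREGROUND
) -> np.ndarray:
    """HSV-threshold a scan; emits an empty-foreground warning when the
    mask is blank (wrong background or exposure)."""
    mask = segment_background(image, thr)
    if not mask.any():
        import warnings

        warnings.warn("scan segmentation produced an empty foreground",
                      stacklevel=2)
    return mask


def open_mask(mask: np.ndarray, radius: int = OPENING_RADIUS) -> np.ndarray:
    """Morphological opening with a disk; structures thinner than
    ``2 * radius`` vanish.  ``radius=0`` is the identity."""
    mask = np.asarray(mask, dtype=bool)
    if radius <= 0:
        return mask.copy()
    return _ndi.binary_opening(mask, structure=_skmorph.disk(radius))


def detect_seeds(
    opened: np.ndarray,
    min_width: int = MIN_SEED_WIDTH,
    min_area: int = MIN_SEED_AREA,
) -> list[SeedRecord]:
    """Measure 8-connected regions of the opened mask as seeds.

    Regions whose same-second-moments-ellipse minor axis is below
    ``min_width`` (too thin: branch residue) or whose area is below
    ``min_area`` are dropped.
    """
    labeled = _skmeasure.label(np.asarray(opened, dtype=bool), connectivity=2)
    seeds = []
    for props in _skmeasure.regionprops(labeled):
        width = float(props.axis_minor_length)
        if width < min_width or props.area < min_area:
            continue
        seeds.append(SeedRecord(
            seed_id=len(seeds) + 1,
            length=float(props.axis_major_length),
            width=width,
            area=int(props.area),
            centroid=tuple(props.centroid),
        ))
    return seeds


def seed_table(seeds: Sequence[SeedRecord]) -> pd.DataFrame:
    """Per-seed CSV-ready table (id, length, width, area, centroid)."""
    return pd.DataFrame(
        [{"seed_id": s.seed_id, "length": s.length, "width": s.width,
          "area": s.area, "centroid_row": s.centroid[0],
          "centroid_col": s.centroid[1]} for s in seeds],
        columns=["seed_id", "length", "width", "area",
                 "centroid_row", "centroid_col"])


def scan_summary(
    image: np.ndarray,
    thr: HSVThreshold = SCAN_FOREGROUND,
    opening_radius: int = OPENING_RADIUS,
    min_width: int = MIN_SEED_WIDTH,
    min_area: int = MIN_SEED_AREA,
) -> ScanSummary:
    """Full scan pipeline: segment, open, detect, summarize."""
    mask = segment_scan(image, thr)
    seeds = detect_seeds(open_mask(mask, opening_radius), min_width, min_area)
    if seeds:
        areas = np.array([s.area for s in seeds], dtype=float)
        lengths = np.array([s.length for s in seeds])
        widths = np.array([s.width for s in seeds])
        means = (float(areas.mean()), float(lengths.mean()),
                 float(widths.mean()))
    else:
        means = (None, None, None)
    return ScanSummary(
        projected_seed_count=len(seeds),
        projected_surface_area=int(mask.sum()),
        mean_seed_area=means[0],
        mean_seed_length=means[1],
        mean_seed_width=means[2],
        seeds=seeds,
    )
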