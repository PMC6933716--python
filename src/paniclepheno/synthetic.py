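"""Seeded synthetic inputs with ground truth for every pipeline stage.

The generators emulate the imaging-chamber study conditions: a panicle of
ellipsoidal seeds drooping from a central attachment point, checkerboard
patches on the five reference planes (random square colors, deliberately
including panicle-green squares), a gray hook above the board aperture,
orthographic multi-view renders with optional checkerboard-square
distractors, flatbed-style scans of oval seeds joined by thin branches,
and a multi-genotype cohort whose end-point measurements are proportional
to true panicle volume (plus optional Gaussian noise).  Everything is
driven by one explicit RNG seed per call; identical seeds give identical
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from skimage import draw as _skdraw

from .cloud3d import DEFAULT_CHAMBER, ChamberModel, SimilarityTransform
from .errors import CapacityError, ValidationError
from .io import (LABEL_APPARATUS, LABEL_CHECKERBOARD, LABEL_PANICLE,
                 PointCloud)

#: panicle color endpoints (8-bit RGB): immature green to mature yellow
GREEN = np.array([50.0, 160.0, 60.0])
YELLOW = np.array([210.0, 180.0, 60.0])

#: panicle attachment point (top of the rachis) in the canonical frame
ATTACH = np.array([0.0, 0.0, 48.0])


def stage_color(stage: float) -> np.ndarray:
    """Mean seed color at maturation stage in [0, 1] (0 green, 1 yellow)."""
    if not 0.0 <= stage <= 1.0:
        raise ValidationError("color_stage must lie in [0, 1]")
    return GREEN + stage * (YELLOW - GREEN)


@dataclass(frozen=True)
class SyntheticPanicleSpec:
    """Parameters of one synthetic panicle scene.

    ``week_scale`` holds the strictly increasing volume multiplier per
    week; the whole panicle (seed semi-axes and seed positions about the
    attachment point) is scaled by its cube root, so the occupied volume
    scales exactly with the multiplier.  ``point_density`` is the
    volumetric sampling density in points per cm^3.  ``layout_seed``
    fixes the branch/seed geometry independently of the sampling seed,
    letting several scenes share one growth habit.
    """

    n_branches: int = 5
    seeds_per_branch: int = 8
    seed_semi_axes: tuple[float, float, float] = (1.3, 0.5, 0.4)
    week_scale: tuple[float, float, float] = (1.0, 1.9, 2.6)
    color_stage: float = 0.2
    week: int = 1
    rng_seed: int = 0
    layout_seed: int | None = None
    point_density: float = 60.0
    checker_points_per_patch: int = 1500
    hook_points: int = 350
    position_jitter: float = 0.4

    def __post_init__(self) -> None:
        if self.n_branches < 0 or self.seeds_per_branch < 0:
            raise ValidationError("counts must be non-negative")
        if not all(a > 0 for a in self.seed_semi_axes):
            raise ValidationError("seed semi-axes must be positive")
        if not (self.week_scale[0] < self.week_scale[1] < self.week_scale[2]):
            raise ValidationError("week_scale must be strictly increasing")
        if self.week not in (1, 2, 3):
            raise ValidationError("week must be 1, 2 or 3")
        if not 0.0 <= self.color_stage <= 1.0:
            raise ValidationError("color_stage must lie in [0, 1]")

    @property
    def volume_multiplier(self) -> float:
        return self.week_scale[self.week - 1]


@dataclass
class SceneTruth:
    """Ground truth attached to one generated scene."""

    labels: np.ndarray              # per-point component label
    true_volume: float              # union volume of all seeds (cm^3)
    n_panicle_points: int
    seed_centers: np.ndarray        # (n_seeds, 3)
    color_stage: float


def _branch_point(azimuth: float, radial_max: float, droop: float,
                  t: float | np.ndarray) -> np.ndarray:
    """Point(s) on a drooping branch curve at parameter t in [0, 1]."""
    t = np.asarray(t, dtype=float)
    radial = radial_max * t
    return ATTACH + np.stack([
        radial * np.cos(azimuth), radial * np.sin(azimuth),
        -droop * t ** 1.3,
    ], axis=-1)


def _seed_layout(
    spec: SyntheticPanicleSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[float, float, float]]]:
    """Unit-scale layout: seed centers, rotations, semi-axes, and the
    (azimuth, radial_max, droop) parameters of each branch curve."""
    axes = np.asarray(spec.seed_semi_axes, dtype=float)
    centers = []
    rotations = []
    branches = []
    for b in range(spec.n_branches):
        azimuth = 2.0 * np.pi * b / max(spec.n_branches, 1) \
            + rng.uniform(-0.2, 0.2)
        radial_max = rng.uniform(7.0, 11.5)
        droop = rng.uniform(10.0, 20.0)
        branches.append((azimuth, radial_max, droop))
        for j in range(spec.seeds_per_branch):
            t = 0.5 + 0.42 * j / max(spec.seeds_per_branch - 1, 1)
            center = _branch_point(azimuth, radial_max, droop, t)
            center += rng.uniform(-spec.position_jitter,
                                  spec.position_jitter, 3)
            centers.append(center)
            rotations.append(Rotation.random(rng=rng).as_matrix())
    if not centers:
        return np.empty((0, 3)), np.empty((0, 3, 3)), axes, branches
    return np.asarray(centers), np.asarray(rotations), axes, branches


def _union_volume(centers: np.ndarray, rotations: np.ndarray,
                  axes: np.ndarray, cell: float) -> float:
    """Union volume of rotated ellipsoids by cell-center rasterization
    (a shared global cell index set corrects for overlaps)."""
    occupied: set[int] = set()
    stride = 1 << 21
    for center, rot in zip(centers, rotations):
        radius = float(axes.max())
        lo = np.floor((center - radius) / cell).astype(np.int64)
        hi = np.ceil((center + radius) / cell).astype(np.int64)
        grid = np.stack(np.meshgrid(
            np.arange(lo[0], hi[0] + 1),
            np.arange(lo[1], hi[1] + 1),
            np.arange(lo[2], hi[2] + 1), indexing="ij"), axis=-1).reshape(-1, 3)
        pts = (grid + 0.5) * cell
        local = (pts - center) @ rot
        inside = ((local / axes) ** 2).sum(axis=1) <= 1.0
        cells = grid[inside]
        flat = (cells[:, 0] * stride + cells[:, 1]) * stride + cells[:, 2]
        occupied.update(flat.tolist())
    return len(occupied) * cell ** 3


def panicle_layout_volume(
    spec: SyntheticPanicleSpec, *, truth_cell: float = 0.05
) -> float:
    """Union volume of the unit-scale seed layout of ``spec`` (cm^3).

    Because a scene at volume multiplier m is the similarity-scaled copy
    of this layout, its true volume is exactly ``m *
    panicle_layout_volume(spec)``.
    """
    rng = np.random.default_rng(
        spec.layout_seed if spec.layout_seed is not None else spec.rng_seed)
    centers, rotations, axes, _ = _seed_layout(spec, rng)
    if not len(centers):
        return 0.0
    return _union_volume(centers, rotations, axes, truth_cell)


def _sample_ellipsoid(n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform in the unit ball."""
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = rng.random(n) ** (1.0 / 3.0)
    return directions * radii[:, None]


def make_scene(
    spec: SyntheticPanicleSpec,
    chamber: ChamberModel = DEFAULT_CHAMBER,
    *,
    truth_cell: float = 0.1,
) -> tuple[PointCloud, SceneTruth]:
    """One canonical-frame chamber scene: panicle + checkerboards + hook.

    The truth records per-point labels and the union volume of all seed
    ellipsoids (rasterized at ``truth_cell``, so overlaps are not double
    counted).  A fixed ``rng_seed`` reproduces the scene byte for byte.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rng_layout = (np.random.default_rng(spec.layout_seed)
                  if spec.layout_seed is not None else rng)
    points_parts: list[np.ndarray] = []
    colors_parts: list[np.ndarray] = []
    labels_parts: list[np.ndarray] = []

    # --- checkerboard patches (one per reference plane, margins kept) ---
    cx = 0.5 * (chamber.x_min + chamber.x_max)
    cy = 0.5 * (chamber.y_min + chamber.y_max)
    half = 10.0  # 20 squares x 1 cm, centered
    z_lo = 30.0
    patches = [
        # (origin, in-plane axis u, in-plane axis v), each spanning 20 cm
        (np.array([35.0 - half, 35.0 - half, 0.0]),
         np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),      # board surface
        (np.array([chamber.x_min, cy - half, z_lo]),
         np.array([0, 1.0, 0]), np.array([0, 0, 1.0])),
        (np.array([chamber.x_max, cy - half, z_lo]),
         np.array([0, 1.0, 0]), np.array([0, 0, 1.0])),
        (np.array([cx - half, chamber.y_min, z_lo]),
         np.array([1.0, 0, 0]), np.array([0, 0, 1.0])),
        (np.array([cx - half, chamber.y_max, z_lo]),
         np.array([1.0, 0, 0]), np.array([0, 0, 1.0])),
    ]
    n_sq = int(round(2 * half / chamber.square_edge))
    for origin, u_axis, v_axis in patches:
        palette = rng.integers(0, 256, size=(n_sq, n_sq, 3))
        # some squares share the panicle's green on purpose: they must be
        # rejected by shape, not color, in the 2D pipeline
        palette[rng.random((n_sq, n_sq)) < 0.1] = GREEN.astype(np.int64)
        uv = rng.random((spec.checker_points_per_patch, 2)) * 2 * half
        square = np.minimum((uv // chamber.square_edge).astype(int), n_sq - 1)
        pts = origin + uv[:, :1] * u_axis + uv[:, 1:2] * v_axis
        points_parts.append(pts)
        colors_parts.append(palette[square[:, 0], square[:, 1]])
        labels_parts.append(np.full(len(pts), LABEL_CHECKERBOARD,
                                    dtype=np.uint8))

    # --- gray hook above the aperture -----------------------------------
    hx, hy, hz = chamber.hook_center
    n_hook = spec.hook_points
    radius = 1.2 * np.sqrt(rng.random(n_hook))
    phi = rng.uniform(0, 2 * np.pi, n_hook)
    hook_pts = np.column_stack([
        hx + radius * np.cos(phi), hy + radius * np.sin(phi),
        rng.uniform(hz - 3.0, hz + 3.0, n_hook),
    ])
    gray = rng.integers(110, 150, n_hook)
    points_parts.append(hook_pts)
    colors_parts.append(np.clip(
        gray[:, None] + rng.integers(-5, 6, (n_hook, 3)), 0, 255))
    labels_parts.append(np.full(n_hook, LABEL_APPARATUS, dtype=np.uint8))

    # --- panicle: volumetrically sampled seed ellipsoids -----------------
    centers, rotations, axes, branches = _seed_layout(spec, rng_layout)
    scale = spec.volume_multiplier ** (1.0 / 3.0)
    centers = ATTACH + scale * (centers - ATTACH) if len(centers) \
        else centers
    axes = axes * scale
    base_color = stage_color(spec.color_stage)
    seed_volume = 4.0 / 3.0 * np.pi * float(np.prod(axes))
    n_panicle = 0
    for center, rot in zip(centers, rotations):
        n_pts = max(1, int(round(spec.point_density * seed_volume)))
        unit = _sample_ellipsoid(n_pts, rng)
        pts = center + (unit * axes) @ rot.T
        jitter = rng.integers(-10, 11, (n_pts, 3))
        points_parts.append(pts)
        colors_parts.append(np.clip(base_color + jitter, 0, 255))
        labels_parts.append(np.full(n_pts, LABEL_PANICLE, dtype=np.uint8))
        n_panicle += n_pts

    # --- rachis/branch stems (green throughout maturation): they keep the
    # projected silhouette connected and sprawling, like a real panicle --
    if spec.n_branches and spec.seeds_per_branch:
        stem_color = np.array([70.0, 150.0, 70.0])
        for azimuth, radial_max, droop in branches:
            t = np.linspace(0.0, 0.92, int(round(320 * scale)))
            curve = ATTACH + scale * (
                _branch_point(azimuth, radial_max, droop, t) - ATTACH)
            curve = curve + rng.normal(0.0, 0.15 * scale, curve.shape)
            jitter = rng.integers(-10, 11, (len(curve), 3))
            points_parts.append(curve)
            colors_parts.append(np.clip(stem_color + jitter, 0, 255))
            labels_parts.append(np.full(len(curve), LABEL_PANICLE,
                                        dtype=np.uint8))
            n_panicle += len(curve)

    points = np.vstack(points_parts)
    colors = np.vstack(colors_parts).astype(np.uint8)
    labels = np.concatenate(labels_parts)
    true_volume = (_union_volume(centers, rotations, axes, truth_cell)
                   if len(centers) else 0.0)
    cloud = PointCloud(points, colors, labels)
    truth = SceneTruth(labels=labels.copy(), true_volume=true_volume,
                       n_panicle_points=n_panicle, seed_centers=centers,
                       color_stage=spec.color_stage)
    return cloud, truth


def random_similarity(
    rng: np.random.Generator,
    scale_range: tuple[float, float] = (0.5, 2.5),
    max_translation: float = 30.0,
) -> SimilarityTransform:
    """A random, well-conditioned similarity transform (for invariance
    tests: apply it to a canonical scene, then recover it)."""
    return SimilarityTransform(
        float(rng.uniform(*scale_range)),
        Rotation.random(rng=rng).as_matrix(),
        rng.uniform(-max_translation, max_translation, 3),
    )


# ---------------------------------------------------------------------------
# multi-view rendering
# ---------------------------------------------------------------------------


@dataclass
class ViewsTruth:
    """Per-view true panicle foreground pixel counts (distractors not
    included)."""

    pixel_counts: list[int]


def render_views(
    cloud: PointCloud,
    n_views: int = 120,
    *,
    image_size: tuple[int, int] = (320, 320),
    px_per_unit: float = 6.0,
    point_radius: int = 2,
    distractor_squares: int = 0,
    rng_seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray], ViewsTruth]:
    """Orthographic renders of the panicle at equally spaced azimuths
    (120 views = one per 3 degrees, i.e. two cameras stepping 6 degrees).

    Panicle points (label ``panicle``, or all points when the cloud has
    no labels) are splatted as colored disks on black; optional
    checkerboard-square distractors (solid, panicle-green so color
    segmentation cannot reject them) are drawn along the left and right
    frame edges, clear of the centered panicle.  Returns color images,
    boolean panicle masks, and the true panicle pixel count per view.
    """
    sub = (cloud.select(cloud.labels == LABEL_PANICLE)
           if cloud.labels is not None else cloud)
    rng = np.random.default_rng(rng_seed)
    h, w = image_size
    offsets = [(dr, dc)
               for dr in range(-point_radius, point_radius + 1)
               for dc in range(-point_radius, point_radius + 1)
               if dr * dr + dc * dc <= point_radius * point_radius]
    center = sub.points.mean(axis=0) if len(sub) else np.zeros(3)
    images: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    counts: list[int] = []
    for v in range(n_views):
        theta = 2.0 * np.pi * v / n_views
        u_axis = np.array([-np.sin(theta), np.cos(theta), 0.0])
        image = np.zeros((h, w, 3), dtype=np.uint8)
        mask = np.zeros((h, w), dtype=bool)
        if len(sub):
            us = (sub.points - center) @ u_axis
            vs = sub.points[:, 2] - center[2]
            cols = np.round(w / 2 + us * px_per_unit).astype(int)
            rows = np.round(h / 2 - vs * px_per_unit).astype(int)
            for dr, dc in offsets:
                rr = rows + dr
                cc = cols + dc
                ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                mask[rr[ok], cc[ok]] = True
                image[rr[ok], cc[ok]] = sub.colors[ok]
        counts.append(int(mask.sum()))
        for s in range(distractor_squares):
            size = 40 if s % 2 == 0 else 25  # large: shape-filtered;
            #                                  small: area-filtered
            col0 = 4 if s % 4 < 2 else w - size - 4
            row0 = int(rng.integers(4, h - size - 4))
            image[row0:row0 + size, col0:col0 + size] = GREEN.astype(np.uint8)
        images.append(image)
        masks.append(mask)
    return images, masks, ViewsTruth(pixel_counts=counts)


def draw_frame(
    shape: tuple[int, int] = (300, 400),
    ellipses: Sequence[tuple[tuple[float, float], tuple[float, float], float]] = (),
    squares: Sequence[tuple[int, int, int]] = (),
) -> tuple[np.ndarray, int]:
    """Binary test frame of ellipse blobs plus solid square distractors.

    ``ellipses`` are ((row, col), (semi_r, semi_c), rotation_rad);
    ``squares`` are (row0, col0, size).  Returns the mask and the exact
    drawn-ellipse pixel count (shapes must not overlap for the truth to
    stay exact).
    """
    mask = np.zeros(shape, dtype=bool)
    blob_px = 0
    for (r, c), (sr, sc), angle in ellipses:
        rr, cc = _skdraw.ellipse(r, c, sr, sc, shape=shape, rotation=angle)
        blob_px += len(rr)
        mask[rr, cc] = True
    for r0, c0, size in squares:
        mask[r0:r0 + size, c0:c0 + size] = True
    return mask, blob_px


# ---------------------------------------------------------------------------
# flatbed-scan emulation
# ---------------------------------------------------------------------------


@dataclass
class ScanTruth:
    """Ground truth of one synthetic scan."""

    seed_count: int
    major_axis: float           # full major-axis length, px
    minor_axis: float           # full minor-axis length, px
    centers: np.ndarray         # (n, 2) row/col
    foreground_px: int          # every painted pixel (seeds + connectors)


def make_scan(
    n_seeds: int = 30,
    axes: tuple[float, float] = (20.0, 10.0),
    connector_width: int = 3,
    rng_seed: int = 0,
    *,
    image_size: tuple[int, int] = (600, 800),
    max_attempts: int = 20000,
) -> tuple[np.ndarray, ScanTruth]:
    """Yellow seed ovals on black, chained by thin branch segments.

    ``axes`` are the ellipse semi-axes in pixels (so 40 x 20 px seeds by
    default).  Placement is rejection sampled so ovals never overlap
    (centers at least ``2 * major + 6`` px apart); a
    :class:`CapacityError` is raised when the canvas cannot host
    ``n_seeds``.
    """
    rng = np.random.default_rng(rng_seed)
    h, w = image_size
    major = max(axes)
    margin = int(np.ceil(major)) + 4
    min_dist = 2.0 * major + 6.0
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_seeds:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not place {n_seeds} non-overlapping seeds in "
                f"{image_size} after {max_attempts} attempts")
        attempts += 1
        cand = np.array([rng.uniform(margin, h - margin),
                         rng.uniform(margin, w - margin)])
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
    centers_arr = (np.asarray(centers).reshape(-1, 2)
                   if centers else np.empty((0, 2)))

    image = np.zeros((h, w, 3), dtype=np.uint8)
    # thin connectors first, ovals painted on top; the Euclidean minimum
    # spanning tree over seed centers keeps connectors from crossing or
    # piling up (overlaps would form junctions thicker than one segment)
    if connector_width > 0 and len(centers) > 1:
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial.distance import squareform

        dist = squareform(
            np.linalg.norm(centers_arr[:, None] - centers_arr[None], axis=2),
            checks=False)
        tree = minimum_spanning_tree(squareform(dist)).tocoo()
        half = connector_width / 2.0
        for i, j in zip(tree.row, tree.col):
            a, b = centers_arr[i], centers_arr[j]
            direction = b - a
            norm = np.linalg.norm(direction)
            if norm == 0:
                continue
            perp = np.array([-direction[1], direction[0]]) / norm
            rr, cc = _skdraw.polygon(
                [a[0] - perp[0] * half, a[0] + perp[0] * half,
                 b[0] + perp[0] * half, b[0] - perp[0] * half],
                [a[1] - perp[1] * half, a[1] + perp[1] * half,
                 b[1] + perp[1] * half, b[1] - perp[1] * half],
                shape=(h, w))
            image[rr, cc] = YELLOW.astype(np.uint8)
    for center in centers:
        angle = rng.uniform(0, np.pi)
        rr, cc = _skdraw.ellipse(center[0], center[1], axes[1], axes[0],
                                 shape=(h, w), rotation=angle)
        jitter = rng.integers(-8, 9, (len(rr), 3))
        image[rr, cc] = np.clip(YELLOW + jitter, 0, 255).astype(np.uint8)
    foreground = int((image.sum(axis=2) > 0).sum())
    truth = ScanTruth(seed_count=len(centers), major_axis=2 * axes[0],
                      minor_axis=2 * axes[1], centers=centers_arr,
                      foreground_px=foreground)
    return image, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthGroup:
    """A designed genotype growth pattern.

    ``base_volume`` sets the overall panicle magnitude, ``week_scale``
    the within-plant growth trajectory, ``color_stages`` the maturation
    schedule.
    """

    name: str
    base_volume: float
    week_scale: tuple[float, float, float]
    color_stages: tuple[float, float, float]


DEFAULT_GROUPS = (
    GrowthGroup("modest", 1.0, (1.0, 1.9, 2.6), (0.15, 0.45, 0.80)),
    GrowthGroup("vigorous", 4.2, (1.0, 1.35, 1.8), (0.10, 0.40, 0.75)),
)


@dataclass
class CohortPlant:
    """One plant of the cohort with its per-week scene specs."""

    genotype: str
    replicate: int
    treatment: str
    group: str
    specs: dict[int, SyntheticPanicleSpec]   # week -> spec


@dataclass
class CohortTruth:
    """Designed group per genotype and true volume per plant x week."""

    genotype_groups: dict[str, str]
    true_volumes: pd.DataFrame  # key columns + true_volume
    layout_volume: float        # unit-scale union volume shared by plants


@dataclass
class Cohort:
    plants: list[CohortPlant]
    manual_table: pd.DataFrame  # end-point measurements keyed like TraitTable
    truth: CohortTruth


def make_cohort(
    n_genotypes: int = 11,
    reps: tuple[int, int] = (3, 2),
    treatments: tuple[str, ...] = ("control", "HNT"),
    rng_seed: int = 0,
    *,
    groups: tuple[GrowthGroup, ...] = DEFAULT_GROUPS,
    noise_sd: float = 0.05,
    point_density: float = 60.0,
    checker_points_per_patch: int = 1200,
    layout_seed: int = 101,
) -> Cohort:
    """A designed multi-genotype cohort with ground truth.

    The default design matches an 11-genotype validation study with 3
    control and 2 heat-treated (HNT) replicates per genotype: 55 plants,
    each imaged at weeks 1-3.  Genotypes split across ``groups`` in
    contiguous blocks; within a group, genotype volume is geometrically
    spaced (9 % apart) and replicates sit 1.5 % apart, so all plant
    volumes are distinct.  Every plant shares one branch/seed layout
    (``layout_seed``) scaled by its own volume multiplier, which makes
    the true volume exactly proportional to the multiplier.  HNT raises
    week-1 volume by 15 % and advances the color stage, mirroring
    accelerated maturation.  End-point seed number and weight are
    proportional to final true volume times ``1 + N(0, noise_sd)``, so
    the voxel-count / seed-weight correlation is positive by
    construction and exact (up to discretization) when ``noise_sd=0``.
    """
    if n_genotypes < len(groups):
        raise ValidationError("need at least one genotype per group")
    rng = np.random.default_rng(rng_seed)
    layout_volume = None
    plants: list[CohortPlant] = []
    genotype_groups: dict[str, str] = {}
    manual_rows = []
    volume_rows = []
    group_of = [groups[g * len(groups) // n_genotypes]
                for g in range(n_genotypes)]
    for g in range(n_genotypes):
        genotype = f"G{g + 1:02d}"
        group = group_of[g]
        genotype_groups[genotype] = group.name
        within = g - next(i for i in range(n_genotypes)
                          if group_of[i] is group)
        geno_mult = group.base_volume * 1.09 ** within
        for t_idx, treatment in enumerate(treatments):
            n_reps = reps[t_idx % len(reps)]
            for rep in range(1, n_reps + 1):
                plant_mult = geno_mult * (1.0 + 0.015 * (rep - 1))
                hnt = treatment == "HNT"
                week_mult = list(group.week_scale)
                if hnt:
                    week_mult[0] *= 1.15
                specs = {}
                for week in (1, 2, 3):
                    stage = min(1.0, group.color_stages[week - 1]
                                + (0.15 if hnt else 0.0))
                    spec = SyntheticPanicleSpec(
                        week_scale=tuple(np.asarray(week_mult) * plant_mult),
                        color_stage=stage,
                        week=week,
                        rng_seed=int(rng.integers(0, 2 ** 31)),
                        layout_seed=layout_seed,
                        point_density=point_density,
                        checker_points_per_patch=checker_points_per_patch,
                    )
                    specs[week] = spec
                    if layout_volume is None:
                        layout_volume = panicle_layout_volume(spec)
                    volume_rows.append({
                        "genotype": genotype, "replicate": rep,
                        "treatment": treatment, "week": week,
                        "true_volume": spec.volume_multiplier * layout_volume,
                    })
                final_volume = week_mult[2] * plant_mult * layout_volume
                noise = (rng.normal(0.0, noise_sd, 3) if noise_sd > 0
                         else np.zeros(3))
                seed_number = max(1, int(round(
                    0.4 * final_volume * (1.0 + noise[0]))))
                total_weight = 0.012 * final_volume * (1.0 + noise[1])
                manual_rows.append({
                    "genotype": genotype, "replicate": rep,
                    "treatment": treatment, "week": 3,
                    "seed_number": seed_number,
                    "total_seed_weight": total_weight,
                    "weight_per_seed": total_weight / seed_number,
                    "fertility": float(np.clip(90.0 + 40.0 * noise[2],
                                               0.0, 100.0)),
                })
                plants.append(CohortPlant(genotype, rep, treatment,
                                          group.name, specs))
    manual = pd.DataFrame(manual_rows)
    truth = CohortTruth(genotype_groups, pd.DataFrame(volume_rows),
                        layout_volume or 0.0)
    return Cohort(plants, manual, truth)
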