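"""Point-cloud trait extraction for developing panicles.

A reconstructed scene contains three components: the panicle itself, the
color checkerboards pasted flat on the four chamber walls and the board
surface, and the gray metal hook of the rotary apparatus above the board
aperture.  Because multi-view-stereo output has arbitrary scale and
orientation, every cloud is brought into a canonical chamber frame by
fitting the five constant checkerboard planes and Procrustes-aligning
their board-corner intersections; the hook centroid breaks the remaining
180-degree ambiguity of the rectangular wall footprint.

Aligned panicle points are binned into a shared bounding cube divided
``resolution`` times per edge (1000 by default).  Traits are the filled
voxel count (a volume proxy), the per-channel sums of per-voxel mean
colors, and their red:green ratio (a green-to-yellow maturation proxy).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import (AlignmentError, OutOfBoundsError, UndefinedTraitError,
                     ValidationError)
from .io import (LABEL_APPARATUS, LABEL_CHECKERBOARD, LABEL_PANICLE,
                 PointCloud)

# ---------------------------------------------------------------------------
# chamber model and canonical frame
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChamberModel:
    """Constant reference geometry of the imaging chamber, canonical frame.

    The board surface is the plane z = 0 with the aperture center at the
    origin; walls are the four vertical planes ``x = x_min``, ``x = x_max``,
    ``y = y_min``, ``y = y_max``.  The wall rectangle is deliberately not
    centered on the aperture so that the four board-corner landmarks plus
    the hook position determine the frame uniquely.  Units are
    centimeters; each checkerboard square has a 1 cm edge, which makes the
    recovered scale metric if desired.
    """

    x_min: float = -60.0
    x_max: float = 70.0
    y_min: float = -65.0
    y_max: float = 75.0
    wall_height: float = 80.0
    hook_center: tuple[float, float, float] = (0.0, 0.0, 73.0)
    #: max(R,G,B) - min(R,G,B) below which a point counts as gray (8-bit)
    hook_chroma_tol: float = 30.0
    #: the hook lives in this top fraction of the scene height
    hook_top_fraction: float = 0.10
    square_edge: float = 1.0

    def __post_init__(self) -> None:
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValidationError("chamber wall planes are degenerate")
        if self.square_edge <= 0:
            raise ValidationError("checkerboard square edge must be positive")

    def planes(self) -> list[tuple[np.ndarray, float]]:
        """The five reference planes as (unit normal n, offset d): n.x = d."""
        return [
            (np.array([0.0, 0.0, 1.0]), 0.0),            # board surface
            (np.array([1.0, 0.0, 0.0]), self.x_min),
            (np.array([1.0, 0.0, 0.0]), self.x_max),
            (np.array([0.0, 1.0, 0.0]), self.y_min),
            (np.array([0.0, 1.0, 0.0]), self.y_max),
        ]

    def corners(self) -> np.ndarray:
        """The four wall-wall-board intersection landmarks, (4, 3)."""
        return np.array([
            (self.x_min, self.y_min, 0.0),
            (self.x_min, self.y_max, 0.0),
            (self.x_max, self.y_min, 0.0),
            (self.x_max, self.y_max, 0.0),
        ])


DEFAULT_CHAMBER = ChamberModel()


@dataclass(frozen=True)
class BoundingCube:
    """Axis-aligned cube, shared across all clouds of a study, with the
    voxel resolution per edge (1000 by default)."""

    min_corner: tuple[float, float, float] = (-28.0, -28.0, 2.0)
    edge: float = 56.0
    resolution: int = 1000

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValidationError("cube edge must be positive")
        if self.resolution < 1:
            raise ValidationError("resolution must be >= 1")

    @property
    def voxel_edge(self) -> float:
        return self.edge / self.resolution


DEFAULT_CUBE = BoundingCube()


@dataclass
class SimilarityTransform:
    """p -> scale * R @ p + t with R a proper rotation."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray
    #: RMS landmark residual of the fit that produced this transform
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).ravel()
        if self.scale <= 0:
            raise ValidationError("scale must be positive")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3),
                           atol=1e-9):
            raise ValidationError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValidationError("rotation must have determinant +1")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return SimilarityTransform(
            self.scale * other.scale,
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "SimilarityTransform":
        r_inv = self.rotation.T
        return SimilarityTransform(
            1.0 / self.scale, r_inv,
            -(r_inv @ self.translation) / self.scale,
        )


def apply_transform(cloud: PointCloud, transform: SimilarityTransform) -> PointCloud:
    """Transform every coordinate; colors and labels are untouched."""
    return PointCloud(transform.apply_points(cloud.points), cloud.colors,
                      cloud.labels)


# ---------------------------------------------------------------------------
# reference-plane extraction
# ---------------------------------------------------------------------------


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares plane through ``points``: unit normal n, offset d."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    normal = vt[-1]
    return normal, float(normal @ centroid)


def extract_reference_planes(
    points: np.ndarray,
    *,
    tol: float | None = None,
    min_inliers: int = 50,
) -> list[tuple[np.ndarray, float, np.ndarray]]:
    """Recover the planar checkerboard patches of a scene in any frame.

    The checkerboards lie on the convex hull of the scene (the chamber is
    a convex shell around the panicle), so hull facets are clustered into
    coplanar groups, each group's member points are refitted by
    least squares with a median-absolute-deviation outlier guard, and
    groups with fewer than ``min_inliers`` supporting points are dropped.

    Returns (normal, offset, inlier_index) triples sorted by support,
    with ``normal . x = offset``.

    Raises
    ------
    AlignmentError
        If the scene is degenerate (no 3D hull) or no plane has support.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise AlignmentError("too few points to recover reference planes")
    diag = float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))
    if tol is None:
        tol = 2e-3 * diag
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise AlignmentError(f"degenerate scene geometry: {exc}") from None

    # cluster hull facets into coplanar groups
    reps: list[tuple[np.ndarray, float]] = []
    for eq in hull.equations:  # n.x + b <= 0 inside, |n| = 1
        n, b = eq[:3], eq[3]
        for i, (rn, rb) in enumerate(reps):
            if n @ rn > 0.999 and abs(b - rb) < 4 * tol:
                break
        else:
            reps.append((n, b))

    planes = []
    for n, b in reps:
        inl = np.flatnonzero(np.abs(points @ n + b) < tol)
        if len(inl) < min_inliers:
            continue
        # LS refit with MAD outlier guard
        for _ in range(2):
            normal, d = _fit_plane(points[inl])
            res = points[inl] @ normal - d
            med = np.median(res)
            mad = np.median(np.abs(res - med))
            if mad > 1e-12 * max(1.0, diag):
                keep = np.abs(res - med) <= 5.0 * mad
                if keep.sum() >= min_inliers and keep.sum() < len(inl):
                    inl = inl[keep]
                    continue
            break
        planes.append((normal, d, inl))
    if not planes:
        raise AlignmentError("no reference planes with sufficient support")
    planes.sort(key=lambda p: -len(p[2]))
    return planes


def _chamber_structure(
    planes: list[tuple[np.ndarray, float, np.ndarray]],
) -> tuple[tuple[np.ndarray, float], list, list]:
    """Identify board plane and the two parallel wall pairs among planes.

    The board is the unique plane whose normal is parallel to no other;
    walls come as two mutually perpendicular parallel pairs.
    """
    top = planes[: min(len(planes), 7)]
    for combo in itertools.combinations(range(len(top)), 5):
        sel = [top[i] for i in combo]
        normals = [p[0] for p in sel]
        para = [[j for j in range(5)
                 if j != i and abs(normals[i] @ normals[j]) > 0.99]
                for i in range(5)]
        board_idx = [i for i in range(5) if not para[i]]
        if len(board_idx) != 1:
            continue
        b = board_idx[0]
        rest = [i for i in range(5) if i != b]
        pairs = []
        used: set[int] = set()
        for i in rest:
            if i in used:
                continue
            mates = [j for j in para[i] if j in rest and j not in used]
            if len(mates) != 1:
                break
            pairs.append((i, mates[0]))
            used.update({i, mates[0]})
        if len(pairs) != 2:
            continue
        # the two pairs must be mutually perpendicular and perpendicular
        # to the board
        n1, n2 = normals[pairs[0][0]], normals[pairs[1][0]]
        nb = normals[b]
        if (abs(n1 @ n2) < 0.05 and abs(n1 @ nb) < 0.05
                and abs(n2 @ nb) < 0.05):
            return ((normals[b], sel[b][1]),
                    [sel[pairs[0][0]], sel[pairs[0][1]]],
                    [sel[pairs[1][0]], sel[pairs[1][1]]])
    raise AlignmentError(
        "could not identify board plane and two wall pairs among the "
        "recovered planes"
    )


# ---------------------------------------------------------------------------
# component segmentation
# ---------------------------------------------------------------------------


def segment_components(
    cloud: PointCloud,
    model: ChamberModel = DEFAULT_CHAMBER,
    wall_distance_tol: float | None = None,
) -> PointCloud:
    """Label scene points as checkerboard, apparatus (hook), or panicle.

    Works in any frame: checkerboard points are those near one of the five
    recovered reference planes; hook points are gray (low chroma) points
    in the top ``model.hook_top_fraction`` of the scene along the board
    normal (oriented toward the bulk of the non-plane points); everything
    else is panicle.

    Raises
    ------
    AlignmentError
        If no reference planes can be recovered (alignment impossible).
    """
    if len(cloud) == 0:
        raise ValidationError("cannot segment an empty cloud")
    planes = extract_reference_planes(cloud.points, tol=wall_distance_tol)
    labels = np.full(len(cloud), LABEL_PANICLE, dtype=np.uint8)

    diag = float(np.linalg.norm(cloud.points.max(axis=0)
                                - cloud.points.min(axis=0)))
    tol = wall_distance_tol if wall_distance_tol is not None else 2e-3 * diag
    near_plane = np.zeros(len(cloud), dtype=bool)
    for normal, d, _ in planes:
        near_plane |= np.abs(cloud.points @ normal - d) < tol
    labels[near_plane] = LABEL_CHECKERBOARD

    # orient the board normal toward the interior (panicle + hook) side
    (nb, db), _, _ = _chamber_structure(planes)
    interior = ~near_plane
    if interior.any():
        heights = cloud.points @ nb - db
        if np.median(heights[interior]) < 0:
            heights = -heights
        lo, hi = heights.min(), heights.max()
        if hi > lo:
            top = heights >= lo + (1.0 - model.hook_top_fraction) * (hi - lo)
            colors = cloud.colors.astype(np.int16)
            chroma = colors.max(axis=1) - colors.min(axis=1)
            gray = chroma <= model.hook_chroma_tol
            labels[interior & top & gray] = LABEL_APPARATUS
    return PointCloud(cloud.points, cloud.colors, labels)


# ---------------------------------------------------------------------------
# similarity alignment to the canonical frame
# ---------------------------------------------------------------------------


def _umeyama(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping src landmarks onto dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.ones(3)
    d[-1] = sign
    rotation = u @ np.diag(d) @ vt
    var_s = (xs ** 2).sum() / len(src)
    if var_s <= 0:
        raise AlignmentError("landmarks are coincident (rank deficient)")
    scale = float((s * d).sum() / var_s)
    translation = mu_d - scale * rotation @ mu_s
    fit = SimilarityTransform(scale, rotation, translation)
    res = fit.apply_points(src) - dst
    fit.residual_rms = float(np.sqrt((res ** 2).sum(axis=1).mean()))
    return fit


def estimate_reference_transform(
    cloud: PointCloud,
    model: ChamberModel = DEFAULT_CHAMBER,
    *,
    plane_tol: float | None = None,
) -> SimilarityTransform:
    """Similarity transform taking a labeled scene into the canonical frame.

    The five checkerboard planes are recovered from the
    checkerboard-labeled points, their four board-wall-wall intersection
    corners are matched to the canonical corners over every
    correspondence (best Procrustes residual wins), and the hook
    (apparatus) centroid disambiguates the 180-degree symmetry of the
    rectangular footprint.  ``residual_rms`` on the result reports the
    landmark misfit.

    Raises
    ------
    AlignmentError
        If checkerboard points are absent, the plane set is degenerate,
        or the corner landmarks are rank deficient.
    """
    if cloud.labels is None or not (cloud.labels == LABEL_CHECKERBOARD).any():
        raise AlignmentError(
            "no checkerboard points labeled; alignment impossible"
        )
    ref = cloud.points[cloud.labels == LABEL_CHECKERBOARD]
    planes = extract_reference_planes(ref, tol=plane_tol)
    board, pair_a, pair_b = _chamber_structure(planes)

    corners = []
    for na, da, _ in pair_a:
        for nb2, db2, _ in pair_b:
            a = np.vstack([board[0], na, nb2])
            rhs = np.array([board[1], da, db2])
            if abs(np.linalg.det(a)) < 1e-6:
                raise AlignmentError("reference planes nearly parallel")
            corners.append(np.linalg.solve(a, rhs))
    corners = np.asarray(corners)
    # rank check: collinear landmarks cannot anchor a 3D similarity
    sv = np.linalg.svd(corners - corners.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise AlignmentError("corner landmarks are collinear (rank deficient)")

    canonical = model.corners()
    hook = None
    if (cloud.labels == LABEL_APPARATUS).any():
        hook = cloud.points[cloud.labels == LABEL_APPARATUS].mean(axis=0)
    hook_canon = np.asarray(model.hook_center)

    candidates = []
    for perm in itertools.permutations(range(4)):
        try:
            fit = _umeyama(corners[list(perm)], canonical)
        except AlignmentError:
            continue
        hook_err = (np.linalg.norm(fit.apply_points(hook[None])[0]
                                   - hook_canon)
                    if hook is not None else 0.0)
        candidates.append((fit.residual_rms, hook_err, fit))
    if not candidates:
        raise AlignmentError("no valid corner correspondence found")
    best_res = min(c[0] for c in candidates)
    span = float(np.linalg.norm(canonical.max(0) - canonical.min(0)))
    close = [c for c in candidates if c[0] <= best_res + 1e-6 * span]
    close.sort(key=lambda c: c[1])
    return close[0][2]


# ---------------------------------------------------------------------------
# voxelization and traits
# ---------------------------------------------------------------------------


@dataclass
class VoxelGrid:
    """Sparse occupancy grid over a bounding cube.

    ``indices`` holds the (i, j, k) of each filled voxel (a voxel is
    filled iff at least one point maps to it); ``mean_colors`` the
    arithmetic mean RGB of its member points.
    """

    cube: BoundingCube
    indices: np.ndarray
    mean_colors: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64).reshape(-1, 3)
        self.mean_colors = np.asarray(self.mean_colors, dtype=float).reshape(-1, 3)
        res = self.cube.resolution
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= res
        ):
            raise ValidationError("voxel indices out of grid bounds")
        if len(self.indices) != len(self.mean_colors):
            raise ValidationError("indices and mean_colors length mismatch")
        if self.mean_colors.size and (
            self.mean_colors.min() < 0 or self.mean_colors.max() > 255
        ):
            raise ValidationError("mean colors must lie in [0, 255]")

    @property
    def voxel_count(self) -> int:
        return len(self.indices)


@dataclass
class PanicleTraits:
    """Digital traits of one panicle x week.

    ``rg_ratio`` is the ratio of the red to the green color-intensity sum
    over filled voxels; ``None`` flags the undefined case (zero green sum).
    """

    voxel_count: int
    color_sum_r: float
    color_sum_g: float
    color_sum_b: float
    rg_ratio: float | None

    def require_rg_ratio(self) -> float:
        if self.rg_ratio is None:
            raise UndefinedTraitError(
                "R:G ratio undefined (green color sum is zero)"
            )
        return self.rg_ratio


def voxelize(cloud: PointCloud, cube: BoundingCube = DEFAULT_CUBE) -> VoxelGrid:
    """Bin points into the shared cube: half-open cells, floor indexing,
    points exactly on the max face clamped into the last voxel.

    Raises
    ------
    OutOfBoundsError
        Naming the first point outside the cube (signals failed alignment).
    """
    points = cloud.points
    lo = np.asarray(cube.min_corner, dtype=float)
    hi = lo + cube.edge
    if len(points):
        bad = np.any((points < lo) | (points > hi), axis=1)
        if bad.any():
            first = points[np.argmax(bad)]
            raise OutOfBoundsError(
                f"point {tuple(first)} lies outside the bounding cube "
                f"[{tuple(lo)} .. {tuple(hi)}] - check alignment"
            )
    res = cube.resolution
    idx = np.floor((points - lo) / cube.voxel_edge).astype(np.int64)
    np.clip(idx, 0, res - 1, out=idx)
    if len(points) == 0:
        return VoxelGrid(cube, np.empty((0, 3), dtype=np.int64),
                         np.empty((0, 3)))
    flat = (idx[:, 0] * res + idx[:, 1]) * res + idx[:, 2]
    uniq, inverse = np.unique(flat, return_inverse=True)
    counts = np.bincount(inverse)
    sums = np.zeros((len(uniq), 3))
    np.add.at(sums, inverse, cloud.colors.astype(float))
    mean_colors = sums / counts[:, None]
    indices = np.column_stack([uniq // (res * res),
                               (uniq // res) % res,
                               uniq % res])
    return VoxelGrid(cube, indices, mean_colors)


def extract_traits(grid: VoxelGrid) -> PanicleTraits:
    """Voxel count, per-channel color-intensity sums, and the R:G ratio."""
    sums = grid.mean_colors.sum(axis=0) if grid.voxel_count else np.zeros(3)
    ratio = float(sums[0] / sums[1]) if sums[1] > 0 else None
    return PanicleTraits(
        voxel_count=grid.voxel_count,
        color_sum_r=float(sums[0]),
        color_sum_g=float(sums[1]),
        color_sum_b=float(sums[2]),
        rg_ratio=ratio,
    )


def save_voxel_grid(grid: VoxelGrid, path: str | Path) -> Path:
    """Persist a sparse grid as CSV (i,j,k,r,g,b) with the cube spec in a
    leading comment line."""
    path = Path(path)
    cube = {"min_corner": list(grid.cube.min_corner),
            "edge": grid.cube.edge, "resolution": grid.cube.resolution}
    frame = pd.DataFrame(
        np.column_stack([grid.indices, grid.mean_colors]),
        columns=["i", "j", "k", "r", "g", "b"],
    )
    frame[["i", "j", "k"]] = frame[["i", "j", "k"]].astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# cube: {json.dumps(cube)}\n")
        frame.to_csv(fh, index=False)
    return path


def load_voxel_grid(path: str | Path) -> VoxelGrid:
    """Inverse of :func:`save_voxel_grid`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# cube:"):
            raise ValidationError(f"{path} lacks the cube spec comment line")
        spec = json.loads(first.split(":", 1)[1])
        frame = pd.read_csv(fh)
    cube = BoundingCube(tuple(spec["min_corner"]), spec["edge"],
                        spec["resolution"])
    return VoxelGrid(cube, frame[["i", "j", "k"]].to_numpy(),
                     frame[["r", "g", "b"]].to_numpy())


def session_traits(
    cloud: PointCloud,
    model: ChamberModel = DEFAULT_CHAMBER,
    cube: BoundingCube = DEFAULT_CUBE,
    *,
    out_dir: str | Path | None = None,
) -> PanicleTraits:
    """Full per-session pipeline: segment, align, voxelize, extract.

    If ``out_dir`` is given, the labeled cloud (PLY), the recovered
    transform (JSON) and the sparse voxel grid (CSV) are persisted there
    for audit.
    """
    from .io import write_point_cloud  # local import avoids cycle at load

    labeled = segment_components(cloud, model)
    transform = estimate_reference_transform(labeled, model)
    aligned = apply_transform(labeled, transform)
    panicle = aligned.select(aligned.labels == LABEL_PANICLE)
    grid = voxelize(panicle, cube)
    traits = extract_traits(grid)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_point_cloud(aligned, out / "aligned_labeled.ply")
        (out / "transform.json").write_text(json.dumps({
            "scale": transform.scale,
            "rotation": transform.rotation.tolist(),
            "translation": transform.translation.tolist(),
            "residual_rms": transform.residual_rms,
        }, indent=2))
        save_voxel_grid(grid, out / "voxel_grid.csv")
    return traits
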