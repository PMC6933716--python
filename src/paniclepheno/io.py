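"""Readers and writers for every external representation the pipeline touches.

Point clouds travel as PLY (the de-facto multi-view-stereo interchange
format): ASCII and binary little-endian are accepted on read, binary
little-endian is written by default.  Component labels (panicle /
checkerboard / apparatus) persist as an extra integer vertex property.
Trait tables are plain UTF-8 CSV keyed by (genotype, replicate, treatment,
week).
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, PLYParseError, ValidationError

# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

#: integer codes for the per-point component label
LABEL_UNASSIGNED = 0
LABEL_PANICLE = 1
LABEL_CHECKERBOARD = 2
LABEL_APPARATUS = 3
LABEL_NAMES = {
    LABEL_UNASSIGNED: "unassigned",
    LABEL_PANICLE: "panicle",
    LABEL_CHECKERBOARD: "checkerboard",
    LABEL_APPARATUS: "apparatus",
}


@dataclass
class PointCloud:
    """A colored 3D point cloud from one imaging session.

    Attributes
    ----------
    points : (N, 3) float64 array
        Coordinates in arbitrary reconstruction units until aligned.
    colors : (N, 3) uint8 array
        RGB in [0, 255].
    labels : (N,) uint8 array, optional
        Component tag per point (see ``LABEL_NAMES``); ``None`` means
        no segmentation has been attached.
    """

    points: np.ndarray
    colors: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        colors = np.asarray(self.colors)
        if colors.shape != self.points.shape:
            raise ValidationError(
                f"points and colors must have equal length: "
                f"{self.points.shape[0]} vs {colors.shape[0] if colors.ndim else 0}"
            )
        if colors.size and (colors.min() < 0 or colors.max() > 255):
            raise ValidationError("colors must lie in [0, 255]")
        self.colors = colors.astype(np.uint8)
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=np.uint8).ravel()
            if labels.shape[0] != self.points.shape[0]:
                raise ValidationError("labels must have one entry per point")
            self.labels = labels

    def __len__(self) -> int:
        return self.points.shape[0]

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Return the sub-cloud at boolean/integer index ``mask``."""
        return PointCloud(
            self.points[mask],
            self.colors[mask],
            None if self.labels is None else self.labels[mask],
        )


_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}

_COLOR_ALIASES = {"red": "red", "r": "red", "green": "green", "g": "green",
                  "blue": "blue", "b": "blue"}


def read_point_cloud(path: str | Path) -> PointCloud:
    """Read a colored PLY point cloud (ASCII or binary little-endian).

    Vertex order is preserved.  A ``label`` integer property, if present,
    is recovered as the component labels.

    Raises
    ------
    FormatError
        If a required color property is absent.
    PLYParseError
        On a malformed header or truncated body, with the byte offset.
    """
    raw = Path(path).read_bytes()
    if not raw.startswith(b"ply"):
        raise PLYParseError("not a PLY file (missing 'ply' magic)", 0)

    # -- header ------------------------------------------------------------
    end = raw.find(b"end_header")
    if end < 0:
        raise PLYParseError("header has no 'end_header' line", len(raw))
    body_start = raw.index(b"\n", end) + 1
    header = raw[:end].decode("ascii", errors="replace")

    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []  # (name, numpy dtype code)
    in_vertex = False
    offset = 0
    for line in header.splitlines():
        tokens = line.strip().split()
        if not tokens or tokens[0] == "comment":
            offset += len(line) + 1
            continue
        if tokens[0] == "format":
            if len(tokens) < 2 or tokens[1] not in (
                "ascii", "binary_little_endian"
            ):
                raise PLYParseError(
                    f"unsupported PLY format {tokens[1:2]}", offset
                )
            fmt = tokens[1]
        elif tokens[0] == "element":
            if tokens[1] == "vertex":
                if len(tokens) != 3 or not tokens[2].isdigit():
                    raise PLYParseError("malformed vertex element line", offset)
                n_vertex = int(tokens[2])
                in_vertex = True
            else:
                in_vertex = False
        elif tokens[0] == "property" and in_vertex:
            if tokens[1] == "list":
                raise PLYParseError(
                    "list properties on vertices are not supported", offset
                )
            if len(tokens) != 3 or tokens[1] not in _PLY_DTYPES:
                raise PLYParseError(
                    f"unknown property type {tokens[1]!r}", offset
                )
            props.append((tokens[2], _PLY_DTYPES[tokens[1]]))
        offset += len(line) + 1
    if fmt is None:
        raise PLYParseError("header missing 'format' line", 0)
    if n_vertex is None:
        raise PLYParseError("header has no vertex element", 0)

    names = [n for n, _ in props]
    for coord in "xyz":
        if coord not in names:
            raise FormatError(f"PLY vertex element lacks property {coord!r}")
    colmap: dict[str, str] = {}
    for name in names:
        canon = _COLOR_ALIASES.get(name.lower())
        if canon and canon not in colmap:
            colmap[canon] = name
    for canon in ("red", "green", "blue"):
        if canon not in colmap:
            raise FormatError(
                f"PLY vertex element lacks color property {canon!r}"
            )

    dtype = np.dtype([(n, "<" + c) for n, c in props])
    if fmt == "binary_little_endian":
        need = n_vertex * dtype.itemsize
        if len(raw) - body_start < need:
            raise PLYParseError(
                f"vertex data truncated: need {need} bytes", len(raw)
            )
        data = np.frombuffer(raw, dtype=dtype, count=n_vertex,
                             offset=body_start)
    else:
        text = raw[body_start:].decode("ascii", errors="replace")
        rows = [ln.split() for ln in text.splitlines() if ln.strip()]
        if len(rows) < n_vertex:
            raise PLYParseError(
                f"vertex data truncated: {len(rows)} of {n_vertex} rows",
                len(raw),
            )
        data = np.zeros(n_vertex, dtype=dtype)
        try:
            for i in range(n_vertex):
                row = rows[i]
                for (name, _), value in zip(props, row):
                    data[name][i] = float(value)
        except (ValueError, IndexError) as exc:
            raise PLYParseError(f"bad ASCII vertex row {i}: {exc}",
                                body_start) from None

    points = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    colors = np.column_stack(
        [data[colmap["red"]], data[colmap["green"]], data[colmap["blue"]]]
    )
    labels = data["label"].astype(np.uint8) if "label" in names else None
    return PointCloud(points, np.clip(colors, 0, 255), labels)


def write_point_cloud(
    cloud: PointCloud, path: str | Path, *, ascii: bool = False
) -> Path:
    """Write ``cloud`` as PLY; binary little-endian unless ``ascii``.

    Coordinates are stored as 32-bit floats (lossless round trip at
    float32 precision), colors exactly, labels (if any) as a uchar
    ``label`` property.
    """
    path = Path(path)
    n = len(cloud)
    have_labels = cloud.labels is not None
    header = ["ply",
              "format ascii 1.0" if ascii else "format binary_little_endian 1.0",
              "comment written by paniclepheno",
              f"element vertex {n}",
              "property float x", "property float y", "property float z",
              "property uchar red", "property uchar green", "property uchar blue"]
    if have_labels:
        header.append("property uchar label")
    header.append("end_header")

    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
              ("red", "u1"), ("green", "u1"), ("blue", "u1")]
    if have_labels:
        fields.append(("label", "u1"))
    data = np.zeros(n, dtype=np.dtype(fields))
    pts32 = cloud.points.astype(np.float32)
    data["x"], data["y"], data["z"] = pts32[:, 0], pts32[:, 1], pts32[:, 2]
    data["red"], data["green"], data["blue"] = (
        cloud.colors[:, 0], cloud.colors[:, 1], cloud.colors[:, 2])
    if have_labels:
        data["label"] = cloud.labels

    buf = _stdio.BytesIO()
    buf.write(("\n".join(header) + "\n").encode("ascii"))
    if ascii:
        for rec in data:
            vals = [repr(float(rec[k])) for k in ("x", "y", "z")]
            vals += [str(int(rec[k])) for k in ("red", "green", "blue")]
            if have_labels:
                vals.append(str(int(rec["label"])))
            buf.write((" ".join(vals) + "\n").encode("ascii"))
    else:
        buf.write(data.tobytes())
    path.write_bytes(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# imaging-session manifests
# ---------------------------------------------------------------------------

TREATMENTS = ("control", "HNT")


@dataclass
class SessionManifest:
    """One panicle x timepoint imaging session.

    The platform holds the panicle still while cameras rotate around it;
    each camera takes one frame every six degrees, so a session of two
    cameras yields 120 views.
    """

    panicle_id: str
    genotype: str
    treatment: str
    week: int
    n_cameras: int
    images_per_camera: int
    image_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.week <= 0:
            raise ValidationError("week must be positive")
        for name in ("n_cameras", "images_per_camera"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.image_paths and len(self.image_paths) != self.expected_images:
            raise ValidationError(
                f"manifest lists {len(self.image_paths)} images, expected "
                f"{self.expected_images}"
            )

    @property
    def expected_images(self) -> int:
        return self.n_cameras * self.images_per_camera


def build_imaging_manifest(
    n_panicles: int,
    n_timepoints: int,
    n_cameras: int,
    images_per_camera: int,
) -> tuple[list[SessionManifest], int]:
    """Enumerate all imaging sessions of a campaign and its total frame count.

    Returns one manifest per panicle x timepoint and the grand total
    ``n_panicles * n_timepoints * n_cameras * images_per_camera``.
    """
    for name, value in (("n_panicles", n_panicles),
                        ("n_timepoints", n_timepoints),
                        ("n_cameras", n_cameras),
                        ("images_per_camera", images_per_camera)):
        if not isinstance(value, (int, np.integer)) or value <= 0:
            raise ValidationError(f"{name} must be a positive integer")
    manifests = []
    for p in range(n_panicles):
        for w in range(1, n_timepoints + 1):
            paths = [
                f"P{p:03d}/week{w}/cam{c}_frame{f:03d}.png"
                for c in range(n_cameras)
                for f in range(images_per_camera)
            ]
            manifests.append(SessionManifest(
                panicle_id=f"P{p:03d}", genotype="NA", treatment="control",
                week=w, n_cameras=n_cameras,
                images_per_camera=images_per_camera, image_paths=paths,
            ))
    total = n_panicles * n_timepoints * n_cameras * images_per_camera
    return manifests, total


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

#: columns identifying one plant x timepoint observation
KEY_COLUMNS = ["genotype", "replicate", "treatment", "week"]

#: measured/derived trait columns (all optional; empty cell = missing)
TRAIT_COLUMNS = [
    "voxel_count", "color_sum_r", "color_sum_g", "color_sum_b", "rg_ratio",
    "pixel_count_2d", "projected_surface_area", "projected_seed_count",
    "seed_area", "seed_length", "seed_width",
    "total_seed_weight", "seed_number", "weight_per_seed", "fertility",
]

_NON_NEGATIVE = [
    "voxel_count", "color_sum_r", "color_sum_g", "color_sum_b",
    "pixel_count_2d", "projected_surface_area", "projected_seed_count",
    "seed_area", "seed_length", "seed_width",
    "total_seed_weight", "seed_number", "weight_per_seed",
]


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check key uniqueness and value ranges of a trait table.

    Returns the table unchanged on success.

    Raises
    ------
    IntegrityError
        Listing duplicated (genotype, replicate, treatment, week) keys,
        negative counts, or fertility outside [0, 100].
    """
    missing = [c for c in KEY_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrityError(f"trait table lacks key columns {missing}")
    dup = table.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        keys = table.loc[dup, KEY_COLUMNS].drop_duplicates()
        raise IntegrityError(
            "duplicate trait-table keys: "
            + "; ".join(str(tuple(r)) for r in keys.itertuples(index=False))
        )
    for col in _NON_NEGATIVE:
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise IntegrityError(f"negative values in column {col!r}")
    if "fertility" in table.columns:
        fert = pd.to_numeric(table["fertility"], errors="coerce").dropna()
        if ((fert < 0) | (fert > 100)).any():
            raise IntegrityError("fertility must lie in [0, 100]")
    return table


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trait-table CSV (UTF-8, '.' decimal)."""
    table = pd.read_csv(path)
    return validate_trait_table(table)


def write_trait_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Validate and write a trait table as CSV; lossless round trip."""
    validate_trait_table(table)
    path = Path(path)
    table.to_csv(path, index=False)
    return path
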