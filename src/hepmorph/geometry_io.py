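"""Readers and writers for outlines, volumes and feature tables.

Outlines follow the Fiji "save xy coordinates" dialect: one vertex per line,
two whitespace-separated numeric columns (x then y), image coordinates with y
increasing downward.  Under that convention a clockwise-drawn polygon has
positive shoelace area; loaded outlines are normalized to clockwise.

Physical units are µm throughout.  Because outline exports carry no scale
metadata, a ``pixel_size`` factor (µm per coordinate unit, default 1.0) is
applied at load time.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._errors import (
    MalformedOutlineError,
    OutlineParseError,
    VolumeFormatError,
)

log = logging.getLogger(__name__)

__all__ = [
    "PolygonOutline",
    "VolumeSpec",
    "FeatureTable",
    "read_outline_txt",
    "read_volume",
    "write_volume",
    "write_features",
    "read_features",
]


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed polygon area; positive = clockwise in image coordinates."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class PolygonOutline:
    """Closed 2D boundary of one organoid at one time point (µm)."""

    vertices: np.ndarray  # (n, 2) float array, implicitly closed
    label: str = ""
    time_h: float | None = None
    closed: bool = True
    clockwise: bool = True

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise MalformedOutlineError(
                f"outline needs >=3 (x, y) vertices, got array of shape {v.shape}"
            )
        if np.any(np.all(v == np.roll(v, -1, axis=0), axis=1)):
            raise MalformedOutlineError("two consecutive vertices are identical")
        area = shoelace_area(v)
        if area == 0.0:
            raise MalformedOutlineError("outline has zero signed area")
        if area < 0:  # counter-clockwise in image convention
            v = v[::-1].copy()
        self.vertices = v
        self.closed = True
        self.clockwise = True

    @property
    def area(self) -> float:
        """Enclosed area in µm²."""
        return abs(shoelace_area(self.vertices))

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid (µm)."""
        v = self.vertices
        w = v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1]
        a = w.sum() / 2.0
        cx = np.sum((v[:, 0] + np.roll(v[:, 0], -1)) * w) / (6.0 * a)
        cy = np.sum((v[:, 1] + np.roll(v[:, 1], -1)) * w) / (6.0 * a)
        return np.array([cx, cy])

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def max_radius(self) -> float:
        """Largest centroid-to-vertex distance (µm)."""
        d = self.vertices - self.centroid
        return float(np.hypot(d[:, 0], d[:, 1]).max())


@dataclass
class VolumeSpec:
    """Geometry of a 3D stack: shape in (z, y, x) voxels, isotropic voxel size in µm."""

    shape: tuple[int, int, int] | None = None
    voxel_size: float = 0.3
    channels: dict = field(default_factory=lambda: {"apical": 0, "cortical": 1})

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.shape is not None and any(s < 1 for s in self.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.shape}")


def read_outline_txt(
    path: str | Path,
    pixel_size: float = 1.0,
    label: str | None = None,
    time_h: float | None = None,
) -> PolygonOutline:
    """Load a two-column x,y outline text file as a clockwise closed polygon.

    A duplicate closing vertex (last line repeating the first) is dropped.
    Counter-clockwise files are reversed with a warning.  Blank lines are
    ignored; any other malformed line raises :class:`OutlineParseError`
    naming the line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 2:
                raise OutlineParseError(
                    f"{path.name}:{lineno}: expected two columns, got {len(toks)}"
                )
            try:
                rows.append((float(toks[0]), float(toks[1])))
            except ValueError as exc:
                raise OutlineParseError(
                    f"{path.name}:{lineno}: non-numeric token in {toks!r}"
                ) from exc
    if rows and rows[0] == rows[-1]:
        rows = rows[:-1]
    # drop consecutive duplicates (Fiji sometimes repeats a clicked vertex)
    dedup: list[tuple[float, float]] = []
    for r in rows:
        if not dedup or r != dedup[-1]:
            dedup.append(r)
    if len({tuple(r) for r in dedup}) < 3:
        raise MalformedOutlineError(
            f"{path.name}: fewer than 3 distinct vertices"
        )
    verts = np.asarray(dedup, dtype=float) * pixel_size
    if shoelace_area(verts) < 0:
        log.warning("%s: counter-clockwise outline, reversing to clockwise", path.name)
    return PolygonOutline(
        verts, label=label if label is not None else path.stem, time_h=time_h
    )


def read_volume(path: str | Path, spec: VolumeSpec | None = None) -> dict[str, np.ndarray]:
    """Read a multi-page grayscale TIFF as per-channel (z, y, x) arrays.

    A 3D stack with ``n`` declared channels is treated as plane-interleaved
    (z0c0, z0c1, z1c0, ...); a 4D stack is interpreted as (z, c, y, x) or
    (c, z, y, x), whichever matches the declared channel count.
    """
    spec = spec or VolumeSpec()
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # corrupt file, mismatched pages
        raise VolumeFormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    n_ch = len(spec.channels)
    names = sorted(spec.channels, key=spec.channels.get)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        if n_ch == 1:
            return {names[0]: arr}
        if arr.shape[0] % n_ch:
            raise VolumeFormatError(
                f"{path}: {arr.shape[0]} pages not divisible by {n_ch} channels"
            )
        return {nm: arr[i::n_ch] for i, nm in enumerate(names)}
    if arr.ndim == 4:
        if arr.shape[1] == n_ch:
            return {nm: arr[:, i] for i, nm in enumerate(names)}
        if arr.shape[0] == n_ch:
            return {nm: arr[i] for i, nm in enumerate(names)}
        raise VolumeFormatError(
            f"{path}: cannot locate a {n_ch}-channel axis in shape {arr.shape}; "
            "pass an explicit VolumeSpec"
        )
    raise VolumeFormatError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")


def write_volume(path: str | Path, channels: dict[str, np.ndarray] | np.ndarray) -> None:
    """Write one or more (z, y, x) channels as a plane-interleaved TIFF."""
    if isinstance(channels, np.ndarray):
        tifffile.imwrite(str(path), channels, photometric="minisblack")
        return
    arrs = list(channels.values())
    inter = np.stack(arrs, axis=1).reshape((-1,) + arrs[0].shape[1:])
    tifffile.imwrite(str(path), inter, photometric="minisblack")


class FeatureTable:
    """Per-structure feature rows plus list-valued branch diameters.

    Scalar fields live in a DataFrame (one row per structure); per-branch
    mean diameters are kept as lists and serialized to a long-format
    sidecar CSV keyed by structure id.
    """

    def __init__(self, rows: list[dict] | pd.DataFrame | None = None):
        if rows is None:
            rows = []
        if isinstance(rows, pd.DataFrame):
            self.frame = rows.copy()
        else:
            self.frame = pd.DataFrame(rows)

    def __len__(self) -> int:
        return len(self.frame)

    def validate(self) -> None:
        f = self.frame
        for col in ("largest_network_length_um",):
            if col in f and (f[col] < 0).any():
                raise ValueError(f"negative values in {col}")
        jc = [c for c in ("triple_junctions", "quadruple_junctions", "total_junctions") if c in f]
        for col in jc:
            vals = f[col].to_numpy()
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{col} must be non-negative integers")


def write_features(table: FeatureTable, path: str | Path, config: dict | None = None) -> None:
    """Write a feature table as CSV; diameters go to ``<stem>_diameters.csv``.

    A JSON echo of the resolved configuration is written next to the CSV.
    """
    if len(table) == 0:
        raise ValueError("feature table is empty")
    path = Path(path)
    table.validate()
    frame = table.frame
    list_cols = [
        c for c in frame.columns
        if frame[c].map(lambda v: isinstance(v, (list, tuple, np.ndarray))).any()
    ]
    frame.drop(columns=list_cols).to_csv(path, index=False)
    if list_cols:
        long_rows = []
        for _, row in frame.iterrows():
            for col in list_cols:
                for v in row[col]:
                    long_rows.append(
                        {"structure_id": row.get("structure_id", ""), "feature": col, "value": v}
                    )
        pd.DataFrame(long_rows).to_csv(path.with_name(path.stem + "_diameters.csv"), index=False)
    if config is not None:
        path.with_suffix(".config.json").write_text(json.dumps(config, indent=2, default=str))


def read_features(path: str | Path) -> FeatureTable:
    """Round-trip reader for :func:`write_features` main CSV."""
    return FeatureTable(pd.read_csv(path))
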