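"""Temporal shape scoring: descriptor distances, the d1/d0 distance ratio,
and clustering of organoid morphologies.

The descriptor of a shape lives on a (direction x threshold) grid; rotating
the shape by a multiple of the direction spacing permutes the rows cyclically,
so rotation invariance is obtained by minimizing the L2 distance over the D
cyclic shifts of one descriptor's direction axis.

For a time course, one raster window (sized to the largest frame) is shared
by all frames so that absolute compaction is preserved, and the rotational
alignment is estimated once on the first frame and frozen: an organoid's
orientation in the well is common to all frames, and re-aligning every frame
would absorb genuine shape change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._errors import IncompatibleDescriptorsError, InsufficientFramesError
from .ect import (
    DEFAULT_DIRECTIONS,
    DEFAULT_RESOLUTION,
    DEFAULT_THRESHOLDS,
    GridSpec,
    SECTDescriptor,
    ect,
    sect,
)
from .geometry_io import PolygonOutline

log = logging.getLogger(__name__)

__all__ = [
    "TemporalDescriptor",
    "TemporalShapeResult",
    "descriptor_distance",
    "build_timecourse",
    "distance_ratio",
    "pairwise_matrix",
    "cluster_shapes",
]


def _check_compatible(a: SECTDescriptor, b: SECTDescriptor) -> None:
    if a.grid_key() != b.grid_key():
        raise IncompatibleDescriptorsError(
            f"descriptor grids differ: {a.grid_key()} vs {b.grid_key()}"
        )


ALIGN_UPSAMPLE = 16  # sub-grid rotation search resolution, 1/16 of a step


def descriptor_distance(a: SECTDescriptor, b: SECTDescriptor, align: bool = False) -> float:
    """L2 distance between two descriptors under the grid measure.

    With ``align=True`` the distance is minimized over rotations of ``b``'s
    direction axis: the D cyclic shifts plus sub-grid rotations realized as
    band-limited (trigonometric) translation of the direction spectrum.
    Integer shifts are a subset of the search, so rotations by exact grid
    angles align perfectly.  The rotations form a group of isometries, so
    the aligned distance is symmetric and obeys the triangle inequality.
    """
    _check_compatible(a, b)
    if not align:
        return float(np.sqrt(a.measure * np.sum((a.s - b.s) ** 2)))
    # integer shifts evaluated directly, so grid-angle rotations (and the
    # identity) align to exact floating-point zero
    best = min(np.sum((a.s - np.roll(b.s, k, axis=0)) ** 2) for k in range(a.D))
    # sub-grid rotations: trigonometric interpolation of the circular
    # cross-correlation over the direction axis
    A = np.fft.rfft(a.s, axis=0)
    B = np.fft.rfft(b.s, axis=0)
    spec = (A * B.conj()).sum(axis=1)
    D = a.D
    up = ALIGN_UPSAMPLE
    padded = np.zeros(D * up // 2 + 1, dtype=complex)
    padded[: len(spec)] = spec
    if D % 2 == 0:
        padded[D // 2] *= 0.5  # split the Nyquist bin when zero-padding
    corr = np.fft.irfft(padded, n=D * up) * up
    frac = np.sum(a.s ** 2) + np.sum(b.s ** 2) - 2.0 * corr.max()
    best = min(best, max(frac, 0.0))
    return float(np.sqrt(a.measure * best))


@dataclass
class TemporalDescriptor:
    """Per-frame descriptors of one organoid's time course."""

    frames: list[SECTDescriptor]
    times_h: np.ndarray
    alignment_shift: int = 0
    label: str = ""

    def __post_init__(self):
        if len(self.frames) < 1:
            raise InsufficientFramesError("a time course needs at least one frame")
        keys = {f.grid_key() for f in self.frames}
        if len(keys) != 1:
            raise IncompatibleDescriptorsError(f"frames on mixed grids: {keys}")
        t = np.asarray(self.times_h, float)
        if len(t) != len(self.frames):
            raise ValueError("times_h length must match number of frames")
        if np.any(np.diff(t) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        self.times_h = t


@dataclass
class TemporalShapeResult:
    """d0, d1 and the distance ratio summarizing morphological change."""

    d0: float
    d1: float
    ratio: float
    interval_distances: np.ndarray
    label: str = ""
    mode: str = "endpoint"


def build_timecourse(
    outlines: list[PolygonOutline],
    grid: GridSpec | None = None,
    D: int = DEFAULT_DIRECTIONS,
    T: int = DEFAULT_THRESHOLDS,
    N: int = DEFAULT_RESOLUTION,
) -> TemporalDescriptor:
    """Compute one descriptor per frame on a common grid.

    The canonical alignment shift is the direction index of the first frame's
    largest row (by L2 norm); it is recorded once and rotates every frame so
    that descriptors from differently oriented organoids are comparable
    without per-frame re-alignment.
    """
    if not outlines:
        raise InsufficientFramesError("empty outline list")
    labels = {o.label.rsplit("_t", 1)[0] for o in outlines if o.label}
    if len(labels) > 1:
        raise ValueError(f"outlines carry inconsistent organoid labels: {labels}")
    if grid is None:
        grid = GridSpec.for_polygons(outlines, N=N)
    frames = [sect(ect(o, grid, D=D, T=T)) for o in outlines]
    shift = int(np.argmax(np.linalg.norm(frames[0].s, axis=1)))
    if shift:
        for f in frames:
            f.s = np.roll(f.s, -shift, axis=0)
    times = [o.time_h for o in outlines]
    if any(t is None for t in times):
        times = list(range(len(outlines)))
    label = labels.pop() if labels else ""
    return TemporalDescriptor(frames=frames, times_h=np.asarray(times, float),
                              alignment_shift=shift, label=label)


def distance_ratio(tc: TemporalDescriptor, mode: str = "endpoint",
                   eps: float = 1e-9) -> TemporalShapeResult:
    """DETECT distance ratio d1/d0 of a time course.

    d0 is the magnitude of the first frame's descriptor (its distance to the
    empty shape); d1 is the distance of the final frame to the first
    (``mode='endpoint'``, default) or the summed consecutive-interval
    distance (``mode='path'``).  A static series gives ratio 0; compaction
    grows d1 while d0 normalizes for organoid size.
    """
    if len(tc.frames) < 2:
        raise InsufficientFramesError(
            f"distance ratio needs >= 2 frames, got {len(tc.frames)}"
        )
    if mode not in ("endpoint", "path"):
        raise ValueError(f"unknown ratio mode {mode!r}")
    d0 = tc.frames[0].norm
    if d0 < eps:
        raise ValueError("degenerate (empty) first frame: d0 ~ 0, ratio undefined")
    intervals = np.array([
        descriptor_distance(tc.frames[k], tc.frames[k + 1])
        for k in range(len(tc.frames) - 1)
    ])
    if mode == "endpoint":
        d1 = descriptor_distance(tc.frames[-1], tc.frames[0])
    else:
        d1 = float(intervals.sum())
    return TemporalShapeResult(d0=d0, d1=d1, ratio=d1 / d0,
                               interval_distances=intervals,
                               label=tc.label, mode=mode)


def pairwise_matrix(descriptors: list[SECTDescriptor], align: bool = True) -> np.ndarray:
    """Symmetric matrix of (aligned) descriptor distances; zero diagonal."""
    n = len(descriptors)
    if n < 2:
        raise ValueError("need at least 2 descriptors")
    for d in descriptors[1:]:
        _check_compatible(descriptors[0], d)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = descriptor_distance(descriptors[i], descriptors[j],
                                                    align=align)
    return M


def cluster_shapes(matrix: np.ndarray, k: int = 2) -> np.ndarray:
    """Average-linkage hierarchical clustering of a distance matrix, cut at k.

    Returns integer labels 0..k-1, relabelled so that label order follows the
    lowest member index (deterministic for a given matrix).
    """
    matrix = np.asarray(matrix, float)
    n = matrix.shape[0]
    if k > n:
        raise ValueError(f"cannot cut {n} items into {k} clusters")
    if np.allclose(matrix, 0):
        warnings.warn("all pairwise distances are zero; cluster split is degenerate")
    Z = linkage(squareform(matrix, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:  # all-identical degenerate case: split by index
        raw = np.ones(n, int)
        raw[:n - k + 1] = 1
        raw[n - k + 1:] = np.arange(2, k + 1)
    # relabel by first occurrence for determinism
    out = np.empty(n, int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out
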