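"""Euler characteristic transform (ECT) and its smooth variant (SECT) in 2D.

A shape is rasterized onto a square window centered at its centroid and
interpreted as a cubical complex: each on-pixel is a 2-cell together with its
four edges and four vertices.  For a unit direction v, the height of a vertex
at position x is <x, v>; an edge or face enters the sublevel filtration at the
maximum height of its vertices (lower-star convention: vertices before edges
before faces at equal height).  The directional Euler characteristic curve is

    ECC_v(t) = chi({cells entering at height <= t})
             = #V(<=t) - #E(<=t) + #F(<=t),

evaluated on a common threshold grid spanning [-R, R].  The SECT centers each
curve to mean zero over thresholds and cumulatively integrates it, giving a
square-integrable signature that is translation-invariant (by centroid
centering) and turns rotation into a cyclic shift of the direction axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.integrate import cumulative_trapezoid
from shapely.geometry import Polygon as ShapelyPolygon

from ._errors import GeometryError, GridError
from .geometry_io import PolygonOutline

__all__ = [
    "GridSpec",
    "ECTMatrix",
    "SECTDescriptor",
    "rasterize_polygon",
    "euler_characteristic",
    "ecc_directional",
    "ect",
    "sect",
    "sect_from_polygon",
]

DEFAULT_DIRECTIONS = 72
DEFAULT_THRESHOLDS = 128
DEFAULT_RESOLUTION = 256
WINDOW_MARGIN = 1.25  # R = margin * max centroid-to-vertex distance


@dataclass(frozen=True)
class GridSpec:
    """Raster window: half-width ``R`` (µm) centered on the shape centroid,
    ``N`` pixels per side, pixel pitch ``2R/N``."""

    R: float
    N: int = DEFAULT_RESOLUTION

    def __post_init__(self):
        if self.R <= 0:
            raise GridError(f"window half-width R must be > 0, got {self.R}")
        if self.N < 16:
            raise GridError(f"raster resolution N must be >= 16, got {self.N}")

    @property
    def pitch(self) -> float:
        return 2.0 * self.R / self.N

    @classmethod
    def for_polygons(cls, polys: list[PolygonOutline], N: int = DEFAULT_RESOLUTION,
                     margin: float = WINDOW_MARGIN) -> "GridSpec":
        """Shared window sized to the largest shape of a series.

        A common R across a time course preserves absolute size change,
        which is the signal when scoring compaction.
        """
        rmax = max(p.max_radius() for p in polys)
        return cls(R=margin * rmax, N=N)


@dataclass
class ECTMatrix:
    """Integer Euler curves, one row per direction, on a common threshold grid."""

    chi: np.ndarray          # (D, T) int
    directions: np.ndarray   # (D, 2) unit vectors, angle 2*pi*d/D
    thresholds: np.ndarray   # (T,) uniform in [-R, R]
    R: float
    N: int
    label: str = ""

    @property
    def D(self) -> int:
        return self.chi.shape[0]

    @property
    def T(self) -> int:
        return self.chi.shape[1]


@dataclass
class SECTDescriptor:
    """Mean-centered, cumulatively integrated Euler curves (the shape signature)."""

    s: np.ndarray            # (D, T) float
    directions: np.ndarray
    thresholds: np.ndarray
    R: float
    N: int
    label: str = ""

    @property
    def D(self) -> int:
        return self.s.shape[0]

    @property
    def T(self) -> int:
        return self.s.shape[1]

    @property
    def measure(self) -> float:
        """Integration measure dtheta * dt of the (direction, threshold) grid."""
        dtheta = 2.0 * np.pi / self.D
        dt = self.thresholds[1] - self.thresholds[0]
        return dtheta * dt

    @property
    def norm(self) -> float:
        """L2 magnitude under the grid measure (distance to the empty shape)."""
        return float(np.sqrt(self.measure * np.sum(self.s ** 2)))

    def grid_key(self) -> tuple:
        return (self.D, self.T, round(self.R, 9))


def rasterize_polygon(poly: PolygonOutline, grid: GridSpec) -> np.ndarray:
    """Binary mask of the centroid-centered polygon; a pixel is on iff its
    center lies inside (even-odd rule)."""
    sp = ShapelyPolygon(poly.vertices)
    if not sp.is_valid:
        raise GeometryError(f"polygon {poly.label!r} is self-intersecting or degenerate")
    verts = poly.vertices - poly.centroid
    if np.abs(verts).max() >= grid.R:
        raise GridError(
            f"shape extent {np.abs(verts).max():.3g} µm does not fit in window "
            f"half-width R={grid.R:.3g} µm; increase R"
        )
    N, p = grid.N, grid.pitch
    centers = -grid.R + (np.arange(N) + 0.5) * p
    xx, yy = np.meshgrid(centers, centers)  # row=y, col=x
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = MplPath(verts).contains_points(pts)
    return inside.reshape(N, N)


def _cell_heights(mask: np.ndarray, direction: np.ndarray, grid: GridSpec):
    """Heights of vertices, edges and faces of the closed cubical complex.

    Returns three 1D arrays (may be empty).  Vertex positions are pixel
    corners of the physical window; higher cells take the max height of
    their vertices.
    """
    N, p = grid.N, grid.pitch
    corner = -grid.R + np.arange(N + 1) * p
    # vertex height grid H[i, j] = <corner position, direction>
    H = direction[1] * corner[:, None] + direction[0] * corner[None, :]

    von = np.zeros((N + 1, N + 1), bool)
    von[:-1, :-1] |= mask
    von[:-1, 1:] |= mask
    von[1:, :-1] |= mask
    von[1:, 1:] |= mask

    ehon = np.zeros((N + 1, N), bool)  # horizontal edges, between columns j, j+1
    ehon[:-1, :] |= mask
    ehon[1:, :] |= mask
    evon = np.zeros((N, N + 1), bool)  # vertical edges
    evon[:, :-1] |= mask
    evon[:, 1:] |= mask

    h_v = H[von]
    h_eh = np.maximum(H[:, :-1], H[:, 1:])[ehon]
    h_ev = np.maximum(H[:-1, :], H[1:, :])[evon]
    h_f = np.maximum(
        np.maximum(H[:-1, :-1], H[:-1, 1:]), np.maximum(H[1:, :-1], H[1:, 1:])
    )[mask]
    return h_v, np.concatenate([h_eh, h_ev]), h_f


def euler_characteristic(mask: np.ndarray) -> int:
    """chi = V - E + F of the cubical complex of on-pixels.

    Equals #(8-connected components) - #(4-connected enclosed holes).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return 0
    if mask.shape[0] != mask.shape[1] or mask.shape[0] < 16:
        # counts do not depend on geometry; pad into a square >= 16
        n = max(16, *mask.shape)
        padded = np.zeros((n, n), bool)
        padded[: mask.shape[0], : mask.shape[1]] = mask
        mask = padded
    grid = GridSpec(R=1.0, N=mask.shape[0])
    h_v, h_e, h_f = _cell_heights(mask, np.array([1.0, 0.0]), grid)
    return int(len(h_v) - len(h_e) + len(h_f))


def _check_unit(direction: np.ndarray) -> np.ndarray:
    direction = np.asarray(direction, float)
    if abs(np.hypot(direction[0], direction[1]) - 1.0) > 1e-12:
        raise ValueError(f"direction must be a unit vector, got {direction}")
    return direction


def ecc_directional(
    mask: np.ndarray, grid: GridSpec, direction: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """Euler characteristic curve of the directional sublevel filtration.

    ``curve[t]`` is chi of the subcomplex of cells whose (max-vertex) height
    is <= thresholds[t]; computed in one sorted sweep, so successive values
    share the nested subcomplexes of the filtration.
    """
    direction = _check_unit(direction)
    mask = np.asarray(mask, bool)
    thresholds = np.asarray(thresholds, float)
    if not mask.any():
        return np.zeros(len(thresholds), dtype=int)
    h_v, h_e, h_f = _cell_heights(mask, direction, grid)
    nv = np.searchsorted(np.sort(h_v), thresholds, side="right")
    ne = np.searchsorted(np.sort(h_e), thresholds, side="right")
    nf = np.searchsorted(np.sort(h_f), thresholds, side="right")
    return (nv - ne + nf).astype(int)


def triangulate_polygon(vertices: np.ndarray) -> np.ndarray:
    """Ear-clipping triangulation of a simple polygon.

    ``vertices`` is an (n, 2) array in positive (clockwise-in-image)
    orientation; returns (n-2, 3) vertex-index triples.  Deterministic and
    coordinate-frame equivariant: rotating the input rotates the triangles
    but leaves the combinatorics unchanged for shapes in general position.
    """
    v = np.asarray(vertices, float)
    n = len(v)
    if n < 3:
        raise GeometryError("cannot triangulate fewer than 3 vertices")

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    idx = list(range(n))
    tris = []
    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 4 * n * n:
            raise GeometryError("ear clipping failed; polygon may self-intersect")
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % m]
            a, b, c = v[i0], v[i1], v[i2]
            if cross(a, b, c) <= 0:  # reflex or degenerate corner
                continue
            # ear is valid if no other (reflex) vertex lies inside abc
            ear = True
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = v[j]
                if (cross(a, b, p) >= 0 and cross(b, c, p) >= 0
                        and cross(c, a, p) >= 0):
                    ear = False
                    break
            if ear:
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
        if not clipped:
            raise GeometryError("no ear found; polygon is not simple")
    tris.append(tuple(idx))
    return np.asarray(tris, int)


def _pl_chi_matrix(verts: np.ndarray, tris: np.ndarray,
                   directions: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Euler curves of the lower-star filtration of a triangulated polygon.

    Cell heights are the max of their vertex heights, so the sublevel
    complex at each threshold is exactly the PL region's sublevel set.
    """
    edges = set()
    for a, b, c in tris:
        edges.add((min(a, b), max(a, b)))
        edges.add((min(b, c), max(b, c)))
        edges.add((min(c, a), max(c, a)))
    e = np.asarray(sorted(edges), int)
    hv = verts @ directions.T                         # (V, D)
    he = np.maximum(hv[e[:, 0]], hv[e[:, 1]])          # (E, D)
    hf = np.maximum(np.maximum(hv[tris[:, 0]], hv[tris[:, 1]]),
                    hv[tris[:, 2]])                    # (F, D)
    D = directions.shape[0]
    chi = np.empty((D, len(thresholds)), dtype=int)
    hv_s, he_s, hf_s = np.sort(hv, 0), np.sort(he, 0), np.sort(hf, 0)
    for d in range(D):
        nv = np.searchsorted(hv_s[:, d], thresholds, side="right")
        ne = np.searchsorted(he_s[:, d], thresholds, side="right")
        nf = np.searchsorted(hf_s[:, d], thresholds, side="right")
        chi[d] = nv - ne + nf
    return chi


def ect(
    poly: PolygonOutline,
    grid: GridSpec,
    D: int = DEFAULT_DIRECTIONS,
    T: int = DEFAULT_THRESHOLDS,
    method: str = "exact",
) -> ECTMatrix:
    """Euler curves for D uniformly spaced directions on a common T-threshold grid.

    ``method='exact'`` (default) filters the centroid-centered polygon's own
    PL complex, which is free of pixelation artifacts and exactly
    rotation-equivariant at direction-grid angles; ``method='raster'``
    filters the cubical complex of the N x N rasterization instead.
    """
    if D < 8:
        raise ValueError(f"need D >= 8 directions, got {D}")
    if T < 32:
        raise ValueError(f"need T >= 32 thresholds, got {T}")
    angles = 2.0 * np.pi * np.arange(D) / D
    directions = np.column_stack([np.cos(angles), np.sin(angles)])
    thresholds = np.linspace(-grid.R, grid.R, T)
    if method == "raster":
        mask = rasterize_polygon(poly, grid)
        chi = np.empty((D, T), dtype=int)
        for d in range(D):
            chi[d] = ecc_directional(mask, grid, directions[d], thresholds)
    elif method == "exact":
        verts = poly.vertices - poly.centroid
        if np.hypot(verts[:, 0], verts[:, 1]).max() >= grid.R:
            raise GridError(
                f"shape of extent {np.hypot(verts[:, 0], verts[:, 1]).max():.3g} µm "
                f"does not fit in window half-width R={grid.R:.3g} µm; increase R"
            )
        tris = triangulate_polygon(verts)
        chi = _pl_chi_matrix(verts, tris, directions, thresholds)
    else:
        raise ValueError(f"unknown ect method {method!r}")
    return ECTMatrix(chi=chi, directions=directions, thresholds=thresholds,
                     R=grid.R, N=grid.N, label=poly.label)


def sect(m: ECTMatrix) -> SECTDescriptor:
    """Smooth the transform: center each Euler curve to threshold-mean zero,
    then cumulatively integrate it (trapezoid) over thresholds."""
    chi = m.chi.astype(float)
    centered = chi - chi.mean(axis=1, keepdims=True)
    s = cumulative_trapezoid(centered, m.thresholds, axis=1, initial=0.0)
    return SECTDescriptor(s=s, directions=m.directions, thresholds=m.thresholds,
                          R=m.R, N=m.N, label=m.label)


def sect_from_polygon(
    poly: PolygonOutline,
    grid: GridSpec | None = None,
    D: int = DEFAULT_DIRECTIONS,
    T: int = DEFAULT_THRESHOLDS,
    N: int = DEFAULT_RESOLUTION,
) -> SECTDescriptor:
    """Convenience: rasterize, transform and smooth one polygon."""
    if grid is None:
        grid = GridSpec.for_polygons([poly], N=N)
    return sect(ect(poly, grid, D=D, T=T))
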