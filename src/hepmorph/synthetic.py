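"""Synthetic inputs with known ground truth for every pipeline stage.

Organoid outlines come in two morphology families observed in hepatocyte
organoid cultures: smooth near-spherical shapes ("ball") and multi-lobed
folded shapes ("grape"), modelled as star-convex radial functions

    ball:   r(theta) = R (1 + eps * eta(theta))
    grape:  r(theta) = R (1 + a cos(k theta) + eps * eta(theta))

with eta a smooth periodic unit-amplitude noise field.  Time courses model
fibrotic compaction as a per-frame shrink of the radius with matching decay
of lobe amplitude (compaction = smaller and smoother).

Tube phantoms emulate membrane-stained bile canaliculi: the apical channel
carries a hollow shell around each centerline edge (the marker coats the
lumen wall), the cortical channel carries the same shells plus planar
cell-border sheets, both over dim background with additive Gaussian noise.
All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry_io import PolygonOutline, VolumeSpec
from .bcnet import TwoChannelVolume

__all__ = [
    "ShapeSpec",
    "PhantomGroundTruth",
    "gen_outline",
    "gen_timecourse",
    "random_tube_graph",
    "gen_tube_phantom",
    "gen_filter_fixture",
    "DEFAULT_TIMES_H",
]

# imaging schedule: first frame 2 h after assembly, then every 24 h for 2 days
DEFAULT_TIMES_H = (2.0, 26.0, 50.0)
# frame-to-frame jitter of an automated high-contrast boundary segmentation
# is sub-pixel: ~0.05 µm on a 50 µm organoid, i.e. 0.1% of the radius
DEFAULT_BOUNDARY_NOISE = 0.001
FOREGROUND = 280.0  # bright membrane signal
BACKGROUND = 100.0  # detector baseline + diffuse background


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic organoid outline."""

    family: str = "ball"          # 'ball' | 'grape'
    radius_um: float = 50.0
    lobes: int = 5                # k, grape only
    amplitude: float = 0.35       # a, grape only
    noise: float = DEFAULT_BOUNDARY_NOISE
    n_vertices: int = 360
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("ball", "grape"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 0 <= self.amplitude < 1:
            raise ValueError(
                f"lobe amplitude must be in [0, 1), got {self.amplitude} "
                "(>= 1 risks a self-intersecting boundary)"
            )
        if self.family == "grape" and self.lobes < 2:
            raise ValueError("grape shapes need k >= 2 lobes")


def _smooth_noise(theta: np.ndarray, rng: np.random.Generator,
                  n_modes: int = 8) -> np.ndarray:
    """Smooth periodic unit-amplitude noise from a few random Fourier modes."""
    eta = np.zeros_like(theta)
    amps = rng.normal(size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    for m, (A, ph) in enumerate(zip(amps, phases), start=1):
        eta += A * np.cos(m * theta + ph) / m
    peak = np.abs(eta).max()
    return eta / peak if peak > 0 else eta


def gen_outline(spec: ShapeSpec, label: str = "", time_h: float | None = None,
                phase: float = 0.0) -> PolygonOutline:
    """One clockwise outline from a shape spec; deterministic per seed.

    ``phase`` rotates the whole shape (radians), useful for rotation-
    invariance checks.
    """
    rng = np.random.default_rng(spec.seed)
    theta = np.linspace(0.0, 2 * np.pi, spec.n_vertices, endpoint=False)
    r = np.full_like(theta, spec.radius_um)
    if spec.family == "grape":
        r = r * (1 + spec.amplitude * np.cos(spec.lobes * theta))
    if spec.noise > 0:
        r = r + spec.radius_um * spec.noise * _smooth_noise(theta, rng)
    ang = theta + phase
    verts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return PolygonOutline(verts, label=label or f"{spec.family}_{spec.seed}",
                          time_h=time_h)


def gen_timecourse(
    spec: ShapeSpec,
    mode: str = "static",
    n_frames: int = 3,
    shrink: float = 0.15,
    seed: int | None = None,
    times_h: tuple[float, ...] | None = None,
) -> list[PolygonOutline]:
    """A per-frame outline series for one organoid.

    ``static`` re-noises the same base shape each frame (imaging and
    segmentation jitter without morphological change); ``compacting``
    scales the radius by (1 - shrink) per frame and decays the lobe
    amplitude by the same factor.
    """
    if n_frames < 2:
        raise ValueError("a time course needs >= 2 frames")
    if mode not in ("static", "compacting"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 <= shrink < 1:
        raise ValueError(f"per-frame shrink must be in [0, 1), got {shrink}")
    seed = spec.seed if seed is None else seed
    if times_h is None:
        times_h = (DEFAULT_TIMES_H if n_frames == len(DEFAULT_TIMES_H)
                   else tuple(2.0 + 24.0 * k for k in range(n_frames)))
    frames = []
    for k in range(n_frames):
        factor = (1.0 - shrink) ** k if mode == "compacting" else 1.0
        fspec = ShapeSpec(
            family=spec.family,
            radius_um=spec.radius_um * factor,
            lobes=spec.lobes,
            amplitude=spec.amplitude * factor,
            noise=spec.noise,
            n_vertices=spec.n_vertices,
            seed=seed * 1000 + k,  # fresh noise each frame
        )
        frames.append(gen_outline(fspec, label=f"org{seed}_t{k}",
                                  time_h=times_h[k]))
    return frames


@dataclass
class PhantomGroundTruth:
    """Known centerline graph of a tube phantom (coordinates in µm)."""

    nodes: dict[int, np.ndarray]           # node id -> (z, y, x) µm
    edges: list[tuple[int, int, float]]    # (node i, node j, tube radius µm)
    membrane_um: float = 0.6

    def edge_length(self, e: tuple[int, int, float]) -> float:
        return float(np.linalg.norm(self.nodes[e[0]] - self.nodes[e[1]]))

    @property
    def total_length_um(self) -> float:
        """Analytic centerline length, the sum over all edges."""
        return sum(self.edge_length(e) for e in self.edges)

    def junction_degrees(self) -> list[int]:
        """Valences of nodes with >= 3 incident edges."""
        val: dict[int, int] = {}
        for i, j, _ in self.edges:
            val[i] = val.get(i, 0) + 1
            val[j] = val.get(j, 0) + 1
        return [v for v in val.values() if v >= 3]

    @property
    def triple_junctions(self) -> int:
        return sum(1 for v in self.junction_degrees() if v == 3)

    @property
    def quadruple_junctions(self) -> int:
        return sum(1 for v in self.junction_degrees() if v == 4)

    def expected_diameters_um(self) -> list[float]:
        """Outer lumen diameter per branch as the apical marker presents it:
        tube radius plus half the membrane on either side, 2r + h."""
        return [2 * r + self.membrane_um for _, _, r in self.edges]


def random_tube_graph(
    n_edges: int = 10,
    seed: int = 0,
    box_um: float = 26.0,
    radius_um: tuple[float, float] | float = 1.0,
    margin_um: float = 3.0,
    min_junction_sep_um: float = 4.0,
    edge_len_um: tuple[float, float] = (5.0, 9.0),
    membrane_um: float = 0.6,
    clearance_um: float = 4.8,
) -> PhantomGroundTruth:
    """Random tree-structured centerline graph inside a cube, with junctions
    kept well separated and incident edges at wide angles so the skeleton
    topology is unambiguous.

    ``clearance_um`` is the minimum centerline distance between a new edge
    and every non-adjacent existing edge; it keeps tube surfaces from
    touching even after the completion step's inflations (2 x (r + h/2)
    plus two 3-voxel dilation layers).
    """
    rng = np.random.default_rng(seed)
    lo, hi = margin_um, box_um - margin_um
    if isinstance(radius_um, tuple):
        rad = lambda: float(rng.uniform(*radius_um))
    else:
        rad = lambda: float(radius_um)
    nodes = {0: rng.uniform(box_um * 0.4, box_um * 0.6, size=3)}
    edges: list[tuple[int, int, float]] = []
    valence = {0: 0}
    next_id = 1
    attempts = 0
    while len(edges) < n_edges and attempts < 20000:
        attempts += 1
        # favor branching off lower-valence nodes; cap valence at 4
        pool = [i for i, v in valence.items() if v < 4]
        base = int(rng.choice(pool))
        length = rng.uniform(*edge_len_um)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        new = nodes[base] + length * direction
        if np.any(new < lo) or np.any(new > hi):
            continue
        # angle policy: a second edge must continue nearly straight (gentle
        # bend, as real canaliculi do — sharp elbows weld shut during the
        # completion closing); further edges must leave every existing arm
        # at a wide angle so the junction stays compact
        ok = True
        arms = []
        for i, j, _ in edges:
            if base in (i, j):
                other = nodes[j] if i == base else nodes[i]
                u = other - nodes[base]
                arms.append(u / np.linalg.norm(u))
        max_cos = -0.766 if len(arms) == 1 else 0.26  # >=140 deg | >=75 deg
        for u in arms:
            if np.dot(u, direction) > max_cos:
                ok = False
                break
        if not ok:
            continue
        # keep the new node clear of all existing nodes, and the whole new
        # segment clear of every edge not incident to the base node
        for i, coord in nodes.items():
            if i != base and np.linalg.norm(new - coord) < min_junction_sep_um:
                ok = False
                break
        if ok:
            for i, j, _ in edges:
                if base in (i, j):
                    continue
                d = _segment_segment_dist(nodes[base], new, nodes[i], nodes[j])
                if d < clearance_um:
                    ok = False
                    break
        if not ok:
            continue
        nodes[next_id] = new
        valence[next_id] = 1
        valence[base] += 1
        edges.append((base, next_id, rad()))
        next_id += 1
    if len(edges) < n_edges:
        raise RuntimeError(
            f"could not place {n_edges} edges in a {box_um} µm box "
            f"(placed {len(edges)}); enlarge the box"
        )
    return PhantomGroundTruth(nodes=nodes, edges=edges, membrane_um=membrane_um)


def _point_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def _segment_segment_dist(p1, p2, q1, q2) -> float:
    """Minimum distance between segments p1p2 and q1q2 (dense sampling)."""
    t = np.linspace(0.0, 1.0, 48)
    A = p1[None] + t[:, None] * (p2 - p1)[None]
    B = q1[None] + t[:, None] * (q2 - q1)[None]
    return float(np.min(np.linalg.norm(A[:, None] - B[None, :], axis=-1)))


def _segment_distance_field(shape, voxel, a, b):
    """Distance (µm) from every voxel center in a bounding box to segment ab.

    Returns (slices, distance subarray) covering the capsule's bounding box.
    """
    pad = 6.0  # µm beyond the segment ends/extent
    lo = np.maximum(np.floor((np.minimum(a, b) - pad) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(a, b) + pad) / voxel).astype(int) + 1,
                    np.asarray(shape))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    zz = (np.arange(lo[0], hi[0]) + 0.5) * voxel
    yy = (np.arange(lo[1], hi[1]) + 0.5) * voxel
    xx = (np.arange(lo[2], hi[2]) + 0.5) * voxel
    P = np.stack(np.meshgrid(zz, yy, xx, indexing="ij"), axis=-1)
    ab = b - a
    denom = np.dot(ab, ab)
    t = np.clip(np.einsum("zyxc,c->zyx", P - a, ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    return sl, np.linalg.norm(P - closest, axis=-1)


def gen_tube_phantom(
    gt: PhantomGroundTruth,
    spec: VolumeSpec | None = None,
    box_um: float = 26.0,
    snr: float = 5.0,
    seed: int = 0,
    n_border_sheets: int = 2,
) -> TwoChannelVolume:
    """Render a ground-truth centerline graph as a noisy two-channel stack.

    Apical channel: hollow membrane shell (centerline distance within
    [r - h/2, r + h/2]) at bright intensity.  Cortical channel: the same
    shells plus ``n_border_sheets`` planar cell-border sheets.  Additive
    Gaussian noise with sigma = (foreground - background) / SNR.
    """
    spec = spec or VolumeSpec()
    vox = spec.voxel_size
    n = int(round(box_um / vox))
    shape = (n, n, n)
    dist = np.full(shape, np.inf)
    radmap = np.zeros(shape)
    for i, j, r in gt.edges:
        sl, d = _segment_distance_field(shape, vox, gt.nodes[i], gt.nodes[j])
        closer = d < dist[sl]
        dist[sl][closer] = d[closer]
        radmap[sl][closer] = r
    h = gt.membrane_um
    shell = (dist >= radmap - h / 2) & (dist <= radmap + h / 2) & (radmap > 0)

    sheets = np.zeros(shape, bool)
    rng = np.random.default_rng(seed)
    for k in range(n_border_sheets):
        axis = k % 3
        pos = int(rng.integers(n // 4, 3 * n // 4))
        idx = [slice(None)] * 3
        idx[axis] = slice(pos, pos + 2)
        sheets[tuple(idx)] = True

    sigma = (FOREGROUND - BACKGROUND) / snr
    apical = np.where(shell, FOREGROUND, BACKGROUND) + rng.normal(0, sigma, shape)
    cortical = (np.where(shell | sheets, FOREGROUND, BACKGROUND)
                + rng.normal(0, sigma, shape))
    apical = np.clip(apical, 0, 65535).astype(np.uint16)
    cortical = np.clip(cortical, 0, 65535).astype(np.uint16)
    return TwoChannelVolume(apical=apical, cortical=cortical,
                            spec=VolumeSpec(shape=shape, voxel_size=vox))


def gen_filter_fixture(shape=(40, 64, 64)) -> np.ndarray:
    """Fixed 5-component mask for the object filter: interior boxes of
    2000, 1500, 100 and 50 voxels plus a 3000-voxel box touching the y=0
    face."""
    m = np.zeros(shape, bool)
    m[5:15, 5:15, 5:25] = True        # 10*10*20 = 2000
    m[5:15, 20:30, 30:45] = True      # 10*10*15 = 1500
    m[20:25, 5:10, 5:9] = True        # 5*5*4   = 100
    m[20:25, 20:25, 30:32] = True     # 5*5*2   = 50
    m[25:35, 0:10, 34:64] = True      # 10*10*30 = 3000, touches y=0 face
    return m
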