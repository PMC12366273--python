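"""Ground-truthed synthetic inputs for exercising the pipeline end to end.

Real gradient-chip micrographs are not bundled with the package, so every
image-analysis stage is validated against synthetic data with known ground
truth instead:

* random planar vessel networks rendered as blurred noisy tubes, with the
  generating graph (node degrees, geometric length) as truth;
* brightfield-style lipid images of dark non-overlapping droplets at a known
  area fraction;
* time-lapse stacks whose network grows to a peak, partially regresses and
  plateaus — the rise / remodelling / maturation trajectory of in vitro
  vasculogenesis;
* analytic diffusion-decay test cases (pure decay, clamped steady state,
  reflection symmetry) with closed-form expectations.

All generators are pure functions of their spec and seed: repeated calls are
bit-identical.  Ground truth always comes from the generating geometry,
never from the rendered pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay
from scipy import ndimage

from .device import (ChannelSegment, ChipGeometry, FeedingSchedule,
                     GrowthFactor, MediaComposition, MediaEvent)
from .morphometry import ImageFrame
from .transport import Grid

__all__ = [
    "NetworkSpec",
    "GroundTruth",
    "PdeTestCase",
    "generate_network_image",
    "generate_lipid_image",
    "generate_vasculogenesis_timelapse",
    "generate_pde_testcase",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Recipe for one synthetic vessel-network image.

    ``n_seeds`` nodes are scattered with a minimum separation in a square
    domain of ``domain_um`` per side; edges are a spanning tree of the
    Delaunay triangulation plus a fraction ``extra_edge_fraction`` of the
    remaining (non-crossing) Delaunay edges, so junction/endpoint counts are
    controlled by graph topology alone.  Tubes are rendered at widths drawn
    uniformly from ``tube_width_um``, then blurred and corrupted with
    Gaussian and salt-and-pepper noise.
    """

    n_seeds: int = 12
    domain_um: float = 2000.0
    pixel_size: float = 4.0
    tube_width_um: tuple[float, float] = (14.0, 22.0)
    extra_edge_fraction: float = 0.25
    min_separation_um: float = 300.0
    background: int = 40
    foreground: int = 200
    blur_sigma_px: float = 1.2
    noise_sigma: float = 8.0
    salt_pepper_fraction: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 2:
            raise ValueError("need at least 2 seed nodes")
        if self.domain_um <= 4 * self.pixel_size:
            raise ValueError("degenerate domain: too small for the pixel size")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows about the image it rendered."""

    n_endpoints: int = 0
    n_junctions: int = 0
    geometric_length_mm: float = 0.0
    rendered_area_mm2: float = 0.0
    droplet_fraction_pct: float = 0.0
    node_positions: np.ndarray | None = None
    node_degrees: np.ndarray | None = None
    edges: tuple[tuple[int, int], ...] = ()
    tube_widths_um: tuple[float, ...] = ()
    trajectories: dict[str, np.ndarray] = field(default_factory=dict)


def _scatter_nodes(rng: np.random.Generator, spec: NetworkSpec) -> np.ndarray:
    """Rejection-sample node positions with a minimum pairwise separation."""
    margin = 0.08 * spec.domain_um
    pts: list[np.ndarray] = []
    sep = spec.min_separation_um
    attempts = 0
    while len(pts) < spec.n_seeds:
        p = rng.uniform(margin, spec.domain_um - margin, size=2)
        if all(np.hypot(*(p - q)) >= sep for q in pts):
            pts.append(p)
        attempts += 1
        if attempts > 20000:
            sep *= 0.8  # relax if the requested packing is infeasible
            attempts = 0
    return np.array(pts)


def _point_segment_dist(p: np.ndarray, q: np.ndarray, z: np.ndarray) -> float:
    d = q - p
    t = np.clip(np.dot(z - p, d) / np.dot(d, d), 0.0, 1.0)
    return float(np.hypot(*(z - (p + t * d))))


def _segment_segment_dist(p1, q1, p2, q2) -> float:
    # Delaunay edges never cross, so endpoint-to-segment distances suffice.
    return min(_point_segment_dist(p1, q1, p2), _point_segment_dist(p1, q1, q2),
               _point_segment_dist(p2, q2, p1), _point_segment_dist(p2, q2, q1))


def _network_edges(
    rng: np.random.Generator,
    points: np.ndarray,
    extra_fraction: float,
    max_width_um: float = 22.0,
) -> list[tuple[int, int]]:
    """Spanning tree of the Delaunay graph plus a random subset of its edges.

    Candidate edges that would render closer than a tube width to a
    non-incident node, or to a non-adjacent accepted edge, are rejected so
    that the rendered tubes only touch where the graph says they do — this
    keeps the graph's degree counts valid as image ground truth.
    """
    n = len(points)
    if n == 2:
        return [(0, 1)]
    tri = Delaunay(points)
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((int(simplex[a]), int(simplex[(a + 1) % 3])))
            pairs.add((i, j))
    pairs = sorted(pairs)
    w = [np.hypot(*(points[i] - points[j])) for i, j in pairs]
    graph = coo_matrix((w, tuple(zip(*pairs))), shape=(n, n))
    mst = minimum_spanning_tree(graph).tocoo()
    tree = {tuple(sorted((int(i), int(j)))) for i, j in zip(mst.row, mst.col)}
    rest = [p for p in pairs if p not in tree]
    n_extra = int(round(extra_fraction * len(rest)))
    candidates = sorted(tree)
    if n_extra and rest:
        idx = rng.choice(len(rest), size=min(n_extra, len(rest)), replace=False)
        candidates += [rest[i] for i in sorted(idx)]

    node_clear = 2.5 * max_width_um
    edge_clear = 2.0 * max_width_um
    min_angle = np.deg2rad(55.0)

    def angle_ok(i: int, j: int, accepted: list[tuple[int, int]]) -> bool:
        # tubes meeting at a node below ~55 deg merge into a blob whose
        # skeleton no longer reflects the graph
        for a, b in accepted:
            shared = {a, b} & {i, j}
            if len(shared) != 1:
                continue
            s = shared.pop()
            o1 = (({a, b} - {s}).pop(), ({i, j} - {s}).pop())
            v1 = points[o1[0]] - points[s]
            v2 = points[o1[1]] - points[s]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.arccos(np.clip(cosang, -1.0, 1.0)) < min_angle:
                return False
        return True

    accepted: list[tuple[int, int]] = []
    for i, j in candidates:
        p, q = points[i], points[j]
        ok = all(
            _point_segment_dist(p, q, points[k]) >= node_clear
            for k in range(n) if k not in (i, j))
        if ok:
            ok = all(
                _segment_segment_dist(p, q, points[a], points[b]) >= edge_clear
                for a, b in accepted if len({a, b, i, j}) == 4)
        if ok:
            ok = angle_ok(i, j, accepted)
        if ok:
            accepted.append((i, j))
    return accepted


def _render_tubes(
    points_um: np.ndarray,
    edges: list[tuple[int, int]],
    widths_um: np.ndarray,
    shape: tuple[int, int],
    pixel_size: float,
) -> np.ndarray:
    """Exact tube mask: pixels whose center lies within w/2 of an edge segment."""
    mask = np.zeros(shape, dtype=bool)
    for (i, j), w in zip(edges, widths_um):
        p, q = points_um[i] / pixel_size, points_um[j] / pixel_size
        r = 0.5 * w / pixel_size
        lo = np.floor(np.minimum(p, q) - r - 1).astype(int)
        hi = np.ceil(np.maximum(p, q) + r + 2).astype(int)
        lo = np.clip(lo, 0, None)
        hi[0] = min(hi[0], shape[1])
        hi[1] = min(hi[1], shape[0])
        if hi[0] <= lo[0] or hi[1] <= lo[1]:
            continue
        xs = np.arange(lo[0], hi[0]) + 0.5
        ys = np.arange(lo[1], hi[1]) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        d = q - p
        t = ((gx - p[0]) * d[0] + (gy - p[1]) * d[1]) / (d @ d)
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(gx - (p[0] + t * d[0]), gy - (p[1] + t * d[1]))
        mask[lo[1]:hi[1], lo[0]:hi[0]] |= dist <= r
    return mask


def generate_network_image(spec: NetworkSpec) -> tuple[ImageFrame, GroundTruth]:
    """Render one random planar vessel network and report its graph truth.

    Truth counts are the generating graph's degree-1 (endpoint) and
    degree->=3 (junction) node totals; geometric length is the summed edge
    length.  Rendered area is the pre-noise tube mask area.
    """
    rng = np.random.default_rng(spec.seed)
    points = _scatter_nodes(rng, spec)
    edges = _network_edges(rng, points, spec.extra_edge_fraction)
    widths = rng.uniform(*spec.tube_width_um, size=len(edges))

    npx = int(round(spec.domain_um / spec.pixel_size))
    mask = _render_tubes(points, edges, widths, (npx, npx), spec.pixel_size)

    img = np.full((npx, npx), float(spec.background))
    img[mask] = spec.foreground
    img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
    img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    n_sp = int(spec.salt_pepper_fraction * img.size)
    if n_sp:
        ii = rng.integers(0, npx, size=(2, n_sp))
        jj = rng.integers(0, npx, size=(2, n_sp))
        img[ii[0], ii[1]] = 255.0
        img[jj[0], jj[1]] = 0.0
    frame = ImageFrame(np.clip(img, 0, 255).astype(np.uint8), spec.pixel_size)

    degrees = np.zeros(len(points), dtype=int)
    for i, j in edges:
        degrees[i] += 1
        degrees[j] += 1
    length_mm = sum(
        np.hypot(*(points[i] - points[j])) for i, j in edges) / 1000.0
    truth = GroundTruth(
        n_endpoints=int((degrees == 1).sum()),
        n_junctions=int((degrees >= 3).sum()),
        geometric_length_mm=float(length_mm),
        rendered_area_mm2=float(mask.sum()) * (spec.pixel_size / 1000.0) ** 2,
        node_positions=points,
        node_degrees=degrees,
        edges=tuple(edges),
        tube_widths_um=tuple(float(w) for w in widths),
    )
    return frame, truth


def generate_lipid_image(
    target_fraction: float,
    droplet_radius_um: tuple[float, float] = (6.0, 16.0),
    seed: int = 0,
    *,
    size_px: int = 512,
    pixel_size: float = 2.0,
    background: int = 220,
    droplet_intensity: int = 60,
    blur_sigma_px: float = 0.8,
    noise_sigma: float = 5.0,
    max_attempts: int = 200000,
) -> tuple[ImageFrame, GroundTruth]:
    """Bright background with dark non-overlapping droplets at a known coverage.

    Disks are dart-thrown without overlap until the geometric pixel coverage
    reaches ``target_fraction`` percent (achieved within about one droplet
    area); the truth records the achieved fraction.  Targets beyond the
    non-overlapping packing limit (roughly 55-60%) raise after
    ``max_attempts`` placements fail.
    """
    if not (0 <= target_fraction <= 60):
        raise ValueError("target_fraction must lie in [0, 60] percent")
    rng = np.random.default_rng(seed)
    shape = (size_px, size_px)
    disk_mask = np.zeros(shape, dtype=bool)
    centers: list[tuple[float, float, float]] = []  # (x, y, r) in px
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    covered = 0
    target_px = target_fraction / 100.0 * disk_mask.size
    attempts = 0
    while covered < target_px:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not reach {target_fraction}% coverage with radii "
                f"{droplet_radius_um} in {max_attempts} attempts")
        r = rng.uniform(*droplet_radius_um) / pixel_size
        cx = rng.uniform(r, size_px - r)
        cy = rng.uniform(r, size_px - r)
        if any(np.hypot(cx - x, cy - y) < r + r0 + 1 for x, y, r0 in centers):
            continue
        centers.append((cx, cy, r))
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        disk_mask |= disk
        covered = int(disk_mask.sum())

    img = np.full(shape, float(background))
    img[disk_mask] = droplet_intensity
    img = ndimage.gaussian_filter(img, blur_sigma_px)
    img += rng.normal(0.0, noise_sigma, size=shape)
    frame = ImageFrame(np.clip(img, 0, 255).astype(np.uint8), pixel_size)
    truth = GroundTruth(
        droplet_fraction_pct=100.0 * covered / disk_mask.size,
    )
    return frame, truth


def generate_vasculogenesis_timelapse(
    phases: tuple[float, float, float] = (0.5 * 86400, 3.5 * 86400, 3.0 * 86400),
    frame_interval: float = 1800.0,
    seed: int = 0,
    *,
    spec: NetworkSpec | None = None,
    plateau_retention: float = 0.6,
) -> tuple[list[ImageFrame], GroundTruth]:
    """Time-lapse stack following the rise / remodelling / plateau trajectory.

    A master network is grown edge by edge over the rise phase (peak network
    at the rise/decline boundary), pruned back to ``plateau_retention`` of
    its edges over the decline phase, then held constant.  The per-frame
    ground-truth trajectories (junctions, endpoints, length in mm) come from
    each frame's subgraph.  Frame count is ``floor(total/interval) + 1``
    (both endpoints sampled).
    """
    rise, decline, plateau = phases
    if min(rise, decline, plateau) <= 0:
        raise ValueError("phase durations must be positive")
    if spec is None:
        spec = NetworkSpec(n_seeds=10, domain_um=1600.0, pixel_size=8.0,
                           min_separation_um=260.0, seed=seed)
    rng = np.random.default_rng(spec.seed + 1)
    points = _scatter_nodes(np.random.default_rng(spec.seed), spec)
    edges = _network_edges(np.random.default_rng(spec.seed), points,
                           spec.extra_edge_fraction)
    widths = np.random.default_rng(spec.seed).uniform(
        *spec.tube_width_um, size=len(edges))
    order = rng.permutation(len(edges))

    total = rise + decline + plateau
    n_frames = int(np.floor(total / frame_interval + 1e-9)) + 1
    times = np.arange(n_frames) * frame_interval
    n_edges = len(edges)
    n_plateau = max(1, int(round(plateau_retention * n_edges)))

    def edge_count(t: float) -> int:
        if t <= rise:
            return max(1, int(round(n_edges * t / rise)))
        if t <= rise + decline:
            frac = (t - rise) / decline
            return int(round(n_edges - frac * (n_edges - n_plateau)))
        return n_plateau

    npx = int(round(spec.domain_um / spec.pixel_size))
    frames: list[ImageFrame] = []
    traj = {k: np.zeros(n_frames) for k in
            ("n_junctions", "n_endpoints", "total_length_mm")}
    noise_rng = np.random.default_rng(spec.seed + 2)
    for fi, t in enumerate(times):
        m = edge_count(float(t))
        sub = [edges[i] for i in order[:m]]
        sub_w = widths[order[:m]]
        mask = _render_tubes(points, sub, sub_w, (npx, npx), spec.pixel_size)
        img = np.full((npx, npx), float(spec.background))
        img[mask] = spec.foreground
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
        img += noise_rng.normal(0.0, spec.noise_sigma, size=img.shape)
        frames.append(ImageFrame(np.clip(img, 0, 255).astype(np.uint8),
                                 spec.pixel_size, timestamp=float(t)))
        deg = np.zeros(len(points), dtype=int)
        for i, j in sub:
            deg[i] += 1
            deg[j] += 1
        traj["n_junctions"][fi] = (deg >= 3).sum()
        traj["n_endpoints"][fi] = (deg == 1).sum()
        traj["total_length_mm"][fi] = sum(
            np.hypot(*(points[i] - points[j])) for i, j in sub) / 1000.0
    truth = GroundTruth(
        node_positions=points,
        edges=tuple(edges),
        trajectories={"times_s": times, **traj},
    )
    return frames, truth


@dataclass(frozen=True)
class PdeTestCase:
    """A simulator configuration paired with its closed-form expectation."""

    kind: str
    factor: GrowthFactor
    geometry: ChipGeometry
    grid: Grid
    schedule: FeedingSchedule
    duration: float
    snapshot_interval: float
    initial: float
    clamp_boundaries: bool
    expected: Callable[[np.ndarray], np.ndarray]
    mirror_geometry: ChipGeometry | None = None

    def describe(self) -> str:
        return {
            "pure_decay": "uniform field halving every half-life, no transport",
            "steady_uniform": "long-time uniform field at the clamped boundary value",
            "reflection_symmetry": "left-fed field mirrors the right-fed field",
        }[self.kind]


NO_DECAY = 1e30  # s; half-life so long the decay factor is 1.0 in float64


def generate_pde_testcase(kind: str) -> PdeTestCase:
    """Analytic diffusion-decay cases: ``pure_decay``, ``steady_uniform``,
    ``reflection_symmetry``.

    Each case returns a small, fast simulator configuration together with a
    callable mapping snapshot times (s) to the expected uniform cell value;
    the symmetry case instead pairs a left-fed geometry with its mirrored
    right-fed counterpart and expects mirrored fields.
    """
    geometry = ChipGeometry(length=2.0, width=1.0, channel_segment_length=0.8)
    grid = Grid(spacing=0.1, nx=20, ny=10)
    media = MediaComposition("test", {"X": 10.0})
    schedule = FeedingSchedule(
        (MediaEvent(0.0, ("left", "right"), "full", media),), duration=2 * 86400.0)

    if kind == "pure_decay":
        factor = GrowthFactor("X", 10.0, 1000.0, 1e-9, 3600.0, 1.0)
        return PdeTestCase(
            kind=kind, factor=factor, geometry=geometry, grid=grid,
            schedule=schedule, duration=2 * 3600.0, snapshot_interval=600.0,
            initial=10.0, clamp_boundaries=False,
            expected=lambda t: 10.0 * 2.0 ** (-np.asarray(t) / 3600.0),
        )
    if kind == "steady_uniform":
        # both long edges fully clamped: steady state is the boundary value
        geom = ChipGeometry(length=2.0, width=0.4, channel_segment_length=1.0,
                            segments=(ChannelSegment("top", "left", "left"),
                                      ChannelSegment("bottom", "left", "left"),
                                      ChannelSegment("top", "right", "right"),
                                      ChannelSegment("bottom", "right", "right")))
        factor = GrowthFactor("X", 10.0, 1000.0, 400.0, NO_DECAY, 1.0)
        return PdeTestCase(
            kind=kind, factor=factor, geometry=geom,
            grid=Grid(spacing=0.1, nx=20, ny=4),
            schedule=schedule, duration=6 * 3600.0, snapshot_interval=3600.0,
            initial=0.0, clamp_boundaries=True,
            expected=lambda t: np.full_like(np.asarray(t, dtype=float), 10.0),
        )
    if kind == "reflection_symmetry":
        left_only = ChipGeometry(
            length=2.0, width=1.0, channel_segment_length=0.8,
            segments=(ChannelSegment("top", "left", "left"),
                      ChannelSegment("bottom", "left", "left")))
        right_only = ChipGeometry(
            length=2.0, width=1.0, channel_segment_length=0.8,
            segments=(ChannelSegment("top", "right", "right"),
                      ChannelSegment("bottom", "right", "right")))
        factor = GrowthFactor("X", 10.0, 1000.0, 150.0, 7200.0, 1.0)
        return PdeTestCase(
            kind=kind, factor=factor, geometry=left_only, grid=grid,
            schedule=schedule, duration=4 * 3600.0, snapshot_interval=1800.0,
            initial=0.0, clamp_boundaries=True,
            expected=lambda t: np.asarray(t),  # unused: expectation is the mirror
            mirror_geometry=right_only,
        )
    raise ValueError(f"unknown test-case kind {kind!r}")
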