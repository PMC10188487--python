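"""Synthetic inputs with known ground truth for every pipeline stage.

Real gastrulation movies and confocal stacks are not distributable at
test scale, so each stage is exercised on generated data that emulates
the relevant structure:

* correlated-random-walk nuclei trajectories imaged every 4 minutes at
  0.189 µm/px, rendered as Gaussian spots over noise;
* star-shaped cell masks with a known number of protrusions, for the
  opening-subtraction filopodia operator;
* voxelized ellipsoidal nuclei at 0.132 × 0.132 × 0.24 µm voxels, with
  known axes, flatness and volume;
* two-rate Poisson point fields with a region mask, for the 5-NN
  density statistic;
* line-segment "focal adhesion" images with known total length;
* a single-chromosome genome fixture (genes, peaks, DEG labels) with a
  controllable enrichment factor for the peak-to-gene overlap test.

All generators are pure functions of their parameters and seed, and the
ground truth they return is sufficient to score the downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry2d import CellMask
from .morphometry3d import VoxelGrid3D
from .neighborhood import CentroidField, RegionMask
from .tracking import Trajectory

__all__ = [
    "TrackSimParams",
    "ImageRenderParams",
    "simulate_persistent_tracks",
    "render_timelapse",
    "make_star_cell",
    "make_ellipsoid_stack",
    "make_point_field",
    "make_fa_pattern",
    "make_genome_fixture",
]

SIGMA_MAX = np.pi  # heading dispersion at persistence 0


@dataclass(frozen=True)
class TrackSimParams:
    """Correlated-random-walk parameters for simulated nuclei tracks.

    ``persistence_p`` in [0, 1] sets the dispersion of the per-step
    heading change, Normal(0, pi * (1 - p)): p = 1 walks straight,
    p = 0 re-draws the heading almost uniformly each step.  Defaults
    emulate an 8 h movie at 4 min/frame with ~1 µm/min cells in a
    400 × 400 µm field.
    """

    n_tracks: int = 200
    n_steps: int = 120          # 8 h at 4 min per frame
    dt_min: float = 4.0
    speed_um_min: float = 1.0
    persistence_p: float = 0.5
    drift_um_min: tuple[float, float] = (0.0, 0.0)
    arena_um: tuple[float, float] = (400.0, 400.0)
    start_spacing_um: float | None = None  # jittered-grid starts if set
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.persistence_p <= 1.0:
            raise ValueError("persistence_p must lie in [0, 1]")
        if self.n_steps < 1 or self.n_tracks < 0:
            raise ValueError("counts must be positive")
        if self.speed_um_min < 0 or self.dt_min <= 0:
            raise ValueError("speed must be >= 0 and dt > 0")
        vals = (self.speed_um_min, self.dt_min, *self.drift_um_min,
                *self.arena_um, self.persistence_p)
        if not np.all(np.isfinite(vals)):
            raise ValueError("parameters must be finite")
        if min(self.arena_um) <= 0:
            raise ValueError("arena must have positive extent")


@dataclass(frozen=True)
class ImageRenderParams:
    """Rendering calibration for synthetic microscopy images."""

    shape_px: tuple = (512, 512)
    pixel_size_um: float = 0.189
    voxel_depth_um: float = 0.24
    blob_sigma_px: float = 3.0
    amplitude: float = 1.0
    background_level: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.shape_px) <= 0 or self.pixel_size_um <= 0 \
                or self.voxel_depth_um <= 0 or self.blob_sigma_px <= 0:
            raise ValueError("sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _fold(x: np.ndarray, width: float) -> np.ndarray:
    """Reflect coordinates into [0, width] (triangular-wave folding).

    Because step increments do not depend on position, folding the
    unreflected cumulative path is exactly equivalent to reflecting the
    walk at the boundary step by step.
    """
    period = 2.0 * width
    y = np.mod(x, period)
    return width - np.abs(width - y)


def simulate_persistent_tracks(params: TrackSimParams) -> list[Trajectory]:
    """Simulate correlated random walks in a reflecting rectangular arena.

    Start positions are uniform over the arena, start headings uniform
    on the circle; each subsequent heading is the previous one plus a
    Normal(0, pi * (1 - persistence_p)) increment.  Drift is added per
    step and positions are reflected at the arena boundary.  The same
    seed reproduces the same tracks bit for bit.
    """
    rng = np.random.default_rng(params.seed)
    n, m = params.n_tracks, params.n_steps
    if n == 0:
        return []
    w, h = params.arena_um
    sigma = SIGMA_MAX * (1.0 - params.persistence_p)

    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    dtheta = (rng.normal(0.0, sigma, size=(n, m - 1))
              if (m > 1 and sigma > 0) else np.zeros((n, max(m - 1, 0))))
    theta = theta0[:, None] + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(dtheta, axis=1)], axis=1)

    step = params.speed_um_min * params.dt_min
    drift = np.asarray(params.drift_um_min) * params.dt_min
    steps = np.stack([step * np.cos(theta) + drift[0],
                      step * np.sin(theta) + drift[1]], axis=-1)

    if params.start_spacing_um:
        # nuclei in tissue exclude volume: jittered-grid starts avoid the
        # coincident starts a uniform draw produces
        s = params.start_spacing_um
        gx = np.arange(s / 2, w, s)
        gy = np.arange(s / 2, h, s)
        grid = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)
        if len(grid) < n:
            raise ValueError("arena too small for n_tracks at this spacing")
        idx = rng.choice(len(grid), size=n, replace=False)
        start = grid[idx] + rng.uniform(-s / 4, s / 4, size=(n, 2))
        start = np.clip(start, 0, [w, h])
    else:
        start = np.stack([rng.uniform(0, w, size=n),
                          rng.uniform(0, h, size=n)], axis=-1)
    raw = np.concatenate([start[:, None, :],
                          start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    xy = np.stack([_fold(raw[..., 0], w), _fold(raw[..., 1], h)], axis=-1)

    frames = np.arange(m + 1)
    t = frames * params.dt_min
    return [Trajectory(track_id=i, frames=frames, t_min=t, xy_um=xy[i])
            for i in range(n)]


def render_timelapse(tracks: list[Trajectory], params: ImageRenderParams
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render tracks as Gaussian spots, one frame per time point.

    Returns the float stack (frames, rows, cols) and the ground-truth
    centroid table (track_id, frame, t_min, x_um, y_um).  Tracks must
    share a common frame/time base.
    """
    rows, cols = params.shape_px[-2:]
    if tracks:
        base = tracks[0]
        for tr in tracks[1:]:
            if len(tr) != len(base) or np.any(tr.frames != base.frames) \
                    or not np.allclose(tr.t_min, base.t_min):
                raise ValueError("tracks have mismatched time bases")
        n_frames = len(base)
        frames, t_min = base.frames, base.t_min
    else:
        n_frames, frames, t_min = 1, np.array([0]), np.array([0.0])

    rng = np.random.default_rng(params.seed)
    stack = np.full((n_frames, rows, cols), params.background_level,
                    dtype=float)
    sig = params.blob_sigma_px
    half = int(np.ceil(4 * sig))
    truth = []
    for tr in tracks:
        for k in range(n_frames):
            x_um, y_um = tr.xy_um[k]
            cx, cy = x_um / params.pixel_size_um, y_um / params.pixel_size_um
            r0, r1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
            c0, c1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
            r0c, r1c = max(r0, 0), min(r1, rows)
            c0c, c1c = max(c0, 0), min(c1, cols)
            if r0c >= r1c or c0c >= c1c:
                continue
            yy, xx = np.mgrid[r0c:r1c, c0c:c1c]
            stack[k, r0c:r1c, c0c:c1c] += params.amplitude * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2))
            truth.append((tr.track_id, int(frames[k]), float(t_min[k]),
                          float(x_um), float(y_um)))
    if params.noise_sd > 0:
        stack += rng.normal(0.0, params.noise_sd, size=stack.shape)
    truth_df = pd.DataFrame(truth, columns=["track_id", "frame", "t_min",
                                            "x_um", "y_um"])
    return stack, truth_df


# ---------------------------------------------------------------------------
# 2D cell fixture
# ---------------------------------------------------------------------------

def make_star_cell(base_radius_um: float = 5.0, n_spikes: int = 6,
                   spike_len_um: float = 1.5, spike_width_um: float = 0.4,
                   pixel_size_um: float = 0.1, seed: int = 0
                   ) -> tuple[CellMask, dict]:
    """Disk-shaped cell with thin radial protrusions.

    Spikes are rectangles of length ``spike_len_um`` beyond the disk rim
    and width ``spike_width_um``, evenly spaced with a seeded random
    angular offset.  Spike width must stay below the 2.2 µm opening disk
    diameter so the filopodia operator removes them.  Returns the mask
    plus ground truth: spike count, nominal per-spike area, and how many
    spikes exceed the 0.077 µm² gate.
    """
    if spike_width_um >= 2 * 1.1:
        raise ValueError("spikes wider than the 2.2 µm opening disk "
                         "would survive the opening; invalid fixture")
    if n_spikes < 0:
        raise ValueError("n_spikes must be >= 0")
    if n_spikes > 0:
        # reject overlapping spikes: angular footprint vs spacing
        ang_half = np.arcsin(min(1.0, (spike_width_um / 2) / base_radius_um))
        if 2 * np.pi / n_spikes <= 2.2 * ang_half:
            raise ValueError("spike geometry overlaps; invalid fixture")

    rng = np.random.default_rng(seed)
    offset = rng.uniform(0, 2 * np.pi)
    extent_um = base_radius_um + spike_len_um + 1.0
    half_px = int(np.ceil(extent_um / pixel_size_um))
    size = 2 * half_px + 1
    yy, xx = (np.mgrid[:size, :size] - half_px) * pixel_size_um
    rr = np.hypot(xx, yy)
    mask = rr <= base_radius_um

    for i in range(n_spikes):
        phi = offset + 2 * np.pi * i / max(n_spikes, 1)
        u = xx * np.cos(phi) + yy * np.sin(phi)      # along spike axis
        v = -xx * np.sin(phi) + yy * np.cos(phi)     # across
        spike = ((u >= base_radius_um * 0.8)
                 & (u <= base_radius_um + spike_len_um)
                 & (np.abs(v) <= spike_width_um / 2))
        mask |= spike

    spike_area = spike_len_um * spike_width_um
    truth = {
        "n_spikes": n_spikes,
        "spike_area_um2": spike_area if n_spikes else 0.0,
        "n_above_gate": n_spikes if spike_area > 0.077 else 0,
    }
    return CellMask(mask, pixel_size_um), truth


# ---------------------------------------------------------------------------
# 3D nucleus fixture
# ---------------------------------------------------------------------------

def _rotation_matrix(angles_deg: tuple[float, float, float]) -> np.ndarray:
    """Rotation composed of rotations about the z, y, x axes (degrees)."""
    az, ay, ax = np.deg2rad(angles_deg)
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rz @ ry @ rx


def make_ellipsoid_stack(semi_axes_um: tuple[float, float, float] = (4.0, 3.0, 1.5),
                         orientation_deg: tuple[float, float, float] = (0, 0, 0),
                         render: ImageRenderParams | None = None
                         ) -> tuple[VoxelGrid3D, dict]:
    """Voxelized solid ellipsoid in an anisotropic grid, plus ground truth.

    Semi-axes must satisfy a >= b >= c and c must span more than two
    voxels along every grid axis.  Ground truth records the sorted axes,
    flatness b/c, and analytic volume; these are rotation-invariant by
    construction.
    """
    if render is None:
        planes = int(np.ceil(2.2 * max(semi_axes_um) / 0.24)) + 8
        rc = int(np.ceil(2.2 * max(semi_axes_um) / 0.132)) + 8
        render = ImageRenderParams(shape_px=(planes, rc, rc),
                                   pixel_size_um=0.132, voxel_depth_um=0.24)
    a, b, c = semi_axes_um
    if not a >= b >= c > 0:
        raise ValueError("require a >= b >= c > 0")
    voxel = (render.voxel_depth_um, render.pixel_size_um, render.pixel_size_um)
    if c <= 2 * max(voxel):
        raise ValueError("smallest semi-axis must exceed 2 voxels per axis")
    shape = render.shape_px
    if len(shape) != 3:
        raise ValueError("render.shape_px must be (planes, rows, cols)")
    half_um = np.asarray(shape) * np.asarray(voxel) / 2.0
    if np.any(a >= half_um):
        raise ValueError("ellipsoid exceeds the grid")

    zz, yy, xx = np.mgrid[:shape[0], :shape[1], :shape[2]].astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    phys = np.stack([
        (xx - center[2]) * voxel[2],
        (yy - center[1]) * voxel[1],
        (zz - center[0]) * voxel[0],
    ], axis=-1)
    rot = _rotation_matrix(orientation_deg)
    local = phys @ rot          # rotate coordinates into the ellipsoid frame
    inside = ((local[..., 0] / a) ** 2 + (local[..., 1] / b) ** 2
              + (local[..., 2] / c) ** 2) <= 1.0

    rng = np.random.default_rng(render.seed)
    vol = inside.astype(float) * render.amplitude + render.background_level
    if render.noise_sd > 0:
        vol += rng.normal(0.0, render.noise_sd, size=vol.shape)

    truth = {
        "semi_axes_um": (float(a), float(b), float(c)),
        "flatness": float(b / c),
        "volume_um3": float(4.0 / 3.0 * np.pi * a * b * c),
        "volume_voxels": int(inside.sum()),
    }
    return VoxelGrid3D(vol, voxel), truth


# ---------------------------------------------------------------------------
# point fields
# ---------------------------------------------------------------------------

def make_point_field(rate_per_um2_a: float = 0.005, rate_per_um2_b: float = 0.02,
                     region_split: float = 0.5,
                     extent_um: tuple[float, float] = (200.0, 200.0),
                     pixel_size_um: float = 0.26, seed: int = 0
                     ) -> tuple[CentroidField, RegionMask]:
    """Two-rate homogeneous Poisson point field with a region mask.

    The active region is the left ``region_split`` fraction of the
    field (rate A, sparser by default, as transcriptionally active
    regions are less crowded); the remainder gets rate B.  The returned
    mask marks the active region at ``pixel_size_um`` resolution
    (default 0.26 µm/px, a typical confocal calibration, so the 8 px
    duplicate-removal radius is ~2 µm).
    """
    if rate_per_um2_a < 0 or rate_per_um2_b < 0:
        raise ValueError("rates must be >= 0")
    w, h = extent_um
    if w <= 0 or h <= 0:
        raise ValueError("extent must be positive")
    if not 0.0 <= region_split <= 1.0:
        raise ValueError("region_split must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    split_x = region_split * w

    def poisson_points(rate, x0, x1):
        area = (x1 - x0) * h
        n = rng.poisson(rate * area)
        return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(0, h, n)])

    pts = np.vstack([poisson_points(rate_per_um2_a, 0.0, split_x),
                     poisson_points(rate_per_um2_b, split_x, w)])
    field = CentroidField(pts, (w, h), pixel_size_um)

    ncols = int(np.ceil(w / pixel_size_um))
    nrows = int(np.ceil(h / pixel_size_um))
    cols_x = (np.arange(ncols) + 0.5) * pixel_size_um
    mask = np.broadcast_to(cols_x < split_x, (nrows, ncols)).copy()
    return field, RegionMask(mask, pixel_size_um)


# ---------------------------------------------------------------------------
# focal-adhesion pattern
# ---------------------------------------------------------------------------

def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two 2D segments."""
    def point_seg(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
        return float(np.linalg.norm(p - (a + t * ab)))

    def ccw(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    if (ccw(p1, p2, q1) * ccw(p1, p2, q2) < 0
            and ccw(q1, q2, p1) * ccw(q1, q2, p2) < 0):
        return 0.0
    return min(point_seg(q1, p1, p2), point_seg(q2, p1, p2),
               point_seg(p1, q1, q2), point_seg(p2, q1, q2))


def make_fa_pattern(segments_um: list[tuple[tuple[float, float],
                                            tuple[float, float]]],
                    width_px: float = 3.0,
                    render: ImageRenderParams | None = None
                    ) -> tuple[np.ndarray, dict]:
    """Bright bar for each line segment, plus the exact total length.

    Segments (µm endpoints) must lie inside the frame and must not
    overlap one another; intensity falls off smoothly at the bar edge so
    the pattern resembles diffraction-limited adhesions.
    """
    if render is None:
        render = ImageRenderParams(shape_px=(768, 768), pixel_size_um=0.189)
    rows, cols = render.shape_px[-2:]
    px = render.pixel_size_um
    segs = [(np.asarray(a, float), np.asarray(b, float))
            for a, b in segments_um]
    for a, b in segs:
        for p in (a, b):
            if not (0 <= p[0] <= cols * px and 0 <= p[1] <= rows * px):
                raise ValueError("segment endpoint outside frame")
    min_sep = 2.0 * width_px * px
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if _segment_distance(*segs[i], *segs[j]) < min_sep:
                raise ValueError("segments overlap or nearly touch; "
                                 "invalid fixture")

    img = np.full((rows, cols), render.background_level, dtype=float)
    half_w_um = width_px * px / 2.0
    for a, b in segs:
        lo = np.minimum(a, b) - 4 * half_w_um
        hi = np.maximum(a, b) + 4 * half_w_um
        c0, c1 = max(int(lo[0] / px), 0), min(int(np.ceil(hi[0] / px)) + 1, cols)
        r0, r1 = max(int(lo[1] / px), 0), min(int(np.ceil(hi[1] / px)) + 1, rows)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        pxy = np.stack([(xx + 0.5) * px, (yy + 0.5) * px], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((pxy - a) @ ab) / denom, 0, 1) if denom else 0.0
        closest = a + t[..., None] * ab if denom else np.broadcast_to(a, pxy.shape)
        d = np.linalg.norm(pxy - closest, axis=-1)
        profile = render.amplitude / (1.0 + np.exp((d - half_w_um) / (0.3 * px)))
        img[r0:r1, c0:c1] = np.maximum(img[r0:r1, c0:c1], profile)

    if render.noise_sd > 0:
        rng = np.random.default_rng(render.seed)
        img += rng.normal(0.0, render.noise_sd, size=img.shape)
    total = float(sum(np.linalg.norm(b - a) for a, b in segs))
    return img, {"total_length_um": total, "n_segments": len(segs)}


# ---------------------------------------------------------------------------
# genome fixture
# ---------------------------------------------------------------------------

def make_genome_fixture(n_genes: int = 1000, n_peaks: int = 100,
                        enrichment_factor: float = 1.0, n_deg: int = 150,
                        seed: int = 0) -> dict:
    """Single-chromosome genes/peaks/DEG fixture with known enrichment.

    Genes sit on a regular grid; each peak overlaps one gene of a random
    subset, so closest-gene assignment recovers the target set exactly.
    DEG labels are drawn so that the probability a DEG is a target gene
    equals ``enrichment_factor`` times the background target fraction
    (capped at 1; infeasible factors raise).

    Returns dict with ``peaks``, ``genes``, ``degs`` DataFrames, the
    ``universe`` gene set, ``target_genes``, ``deg_genes``, and the
    constructed fractions.
    """
    if n_deg > n_genes:
        raise ValueError("n_deg cannot exceed n_genes")
    if n_peaks > n_genes:
        raise ValueError("n_peaks cannot exceed n_genes (one peak per target)")
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    rng = np.random.default_rng(seed)

    spacing, gene_len = 10_000, 2_000
    starts = np.arange(n_genes) * spacing + 1_000
    genes = pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
        "chrom": "chr1",
        "start": starts,
        "end": starts + gene_len,
        "strand": np.where(rng.random(n_genes) < 0.5, "+", "-"),
    })

    target_idx = np.sort(rng.choice(n_genes, size=n_peaks, replace=False))
    peak_len = 500
    peak_starts = starts[target_idx] + rng.integers(0, gene_len - peak_len,
                                                    size=n_peaks)
    peaks = pd.DataFrame({"chrom": "chr1", "start": peak_starts,
                          "end": peak_starts + peak_len})
    target_genes = set(genes["gene_id"].iloc[target_idx])

    q = n_peaks / n_genes                     # background target fraction
    p_target = enrichment_factor * q
    if p_target > 1.0 + 1e-12:
        raise ValueError(
            f"infeasible enrichment: required probability {p_target:.3f} > 1")
    p_target = min(p_target, 1.0)

    n_deg_target = int(rng.binomial(n_deg, p_target))
    n_deg_target = min(n_deg_target, n_peaks)
    n_deg_bg = n_deg - n_deg_target
    non_target_idx = np.setdiff1d(np.arange(n_genes), target_idx)
    if n_deg_bg > non_target_idx.size:
        raise ValueError("not enough non-target genes for the DEG draw")
    deg_idx = np.concatenate([
        rng.choice(target_idx, size=n_deg_target, replace=False),
        rng.choice(non_target_idx, size=n_deg_bg, replace=False),
    ])
    deg_mask = np.zeros(n_genes, dtype=bool)
    deg_mask[deg_idx] = True

    padj = np.where(deg_mask, rng.uniform(0.0, 0.049, n_genes),
                    rng.uniform(0.051, 1.0, n_genes))
    log2fc = np.where(deg_mask, -(1.0 + rng.exponential(1.0, n_genes)),
                      rng.normal(0.0, 0.3, n_genes))
    degs = pd.DataFrame({"gene_id": genes["gene_id"], "log2fc": log2fc,
                         "padj": padj})

    return {
        "peaks": peaks,
        "genes": genes,
        "degs": degs,
        "universe": set(genes["gene_id"]),
        "target_genes": target_genes,
        "deg_genes": set(genes["gene_id"][deg_mask]),
        "background_target_fraction": q,
        "expected_deg_target_fraction": p_target,
    }
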