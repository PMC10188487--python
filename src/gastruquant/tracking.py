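"""Nuclei detection, track linking, and migration metrics.

The stage mirrors a time-lapse workflow for gastrulating fish embryos:
paired confocal sections are maximum-projected and contrast-enhanced,
nuclei are detected per frame with a Laplacian-of-Gaussian blob detector
(blob diameter 7.9 px, quality threshold 0.23 on the min-max normalized
response), detections are linked frame-to-frame by greedy mutual nearest
neighbors, and per-track migration metrics are computed:

* displacement ``D`` — straight-line distance between first and last
  position;
* path length ``L`` — total trajectory length;
* persistence ``P = D / L`` — straightness of the track, 1 for a
  perfectly directed cell;
* mean velocity ``v`` — mean over steps of step distance / step time.

Tracks shorter than 15 frames or starting near the embryo midline are
excluded before group statistics, which are computed on per-embryo means
(variance-test-gated two-sided t test, :mod:`gastruquant.stats_core`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stats_core import TwoSampleResult, f_variance_test, t_test_means

__all__ = [
    "Trajectory",
    "TrackMetrics",
    "DetectionParams",
    "preprocess_frame",
    "detect_spots",
    "link_tracks",
    "compute_track_metrics",
    "classify_displacement_bin",
    "filter_tracks",
    "classify_position",
    "compare_groups",
    "trajectories_to_frame",
    "metrics_to_frame",
]

DISPLACEMENT_BINS = ("sub", "blue", "green", "yellow", "red")


@dataclass(frozen=True)
class Trajectory:
    """One cell's track: ordered (frame, t_min, x_um, y_um) points."""

    track_id: int
    frames: np.ndarray      # integer frame indices, strictly increasing
    t_min: np.ndarray       # minutes
    xy_um: np.ndarray       # shape (n, 2)

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=int)
        t = np.asarray(self.t_min, dtype=float)
        xy = np.asarray(self.xy_um, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("xy_um must have shape (n, 2)")
        if not (len(frames) == len(t) == len(xy)) or len(frames) < 1:
            raise ValueError("trajectory arrays must share length >= 1")
        if np.any(np.diff(frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(xy))):
            raise ValueError("trajectory coordinates must be finite")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "xy_um", xy)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class TrackMetrics:
    track_id: int
    n_frames: int
    displacement_um: float
    path_length_um: float
    persistence: float
    mean_velocity_um_min: float
    displacement_bin: str
    position_class: str = "lateral"
    start_xy_um: tuple = (np.nan, np.nan)
    mean_x_um: float = np.nan


@dataclass(frozen=True)
class DetectionParams:
    """Detection / linking / filtering parameters with the published defaults."""

    blob_diameter_px: float = 7.9
    quality_threshold: float = 0.23
    pixel_size_um: float = 0.189
    frame_interval_min: float = 4.0
    max_link_dist_um: float = 15.0
    min_frames: int = 15
    midline_x_um: float = 0.0
    midline_halfwidth_um: float = 50.0

    def __post_init__(self):
        for name in ("blob_diameter_px", "quality_threshold", "pixel_size_um",
                     "frame_interval_min", "max_link_dist_um", "min_frames",
                     "midline_halfwidth_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# image preprocessing and detection
# ---------------------------------------------------------------------------

def preprocess_frame(z_sections: Sequence[np.ndarray],
                     unsharp_sigma_px: float = 15.0,
                     unsharp_weight: float = 0.60,
                     median_radius_px: int = 2) -> np.ndarray:
    """Max-project two sections, unsharp-mask, then median-filter.

    The unsharp mask follows the mask-weight convention
    ``out = (in - w * G_sigma(in)) / (1 - w)`` with sigma = 15 px and
    w = 0.60, clipped at zero; the median filter uses a disk-like
    footprint of radius 2 px.
    """
    sections = [np.asarray(s, dtype=float) for s in z_sections]
    if len(sections) < 1:
        raise ValueError("need at least one section")
    shape = sections[0].shape
    if any(s.shape != shape for s in sections):
        raise ValueError("sections must share the same shape")
    proj = np.maximum.reduce(sections)

    blurred = ndi.gaussian_filter(proj, sigma=unsharp_sigma_px, mode="reflect")
    sharp = (proj - unsharp_weight * blurred) / (1.0 - unsharp_weight)
    sharp = np.clip(sharp, 0.0, None)

    r = int(median_radius_px)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    footprint = (yy**2 + xx**2) <= r**2
    return ndi.median_filter(sharp, footprint=footprint, mode="reflect")


def _quadratic_refine(resp: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Sub-pixel peak offset from a separable quadratic fit (|offset| <= 0.5)."""
    def axis_offset(m1, m0, p1):
        denom = m1 - 2.0 * m0 + p1
        if denom >= 0:  # not a maximum along this axis
            return 0.0
        off = 0.5 * (m1 - p1) / denom
        return float(np.clip(off, -0.5, 0.5))

    dr = axis_offset(resp[r - 1, c], resp[r, c], resp[r + 1, c])
    dc = axis_offset(resp[r, c - 1], resp[r, c], resp[r, c + 1])
    return dr, dc


def detect_spots(image: np.ndarray, params: DetectionParams) -> pd.DataFrame:
    """LoG blob detection with sub-pixel refinement.

    The LoG scale is ``diameter / (2 * sqrt(2))`` px.  The negated,
    scale-normalized response is normalized per frame over its
    nonnegative range to give a quality in [0, 1]; local maxima above
    ``params.quality_threshold`` are kept and refined by a separable
    quadratic fit.  Returns a DataFrame (x_um, y_um, quality); empty for
    a blank frame.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a 2D image")
    sigma = params.blob_diameter_px / (2.0 * np.sqrt(2.0))
    # bright blobs give negative LoG; negate so peaks are maxima
    resp = -(sigma**2) * ndi.gaussian_laplace(img, sigma=sigma, mode="reflect")
    hi = float(resp.max())
    if hi <= 0:
        return pd.DataFrame(columns=["x_um", "y_um", "quality"])
    # quality: response normalized to [0, 1] over the nonnegative range;
    # anchoring at the frame minimum would put the zero-response floor
    # near 0.3 and defeat the 0.23 threshold
    qual = np.clip(resp, 0.0, None) / hi

    size = max(3, int(round(sigma * 2)) | 1)
    maxima = (qual == ndi.maximum_filter(qual, size=size, mode="reflect"))
    maxima &= qual > params.quality_threshold
    rows, cols = np.nonzero(maxima)

    out = []
    h, w = img.shape
    for r, c in zip(rows, cols):
        if 0 < r < h - 1 and 0 < c < w - 1:
            dr, dc = _quadratic_refine(resp, r, c)
        else:
            dr = dc = 0.0
        out.append((
            (c + dc) * params.pixel_size_um,
            (r + dr) * params.pixel_size_um,
            float(qual[r, c]),
        ))
    return pd.DataFrame(out, columns=["x_um", "y_um", "quality"])


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_tracks(per_frame_detections: dict[int, np.ndarray] | pd.DataFrame,
                params: DetectionParams) -> list[Trajectory]:
    """Greedy mutual-nearest-neighbor frame-to-frame linking.

    A link is made only when two detections are each other's nearest
    neighbor across consecutive frames and closer than
    ``params.max_link_dist_um``; unmatched detections start new tracks.
    There is no gap closing: a cell that vanishes for one frame yields
    two tracks.
    """
    if params.max_link_dist_um <= 0:
        raise ValueError("max_link_dist_um must be positive")
    if isinstance(per_frame_detections, pd.DataFrame):
        det = {
            int(f): g[["x_um", "y_um"]].to_numpy(dtype=float)
            for f, g in per_frame_detections.groupby("frame")
        }
    else:
        det = {int(f): np.asarray(p, dtype=float).reshape(-1, 2)
               for f, p in per_frame_detections.items()}
    if not det:
        return []
    frames = sorted(det)

    dt = params.frame_interval_min
    tracks: list[dict] = []          # each: {"frames": [...], "xy": [...]}
    open_idx: list[int] = []         # track index per current detection

    prev_pts = det[frames[0]]
    for i in range(len(prev_pts)):
        tracks.append({"frames": [frames[0]], "xy": [prev_pts[i]]})
        open_idx.append(len(tracks) - 1)

    for fprev, fcur in zip(frames[:-1], frames[1:]):
        cur_pts = det[fcur]
        new_open = [-1] * len(cur_pts)
        if fcur == fprev + 1 and len(prev_pts) and len(cur_pts):
            d = np.linalg.norm(
                prev_pts[:, None, :] - cur_pts[None, :, :], axis=2)
            nn_fwd = np.argmin(d, axis=1)
            nn_bwd = np.argmin(d, axis=0)
            for i, j in enumerate(nn_fwd):
                if nn_bwd[j] == i and d[i, j] <= params.max_link_dist_um:
                    ti = open_idx[i]
                    tracks[ti]["frames"].append(fcur)
                    tracks[ti]["xy"].append(cur_pts[j])
                    new_open[j] = ti
        for j in range(len(cur_pts)):
            if new_open[j] < 0:
                tracks.append({"frames": [fcur], "xy": [cur_pts[j]]})
                new_open[j] = len(tracks) - 1
        prev_pts, open_idx = cur_pts, new_open

    out = []
    for tid, tr in enumerate(tracks):
        fr = np.asarray(tr["frames"], dtype=int)
        out.append(Trajectory(
            track_id=tid, frames=fr, t_min=fr * dt,
            xy_um=np.asarray(tr["xy"], dtype=float)))
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def classify_displacement_bin(displacement_um: float) -> str:
    """Color-code a displacement: 20-50 blue, 50-80 green, 80-130 yellow,
    >130 red; below 20 is 'sub'.  Lower bounds are closed, upper open,
    except 130 which belongs to yellow."""
    d = float(displacement_um)
    if d < 0:
        raise ValueError("displacement must be non-negative")
    if d < 20:
        return "sub"
    if d < 50:
        return "blue"
    if d < 80:
        return "green"
    if d <= 130:
        return "yellow"
    return "red"


def compute_track_metrics(traj: Trajectory, params: DetectionParams,
                          persistence_mode: str = "ratio") -> TrackMetrics:
    """Displacement, path length, persistence, and mean velocity of a track.

    ``persistence_mode='ratio'`` (default) uses the straightness ratio
    D / L; ``'run_length'`` instead reports the mean run length (in
    steps, normalized by track length) over which successive headings
    stay within 30 degrees.
    """
    if len(traj) < 2:
        raise ValueError("metrics need a track with at least 2 points")
    xy = traj.xy_um
    steps = np.diff(xy, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    L = float(np.sum(step_len))
    D = float(np.linalg.norm(xy[-1] - xy[0]))
    dts = np.diff(traj.t_min)
    if np.any(dts <= 0):
        raise ValueError("time stamps must be strictly increasing")
    v = float(np.mean(step_len / dts))

    if persistence_mode == "ratio":
        P = D / L if L > 0 else 0.0
    elif persistence_mode == "run_length":
        P = _mean_run_length_persistence(steps, step_len)
    else:
        raise ValueError(f"unknown persistence_mode {persistence_mode!r}")

    mean_x = float(np.mean(xy[:, 0]))
    pos = ("midline"
           if abs(mean_x - params.midline_x_um) <= params.midline_halfwidth_um
           else "lateral")
    return TrackMetrics(
        track_id=traj.track_id, n_frames=len(traj),
        displacement_um=D, path_length_um=L, persistence=min(P, 1.0),
        mean_velocity_um_min=v,
        displacement_bin=classify_displacement_bin(D),
        position_class=pos,
        start_xy_um=(float(xy[0, 0]), float(xy[0, 1])),
        mean_x_um=mean_x,
    )


def _mean_run_length_persistence(steps: np.ndarray, step_len: np.ndarray,
                                 max_turn_deg: float = 30.0) -> float:
    """Alternative, time-like persistence: mean length of runs of steps
    whose heading change stays below ``max_turn_deg``, normalized by the
    number of steps (so 1 means a single unbroken run)."""
    moving = step_len > 0
    if moving.sum() < 2:
        return 0.0
    ang = np.arctan2(steps[moving, 1], steps[moving, 0])
    turn = np.abs((np.diff(ang) + np.pi) % (2 * np.pi) - np.pi)
    ok = turn < np.deg2rad(max_turn_deg)
    runs, cur = [], 1
    for flag in ok:
        if flag:
            cur += 1
        else:
            runs.append(cur)
            cur = 1
    runs.append(cur)
    return float(np.mean(runs) / len(step_len))


def classify_position(traj: Trajectory, params: DetectionParams) -> str:
    """'midline' if the track's mean |x - midline_x| is within the
    configured halfwidth, else 'lateral'."""
    mean_dev = float(np.mean(np.abs(traj.xy_um[:, 0] - params.midline_x_um)))
    return "midline" if mean_dev <= params.midline_halfwidth_um else "lateral"


def filter_tracks(metrics: Iterable[TrackMetrics],
                  params: DetectionParams) -> list[TrackMetrics]:
    """Exclude tracks seen in fewer than ``min_frames`` frames and tracks
    that start within the midline band.  Idempotent."""
    kept = []
    for m in metrics:
        if m.n_frames < params.min_frames:
            continue
        x0 = m.start_xy_um[0]
        if np.isfinite(x0) and \
                abs(x0 - params.midline_x_um) <= params.midline_halfwidth_um:
            continue
        kept.append(m)
    return kept


def compare_groups(means_a: Sequence[float], means_b: Sequence[float]) -> dict:
    """Variance test then two-sided t test on per-embryo means.

    Returns a dict with both the F-test and the (pooled or Welch) t-test
    results, mirroring how group differences are assessed on n = 3
    embryos per genotype.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 embryo means per group")
    try:
        fres = f_variance_test(a, b)
    except ValueError:  # both variances zero
        fres = TwoSampleResult(1.0, (a.size - 1, b.size - 1), 1.0, "f_var")
    tres = t_test_means(a, b)
    return {
        "n_a": int(a.size), "n_b": int(b.size),
        "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b)),
        "f_statistic": fres.statistic, "f_p": fres.p_two_sided,
        "t_statistic": tres.statistic, "t_df": tres.df,
        "t_p": tres.p_two_sided, "t_method": tres.method,
    }


# ---------------------------------------------------------------------------
# tabular I/O helpers
# ---------------------------------------------------------------------------

def trajectories_to_frame(tracks: Iterable[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, t, (x, y) in zip(tr.frames, tr.t_min, tr.xy_um):
            rows.append((tr.track_id, int(f), float(t), float(x), float(y)))
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_min",
                                       "x_um", "y_um"])


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for tid, g in df.groupby("track_id"):
        g = g.sort_values("frame")
        out.append(Trajectory(
            track_id=int(tid),
            frames=g["frame"].to_numpy(dtype=int),
            t_min=g["t_min"].to_numpy(dtype=float),
            xy_um=g[["x_um", "y_um"]].to_numpy(dtype=float)))
    return out


def metrics_to_frame(metrics: Iterable[TrackMetrics]) -> pd.DataFrame:
    return pd.DataFrame([{
        "track_id": m.track_id, "n_frames": m.n_frames,
        "displacement_um": m.displacement_um,
        "path_length_um": m.path_length_um,
        "persistence": m.persistence,
        "mean_velocity_um_min": m.mean_velocity_um_min,
        "displacement_bin": m.displacement_bin,
        "position_class": m.position_class,
    } for m in metrics])
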