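"""Nearest-neighbor cell-density statistics over nuclei centroid fields.

The density readout for each nucleus is the mean Euclidean distance to
its five closest neighbors (d5); lower d5 means higher local density.
Before computing d5, centroids closer than eight pixels are removed
(both members of each violating pair) and nuclei at the image border
are excluded.  Each point is then assigned to the transcriptionally
active or inactive region via a binary region mask, and the two regions
are compared on per-embryo means with a two-sided t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stats_core import t_test_means

__all__ = [
    "CentroidField",
    "RegionMask",
    "dedupe_centroids",
    "exclude_border",
    "mean_knn_distance",
    "assign_region",
    "compare_density",
]


@dataclass(frozen=True)
class CentroidField:
    """Nuclei centroid positions in µm within a rectangular field."""

    points_um: np.ndarray                  # (n, 2) x, y
    bounds_um: tuple[float, float]         # width, height
    pixel_size_um: float = 1.0

    def __post_init__(self):
        pts = np.asarray(self.points_um, dtype=float).reshape(-1, 2)
        w, h = self.bounds_um
        if w <= 0 or h <= 0 or self.pixel_size_um <= 0:
            raise ValueError("bounds and pixel size must be positive")
        if pts.size and (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
                         or pts[:, 0].max() > w or pts[:, 1].max() > h):
            raise ValueError("points must lie within bounds")
        object.__setattr__(self, "points_um", pts)

    def __len__(self) -> int:
        return len(self.points_um)

    def replace_points(self, pts: np.ndarray) -> "CentroidField":
        return CentroidField(pts, self.bounds_um, self.pixel_size_um)


@dataclass(frozen=True)
class RegionMask:
    """Binary mask marking the active region, co-registered with a field."""

    mask: np.ndarray           # bool, (rows, cols)
    pixel_size_um: float

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("region mask must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "mask", m)

    def lookup(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
        cols = np.floor(pts[:, 0] / self.pixel_size_um).astype(int)
        rows = np.floor(pts[:, 1] / self.pixel_size_um).astype(int)
        # points exactly on the far edge fall in the last pixel
        rows = np.clip(rows, None, self.mask.shape[0] - 1)
        cols = np.clip(cols, None, self.mask.shape[1] - 1)
        if rows.size and (rows.min() < 0 or cols.min() < 0
                          or rows.max() >= self.mask.shape[0]
                          or cols.max() >= self.mask.shape[1]):
            raise ValueError("point outside region-mask bounds")
        return self.mask[rows, cols]


def dedupe_centroids(field: CentroidField, min_sep_px: float = 8.0) -> CentroidField:
    """Drop every centroid with a neighbor closer than ``min_sep_px``.

    Removal is symmetric — both members of a violating pair go — since
    detection doubles give no reason to prefer either.  One pass leaves
    a set with all pairwise gaps >= the separation, so the operation is
    idempotent.
    """
    pts = field.points_um
    if len(pts) < 2:
        return field
    min_sep_um = min_sep_px * field.pixel_size_um
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=min_sep_um * (1 - 1e-12), output_type="ndarray")
    bad = np.zeros(len(pts), dtype=bool)
    if pairs.size:
        bad[pairs.ravel()] = True
    return field.replace_points(pts[~bad])


def exclude_border(field: CentroidField, margin_px: float = 8.0) -> CentroidField:
    """Drop points within ``margin_px`` of any field edge."""
    if margin_px < 0:
        raise ValueError("margin must be non-negative")
    m = margin_px * field.pixel_size_um
    w, h = field.bounds_um
    pts = field.points_um
    keep = ((pts[:, 0] >= m) & (pts[:, 0] <= w - m)
            & (pts[:, 1] >= m) & (pts[:, 1] <= h - m))
    if not keep.any() and len(pts):
        import warnings
        warnings.warn("border exclusion removed every point", stacklevel=2)
    return field.replace_points(pts[keep])


def mean_knn_distance(field: CentroidField, k: int = 5) -> np.ndarray:
    """Per-point mean distance to its k nearest other points (d5 for k=5)."""
    pts = field.points_um
    if len(pts) < k + 1:
        raise ValueError(f"need at least {k + 1} points for k={k}")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)   # first neighbor is the point itself
    return dists[:, 1:].mean(axis=1)


def assign_region(field: CentroidField, region: RegionMask) -> pd.DataFrame:
    """Records table: position, d-statistic placeholder, and region label
    ('active' where the mask pixel under the point is set)."""
    active = region.lookup(field.points_um)
    return pd.DataFrame({
        "x_um": field.points_um[:, 0],
        "y_um": field.points_um[:, 1],
        "region": np.where(active, "active", "inactive"),
    })


def density_records(field: CentroidField, region: RegionMask,
                    k: int = 5) -> pd.DataFrame:
    """Full per-nucleus record: position, mean k-NN distance, region."""
    rec = assign_region(field, region)
    rec["mean_dist_knn_um"] = mean_knn_distance(field, k=k)
    return rec


def compare_density(records_by_embryo: dict[object, pd.DataFrame]) -> dict:
    """Two-sided t test on per-embryo mean d5 of active vs inactive regions.

    Each value of ``records_by_embryo`` is a records table from
    :func:`density_records`; embryos missing either region raise.
    """
    active_means, inactive_means = [], []
    for embryo, rec in records_by_embryo.items():
        for region, sink in (("active", active_means),
                             ("inactive", inactive_means)):
            vals = rec.loc[rec["region"] == region, "mean_dist_knn_um"]
            if vals.empty:
                raise ValueError(f"embryo {embryo!r} has no {region} points")
            sink.append(float(vals.mean()))
    if len(active_means) < 2:
        raise ValueError("need at least 2 embryos")
    res = t_test_means(active_means, inactive_means)
    return {
        "n_embryos": len(active_means),
        "mean_active_um": float(np.mean(active_means)),
        "mean_inactive_um": float(np.mean(inactive_means)),
        "t_statistic": res.statistic,
        "t_df": res.df,
        "p_two_sided": res.p_two_sided,
        "method": res.method,
    }
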