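"""Peak-to-gene assignment and DEG enrichment testing.

Chromatin peak lists (e.g. DamID intervals for two paralogous
transcription factors) are concatenated — not merged — and each peak is
assigned its closest gene (distance 0 on overlap, otherwise the gap
between nearest interval ends, ties to the smaller gene start).  The
set of peak-associated ("target") genes is then intersected with the
differentially expressed genes (padj < 0.05, |log2FC| >= 1, optionally
downregulated only), and the DEG target fraction is compared to the
target fraction of the expressed-gene universe with a pooled
two-proportion Z test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats_core import TwoSampleResult, two_proportion_z

__all__ = [
    "concat_peaks",
    "closest_gene",
    "assign_closest_genes",
    "filter_degs",
    "enrichment_test",
    "read_bed",
    "write_bed",
]

PEAK_COLUMNS = ["chrom", "start", "end"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def _check_intervals(df: pd.DataFrame, what: str) -> None:
    if not {"chrom", "start", "end"}.issubset(df.columns):
        raise ValueError(f"{what} must have chrom/start/end columns")
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    if np.any(starts < 0) or np.any(starts >= ends):
        raise ValueError(f"{what} contains malformed intervals "
                         "(require 0 <= start < end)")


def concat_peaks(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame) -> pd.DataFrame:
    """Multiset concatenation of two peak lists, sorted by (chrom, start).

    Duplicates and overlaps are preserved: the lists are concatenated,
    not unioned, so a peak present in both inputs appears twice.
    """
    _check_intervals(peaks_a, "peaks_a")
    _check_intervals(peaks_b, "peaks_b")
    merged = pd.concat([peaks_a[PEAK_COLUMNS], peaks_b[PEAK_COLUMNS]],
                       ignore_index=True)
    return (merged.sort_values(["chrom", "start", "end"], kind="mergesort")
                  .reset_index(drop=True))


def _interval_distance(p_start, p_end, g_start, g_end):
    """Gap between [p_start, p_end) and [g_start, g_end); 0 on overlap."""
    return np.maximum(0, np.maximum(g_start - p_end, p_start - g_end))


def closest_gene(peak: tuple, genes: pd.DataFrame,
                 use_tss: bool = False) -> tuple[str | None, float]:
    """Closest gene to one peak ``(chrom, start, end)``.

    Distance is 0 when intervals overlap, else the gap between nearest
    ends; with ``use_tss=True`` the distance is measured to the
    strand-aware transcription start site instead of the gene body.
    Ties break to the gene with the smaller start.  Returns
    ``(None, inf)`` when the peak's chromosome carries no gene.
    """
    chrom, start, end = peak
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return None, float("inf")
    if use_tss:
        tss = np.where(sub["strand"].to_numpy() == "-",
                       sub["end"].to_numpy() - 1, sub["start"].to_numpy())
        dist = np.where((tss >= start) & (tss < end), 0,
                        np.minimum(np.abs(tss - start),
                                   np.abs(tss - (end - 1))))
    else:
        dist = _interval_distance(start, end,
                                  sub["start"].to_numpy(),
                                  sub["end"].to_numpy())
    order = np.lexsort((sub["start"].to_numpy(), dist))
    best = order[0]
    return str(sub["gene_id"].iloc[best]), float(dist[best])


def assign_closest_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                         use_tss: bool = False) -> pd.DataFrame:
    """Closest-gene table for every peak (NaN gene for bare chromosomes)."""
    _check_intervals(peaks, "peaks")
    _check_intervals(genes, "genes")
    if genes["gene_id"].duplicated().any():
        raise ValueError("gene_ids must be unique")
    rows = []
    for chrom, start, end in peaks[PEAK_COLUMNS].itertuples(index=False):
        gid, dist = closest_gene((chrom, start, end), genes, use_tss=use_tss)
        rows.append((chrom, int(start), int(end), gid, dist))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "gene_id", "distance"])


def filter_degs(table: pd.DataFrame, padj_max: float = 0.05,
                min_abs_log2fc: float = 1.0,
                direction: str | None = None) -> set[str]:
    """DEG gene set at padj < ``padj_max`` and |log2FC| >= ``min_abs_log2fc``.

    ``direction`` may be ``'down'`` or ``'up'`` to keep only one side,
    matching analyses restricted to downregulated genes.
    """
    for col in ("gene_id", "log2fc", "padj"):
        if col not in table.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    padj = table["padj"].to_numpy(dtype=float)
    if np.any((padj < 0) | (padj > 1)):
        raise ValueError("padj values must lie in [0, 1]")
    lfc = table["log2fc"].to_numpy(dtype=float)
    keep = (padj < padj_max) & (np.abs(lfc) >= min_abs_log2fc)
    if direction == "down":
        keep &= lfc < 0
    elif direction == "up":
        keep &= lfc > 0
    elif direction is not None:
        raise ValueError(f"unknown direction {direction!r}")
    return set(table.loc[keep, "gene_id"].astype(str))


def enrichment_test(deg_genes: set[str], target_genes: set[str],
                    universe_genes: set[str],
                    control: str = "universe") -> dict:
    """Two-proportion Z test of DEG-vs-background target fractions.

    ``p1`` is the fraction of DEGs that are peak targets; the control
    fraction ``p2`` is the target fraction of the expressed-gene
    universe (default) or of the non-DEG genes (``control='non_deg'``).
    All sets are intersected with the universe first, so genes outside
    the universe never influence the result.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty universe")
    deg = set(deg_genes) & universe
    target = set(target_genes) & universe
    if not deg:
        raise ValueError("no DEG genes inside the universe")
    if control == "universe":
        ctrl = universe
    elif control == "non_deg":
        ctrl = universe - deg
    else:
        raise ValueError(f"unknown control {control!r}")
    x1, n1 = len(deg & target), len(deg)
    x2, n2 = len(ctrl & target), len(ctrl)
    res: TwoSampleResult = two_proportion_z(x1, n1, x2, n2)
    return {
        "x1": x1, "n1": n1, "x2": x2, "n2": n2,
        "deg_target_fraction": x1 / n1,
        "control_target_fraction": x2 / n2,
        "z": res.statistic,
        "p_two_sided": res.p_two_sided,
    }


# ---------------------------------------------------------------------------
# BED / table I/O (0-based, half-open)
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=PEAK_COLUMNS)
    _check_intervals(df, str(path))
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    _check_intervals(df, "peaks")
    df[PEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
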