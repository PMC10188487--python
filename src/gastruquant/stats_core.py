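"""Shared statistical procedures used across the pipeline stages.

All group comparisons in the imaging analyses follow the same recipe: an
F test for equality of variances gates the choice between a pooled
(Student) and a Welch two-sample t test, both two-sided, applied to
per-embryo means.  Genomic overlap significance uses a pooled
two-proportion Z test, and qPCR quantification uses the classical
delta-delta-Ct method with the ef1a housekeeping gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoSampleResult",
    "f_variance_test",
    "t_test_means",
    "two_proportion_z",
    "delta_delta_ct",
]


@dataclass(frozen=True)
class TwoSampleResult:
    """Outcome of a two-sample hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (F, t, or z depending on ``method``).
    df : float or tuple or None
        Degrees of freedom; a ``(df1, df2)`` pair for the F test,
        a scalar for t tests, ``None`` for the normal-based Z test.
    p_two_sided : float
        Two-sided p-value.
    method : str
        One of ``pooled_t``, ``welch_t``, ``f_var``, ``two_prop_z``.
    extra : dict
        Method-specific extras (e.g. sample proportions).
    """

    statistic: float
    df: object
    p_two_sided: float
    method: str
    extra: dict = field(default_factory=dict)


def _as_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def f_variance_test(xs, ys) -> TwoSampleResult:
    """Two-sided F test for equality of variances.

    The larger sample variance goes in the numerator so F >= 1; the
    two-sided p-value is twice the upper tail (capped at 1).  The test is
    symmetric in argument order.
    """
    xs = _as_sample(xs, "xs")
    ys = _as_sample(ys, "ys")
    v1 = float(np.var(xs, ddof=1))
    v2 = float(np.var(ys, ddof=1))
    if v1 == 0.0 and v2 == 0.0:
        raise ValueError("both samples have zero variance; F test undefined")
    if v1 >= v2:
        f, d1, d2 = (np.inf if v2 == 0 else v1 / v2), xs.size - 1, ys.size - 1
    else:
        f, d1, d2 = v2 / v1, ys.size - 1, xs.size - 1
    p = min(1.0, 2.0 * float(sps.f.sf(f, d1, d2)))
    return TwoSampleResult(float(f), (d1, d2), p, "f_var")


def t_test_means(xs, ys, variance_rule: str = "f_gate_0.05") -> TwoSampleResult:
    """Two-sided two-sample t test with an F-test gate on the variance.

    With the default rule the pooled (Student) t test is used when the
    variance F test does not reject at alpha = 0.05, otherwise Welch's
    unequal-variance t test.  ``variance_rule`` may also be ``"pooled"``
    or ``"welch"`` to force a branch.
    """
    xs = _as_sample(xs, "xs")
    ys = _as_sample(ys, "ys")
    if variance_rule == "pooled":
        equal_var = True
    elif variance_rule == "welch":
        equal_var = False
    elif variance_rule.startswith("f_gate_"):
        alpha = float(variance_rule.removeprefix("f_gate_"))
        try:
            fres = f_variance_test(xs, ys)
            equal_var = fres.p_two_sided >= alpha
        except ValueError:  # both variances zero: pooled t is the degenerate limit
            equal_var = True
    else:
        raise ValueError(f"unknown variance_rule {variance_rule!r}")

    n1, n2 = xs.size, ys.size
    v1 = float(np.var(xs, ddof=1))
    v2 = float(np.var(ys, ddof=1))
    diff = float(np.mean(xs) - np.mean(ys))
    if equal_var:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        method = "pooled_t"
    else:
        se1, se2 = v1 / n1, v2 / n2
        se = np.sqrt(se1 + se2)
        # Welch–Satterthwaite degrees of freedom
        df = (se1 + se2) ** 2 / (
            se1**2 / (n1 - 1) + se2**2 / (n2 - 1)
        ) if (se1 + se2) > 0 else n1 + n2 - 2
        method = "welch_t"
    if se == 0.0:
        t = 0.0
        p = 1.0
    else:
        t = diff / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return TwoSampleResult(float(t), float(df), min(1.0, p), method)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int,
                     pooled: bool = True) -> TwoSampleResult:
    """Two-sided two-proportion Z test.

    With ``pooled=True`` (default) the standard error uses the pooled
    proportion ``(x1 + x2) / (n1 + n2)``.  When the pooled proportion is
    exactly 0 or 1 the statistic is degenerate; z = 0 / p = 1 is
    returned with a flag in ``extra``.
    """
    for x, n, nm in ((x1, n1, "1"), (x2, n2, "2")):
        if n < 1:
            raise ValueError(f"n{nm} must be >= 1")
        if not 0 <= x <= n:
            raise ValueError(f"x{nm} must lie in [0, n{nm}]")
    p1, p2 = x1 / n1, x2 / n2
    extra = {"p1": p1, "p2": p2, "x1": x1, "n1": n1, "x2": x2, "n2": n2}
    if pooled:
        phat = (x1 + x2) / (n1 + n2)
        var = phat * (1 - phat) * (1 / n1 + 1 / n2)
    else:
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var <= 0.0:
        extra["degenerate"] = True
        return TwoSampleResult(0.0, None, 1.0, "two_prop_z", extra)
    z = (p1 - p2) / np.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return TwoSampleResult(float(z), None, min(1.0, p), "two_prop_z", extra)


def delta_delta_ct(table: pd.DataFrame, reference_gene: str = "ef1a",
                   control_group: str | None = None) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method (efficiency = 2).

    Parameters
    ----------
    table : DataFrame
        Long-format Ct table with columns ``sample_group``, ``gene``,
        ``replicate``, ``ct``.  The reference gene must be measured in
        every group; replicates of the reference within a group are
        averaged before subtraction.
    reference_gene : str
        Housekeeping gene used for normalization.
    control_group : str
        Group whose mean delta-Ct defines the baseline (fold change 1).

    Returns
    -------
    DataFrame with one row per (group, gene) carrying per-replicate fold
    changes, their mean and SD, and the underlying delta-delta-Ct mean.
    """
    required = {"sample_group", "gene", "replicate", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(table["ct"].to_numpy(dtype=float))):
        raise ValueError("Ct values must be finite")
    if control_group is None:
        raise ValueError("control_group must be given")
    groups = table["sample_group"].unique()
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in table")

    ref_mean = (
        table[table["gene"] == reference_gene]
        .groupby("sample_group")["ct"].mean()
    )
    absent = [g for g in groups if g not in ref_mean.index]
    if absent:
        raise ValueError(
            f"reference gene {reference_gene!r} missing in groups {absent}")

    targets = table[table["gene"] != reference_gene].copy()
    targets["delta_ct"] = (
        targets["ct"].to_numpy()
        - ref_mean.loc[targets["sample_group"]].to_numpy()
    )
    control_dct = (
        targets[targets["sample_group"] == control_group]
        .groupby("gene")["delta_ct"].mean()
    )

    rows = []
    for (group, gene), sub in targets.groupby(["sample_group", "gene"], sort=True):
        if gene not in control_dct.index:
            raise ValueError(f"gene {gene!r} absent from control group")
        ddct = sub["delta_ct"].to_numpy() - control_dct.loc[gene]
        folds = np.power(2.0, -ddct)
        rows.append({
            "sample_group": group,
            "gene": gene,
            "n_replicates": len(folds),
            "mean_ddct": float(np.mean(ddct)),
            "fold_changes": list(map(float, folds)),
            "fold_mean": float(np.mean(folds)),
            "fold_sd": float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
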