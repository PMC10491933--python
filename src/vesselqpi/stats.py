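"""Group statistics: per-animal aggregation, t-tests, variance F-test.

The unit of analysis defaults to the animal (each animal's mean over its
included vessels is one independent observation); per-vessel analysis is
available behind the ``unit`` switch. Tests are two-sided; the t-test uses
the equal-variance (pooled) form by default with Welch as an option. No
multiple-testing correction is applied by default (a Benjamini–Hochberg
helper exists but is opt-in).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


class VarianceError(ValueError):
    """A variance test requires strictly positive sample variances."""


@dataclass(frozen=True)
class GroupComparison:
    """Result of comparing one metric between two groups."""

    group_a: str
    group_b: str
    unit: str  # "animal" | "vessel"
    metric: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    t_p_value: float
    f_statistic: float
    f_p_value: float
    alpha: float = 0.05
    significant_t: bool = field(default=False)
    significant_f: bool = field(default=False)
    provenance: dict = field(default_factory=dict)


def per_animal_aggregate(
    vessel_table: pd.DataFrame, metrics: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """One row per animal: unweighted means over its *included* vessels.

    Requires ``group``, ``animal_id`` and (if present) ``included``
    columns; animals whose vessels are all excluded are dropped with a
    logged warning.
    """
    df = vessel_table.copy()
    for col in ("group", "animal_id"):
        if col not in df.columns:
            raise ValueError(f"vessel table needs a '{col}' column")
    if "included" in df.columns:
        kept = df[df["included"].astype(bool)]
        dropped = set(df["animal_id"]) - set(kept["animal_id"])
        for animal in sorted(dropped):
            logger.warning("animal %s has no included vessels; dropped", animal)
        df = kept
    if metrics is None:
        metrics = [
            c
            for c in df.columns
            if c not in ("group", "animal_id", "vessel_id", "included")
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    out = (
        df.groupby(["group", "animal_id"], sort=True)[list(metrics)]
        .mean()
        .reset_index()
    )
    return out


def unpaired_t_test(
    samples_a: Sequence[float],
    samples_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance unless ``welch``).

    Convention: two zero-variance samples with equal means give
    ``(0.0, 1.0)`` rather than NaN.
    """
    a = np.asarray(samples_a, dtype=np.float64)
    b = np.asarray(samples_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def variance_f_test(
    samples_a: Sequence[float], samples_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided F-test of equal variances: ``F = s_a² / s_b²``.

    p-value is twice the smaller tail of F(n_a−1, n_b−1); swapping the
    groups inverts F and leaves p unchanged.
    """
    a = np.asarray(samples_a, dtype=np.float64)
    b = np.asarray(samples_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise VarianceError("zero sample variance; F-test undefined")
    f_stat = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2.0 * min(sps.f.cdf(f_stat, dfa, dfb), sps.f.sf(f_stat, dfa, dfb))
    return float(f_stat), float(min(p, 1.0))


def compare_groups(
    vessel_table: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    unit: str = "animal",
    alpha: float = 0.05,
    welch: bool = False,
) -> GroupComparison:
    """Compare one metric between two groups at the chosen unit of analysis."""
    if unit not in ("animal", "vessel"):
        raise ValueError("unit must be 'animal' or 'vessel'")
    if unit == "animal":
        table = per_animal_aggregate(vessel_table, metrics=[metric])
    else:
        table = vessel_table
        if "included" in table.columns:
            table = table[table["included"].astype(bool)]
    a = table.loc[table["group"] == group_a, metric].to_numpy(dtype=np.float64)
    b = table.loc[table["group"] == group_b, metric].to_numpy(dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"fewer than 2 {unit} units in a group "
            f"({group_a}: {a.size}, {group_b}: {b.size})"
        )
    t, tp = unpaired_t_test(a, b, welch=welch)
    try:
        f, fp = variance_f_test(a, b)
    except VarianceError:
        f, fp = float("nan"), float("nan")
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        unit=unit,
        metric=metric,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=t,
        t_p_value=tp,
        f_statistic=f,
        f_p_value=fp,
        alpha=alpha,
        significant_t=bool(tp < alpha),
        significant_f=bool(fp < alpha) if np.isfinite(fp) else False,
        provenance={"welch": welch, "test": "two-sided"},
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (opt-in; the default reports are uncorrected)."""
    p = np.asarray(p_values, dtype=np.float64)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
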