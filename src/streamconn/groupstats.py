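"""Group comparison and brain-behavior statistics.

Group differences use the Wilcoxon rank-sum (Mann-Whitney U) test: exact
enumeration when the pooled sample is small (n_a + n_b <= 12) and tie-free,
otherwise the normal approximation with tie and continuity corrections.
Family-wise error within each subsystem (DVS, VVS, VS) is controlled by the
Holm-Bonferroni step-down correction.  Brain-behavior association is
Spearman's rank correlation (two-sided, t-approximation for p), with an
ordinary least-squares line fitted for display only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .atlas import Connection
from .errors import DegenerateSignalError, SizingError, StructuralError, ValidationError

logger = logging.getLogger(__name__)

#: Pooled-sample threshold below which the exact rank-sum path is used.
EXACT_THRESHOLD = 12


@dataclass
class GroupComparisonResult:
    connection: str
    direction: str
    metric: str
    family: str
    statistic: float
    p_raw: float
    p_holm: float
    median_gamer: float
    median_nongamer: float
    n_gamer: int
    n_nongamer: int


@dataclass
class BrainBehaviorResult:
    connection: str
    direction: str
    metric: str
    rho: float
    p: float
    slope: float
    intercept: float
    n: int


def ranksum_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    method: str | None = None,
) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (U statistic of ``a``, p-value).

    By default: exact enumeration when n_a + n_b <= 12 and there are no
    ties across the pooled sample; otherwise the normal approximation with
    tie correction and continuity correction.  ``method`` ("exact" or
    "asymptotic") overrides the automatic choice.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SizingError("each group needs >= 2 observations")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if method is None:
        method = "exact" if (pooled.size <= EXACT_THRESHOLD and not has_ties) else "asymptotic"
    elif method == "exact" and has_ties:
        raise ValidationError("exact path is unavailable with ties")
    elif method not in ("exact", "asymptotic"):
        raise ValidationError(f"unknown method {method!r}")
    res = sstats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    adjusted_(i) = max_{j <= i} (m - j + 1) * p_(j) over the ascending sort,
    capped at 1 and mapped back to the original positions.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("need a non-empty 1-D p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties, two-sided t-approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D and of equal length")
    if x.size < 4:
        raise SizingError("need >= 4 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateSignalError("constant vector has no defined rank correlation")
    res = sstats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _group_values(
    table: pd.DataFrame,
    roster: pd.DataFrame,
    connection: str,
    metric: str,
    direction: str,
) -> tuple[np.ndarray, np.ndarray]:
    sel = table[
        (table["connection"] == connection)
        & (table["metric"] == metric)
        & (table["direction"] == direction)
    ]
    merged = sel.merge(roster[["subject_id", "group"]], on="subject_id", how="inner")
    merged = merged.dropna(subset=["value"])
    a = merged.loc[merged["group"] == "gamer", "value"].to_numpy()
    b = merged.loc[merged["group"] == "nongamer", "value"].to_numpy()
    return a, b


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    families: Mapping[str, Sequence[Connection]],
    roster: pd.DataFrame,
    alternative: str = "two-sided",
    directed_both: bool = True,
) -> pd.DataFrame:
    """Per-connection group tests with Holm correction per subsystem family.

    For undirected metrics (fc, fa, qa) each connection contributes one test
    per family; for the directed metric (tgc) both directions enter the
    family (``directed_both=True``, family size 8 for the dorsal stream).
    Subjects missing a value for a connection are dropped for that
    connection only, with a logged count.
    """
    results: list[GroupComparisonResult] = []
    for family, connections in families.items():
        tests = []
        for con in connections:
            if metric == "tgc" and directed_both:
                dirs = [f"{con.roi_a}->{con.roi_b}", f"{con.roi_b}->{con.roi_a}"]
            elif metric == "tgc":
                dirs = [f"{con.roi_a}->{con.roi_b}"]
            else:
                dirs = ["undirected"]
            for direction in dirs:
                a, b = _group_values(table, roster, con.label, metric, direction)
                n_expected = roster["subject_id"].nunique()
                if a.size + b.size < n_expected:
                    logger.info(
                        "connection %s (%s): dropped %d subjects with missing data",
                        con.label, direction, n_expected - a.size - b.size,
                    )
                if a.size < 2 or b.size < 2:
                    raise SizingError(
                        f"connection {con.label}: need >= 2 subjects per group"
                    )
                stat, p = ranksum_test(a, b, alternative=alternative)
                tests.append((con, direction, stat, p, a, b))
        if not tests:
            continue
        adjusted = holm_bonferroni([t[3] for t in tests])
        for (con, direction, stat, p, a, b), p_holm in zip(tests, adjusted):
            results.append(
                GroupComparisonResult(
                    connection=con.label,
                    direction=direction,
                    metric=metric,
                    family=family,
                    statistic=stat,
                    p_raw=p,
                    p_holm=float(p_holm),
                    median_gamer=float(np.median(a)),
                    median_nongamer=float(np.median(b)),
                    n_gamer=int(a.size),
                    n_nongamer=int(b.size),
                )
            )
    return pd.DataFrame([r.__dict__ for r in results])


def brain_behavior(
    table: pd.DataFrame,
    rts: Mapping[str, float],
    connection: str,
    metric: str,
    direction: str = "undirected",
) -> BrainBehaviorResult:
    """Spearman association of one connectivity metric with response time.

    Subjects lacking either the metric or a finite RT are excluded; fewer
    than 4 complete pairs raises :class:`SizingError`.  The least-squares
    line is for display only; inference is the Spearman rho/p.
    """
    sel = table[
        (table["connection"] == connection)
        & (table["metric"] == metric)
        & (table["direction"] == direction)
    ].dropna(subset=["value"])
    if sel.empty:
        raise StructuralError(
            f"no rows for connection {connection!r} metric {metric!r} direction {direction!r}"
        )
    pairs = [
        (float(v), float(rts[sid]))
        for sid, v in zip(sel["subject_id"], sel["value"])
        if sid in rts and np.isfinite(rts[sid])
    ]
    if len(pairs) < 4:
        raise SizingError(f"only {len(pairs)} complete (metric, RT) pairs; need >= 4")
    vals = np.array([p[0] for p in pairs])
    rt = np.array([p[1] for p in pairs])
    rho, p = spearman_corr(vals, rt)
    slope, intercept = np.polyfit(vals, rt, 1)
    return BrainBehaviorResult(
        connection=connection,
        direction=direction,
        metric=metric,
        rho=rho,
        p=p,
        slope=float(slope),
        intercept=float(intercept),
        n=len(pairs),
    )
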