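"""Cut-score stability across panel sizes: one-way ANOVA per station.

Within each station, the resampled panels' cut scores are grouped by panel
size (a categorical factor with one level per size) and a fixed-effects
one-way ANOVA asks whether the group means differ.  A non-significant
omnibus F is the stability claim: panel size leaves the expected cut score
unchanged.

The classical decomposition assumes equal within-group variances.  In this
experiment that assumption is structurally violated — the sampling variance
of a cut score shrinks roughly as 1/size — which makes the classical test
somewhat liberal here.  A Welch (variance-weighted) variant is therefore
available via ``welch=True``, but the classical test is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import ValidationError
from .simulation import SizeGroupTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: float
    df_within: float
    p_value: float
    group_count: int
    total_n: int
    degenerate: bool = False
    welch: bool = False


def one_way_anova(groups: list, welch: bool = False) -> AnovaResult:
    """Omnibus F test for equality of group means.

    Classical (default): F = MSB / MSW from the standard unbalanced
    between/within sums-of-squares decomposition, with p the upper-tail F
    probability at (k-1, N-k) degrees of freedom.  When every observation
    is identical (zero between- and within-group variance) the test is
    vacuous: F is defined as 0 with p = 1 and a degeneracy flag.

    ``welch=True`` uses Welch's variance-weighted statistic with
    Satterthwaite-style denominator degrees of freedom; it requires every
    group to have at least 2 observations.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("ANOVA requires at least 2 groups")
    if any(len(a) == 0 for a in arrs):
        raise ValidationError("every group must contain at least one value")
    k = len(arrs)
    n_i = np.array([len(a) for a in arrs])
    total_n = int(n_i.sum())
    if total_n <= k:
        raise ValidationError("total observations must exceed the group count")
    if welch:
        return _welch_anova(arrs, k, n_i, total_n)
    means = np.array([a.mean() for a in arrs])
    grand = float(np.concatenate(arrs).mean())
    ssb = float((n_i * (means - grand) ** 2).sum())
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    df_b, df_w = k - 1, total_n - k
    if ssw == 0.0 and ssb == 0.0:
        return AnovaResult(0.0, df_b, df_w, 1.0, k, total_n, degenerate=True)
    if ssw == 0.0:
        # group means differ with zero noise: infinitely significant
        return AnovaResult(float("inf"), df_b, df_w, 0.0, k, total_n)
    f_stat = (ssb / df_b) / (ssw / df_w)
    return AnovaResult(
        f_stat=f_stat,
        df_between=df_b,
        df_within=df_w,
        p_value=float(f_dist.sf(f_stat, df_b, df_w)),
        group_count=k,
        total_n=total_n,
    )


def _welch_anova(arrs, k: int, n_i: np.ndarray, total_n: int) -> AnovaResult:
    if (n_i < 2).any():
        raise ValidationError("Welch ANOVA requires >= 2 observations per group")
    means = np.array([a.mean() for a in arrs])
    var_i = np.array([a.var(ddof=1) for a in arrs])
    if (var_i == 0.0).any():
        if np.allclose(means, means[0]):
            return AnovaResult(
                0.0, k - 1, float("inf"), 1.0, k, total_n, degenerate=True, welch=True
            )
        raise ValidationError("Welch ANOVA undefined with a zero-variance group")
    w_i = n_i / var_i
    w_sum = w_i.sum()
    mean_w = float((w_i * means).sum() / w_sum)
    a = float((w_i * (means - mean_w) ** 2).sum() / (k - 1))
    lam = float((((1.0 - w_i / w_sum) ** 2) / (n_i - 1)).sum())
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam
    f_stat = a / b
    df_w = (k**2 - 1.0) / (3.0 * lam)
    return AnovaResult(
        f_stat=f_stat,
        df_between=k - 1,
        df_within=df_w,
        p_value=float(f_dist.sf(f_stat, k - 1, df_w)),
        group_count=k,
        total_n=total_n,
        welch=True,
    )


def anova_by_station(
    table: SizeGroupTable, welch: bool = False
) -> dict[str, AnovaResult]:
    """Per-station ANOVA of cut scores with panel size as the factor.

    Stations with fewer than 2 size groups are skipped with a warning.
    Infinite or NaN cut scores (degenerate zero-gap panels) are excluded
    from the groups before testing.
    """
    results: dict[str, AnovaResult] = {}
    for station, grp in table.panels.groupby("station_id", sort=True):
        groups = []
        for _, g in grp.groupby("panel_size", sort=True):
            vals = g["cut_score"].to_numpy()
            vals = vals[np.isfinite(vals)]
            if len(vals):
                groups.append(vals)
        if len(groups) < 2:
            logger.warning(
                "station %s: fewer than 2 panel-size groups; ANOVA skipped",
                station,
            )
            continue
        results[str(station)] = one_way_anova(groups, welch=welch)
    return results


def size_by_station_matrix(
    table: SizeGroupTable, welch: bool = False
) -> pd.DataFrame:
    """Mean cut score per (size, station) matrix with a final p-value row.

    Rows are panel sizes, columns are stations, and the last row holds each
    station's ANOVA p-value for the between-size comparison — the layout
    used to report cut-score stability.
    """
    agg = table.aggregates()
    matrix = agg.pivot(index="panel_size", columns="station_id", values="mean_cut")
    matrix.index = matrix.index.astype(object)
    anovas = anova_by_station(table, welch=welch)
    p_row = pd.Series(
        {s: r.p_value for s, r in anovas.items()}, name="p_value", dtype=float
    )
    matrix.loc["p_value"] = p_row
    matrix.columns.name = "station_id"
    matrix.index.name = "panel_size"
    return matrix
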