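"""Relative quantification of a target gene and its day-course ANOVA.

The payoff of reference-gene screening: the target's relative quantity
is divided by the normalization factor (geometric mean of the chosen
references' quantities), log2-transformed, and tested across sampling
days with a one-way ANOVA.  A stable reference preserves a real
treatment time-course; normalizing to an unstable (drifting) reference
distorts or hides it.

Relative expression is reported calibrated to the first day group (mean
of the day-0 samples = 1), the usual presentation; the ANOVA is invariant
to that multiplicative constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import gmean

from .genorm import normalization_factor

__all__ = ["RelativeExpression", "AnovaResult", "normalize_target", "one_way_anova"]


@dataclass
class RelativeExpression:
    """Per-sample relative expression of one target under one reference plan."""

    rel: pd.Series  # calibrated ratio, > 0
    log2_rel: pd.Series
    meta: pd.DataFrame
    target: str
    refs: list[str]


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    group_means: pd.Series  # of log2_rel

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df_between": self.df[0],
            "df_within": self.df[1],
            "p": self.p,
            "group_means_log2": {str(k): float(v) for k, v in self.group_means.items()},
        }


def normalize_target(
    q: pd.DataFrame,
    meta: pd.DataFrame,
    target: str,
    refs: list[str],
    calibrate_day: str | None = None,
) -> RelativeExpression:
    """Target quantity over the references' normalization factor.

    Samples where the target or any reference is missing are dropped with
    a warning.  ``calibrate_day`` (default: the first day level) anchors
    the reported ratios at geometric-mean 1 in that day group.
    """
    refs = list(refs)
    if not 1 <= len(refs) <= 2:
        raise ValueError("normalization uses 1 or 2 reference genes")
    if target in refs:
        raise ValueError("target gene cannot be its own reference")
    for g in [target, *refs]:
        if g not in q.index:
            raise ValueError(f"gene {g!r} not in quantity matrix")
    nf = normalization_factor(q, refs)
    rel = q.loc[target] / nf
    ok = rel.notna()
    if not ok.all():
        warnings.warn(f"dropping {(~ok).sum()} sample(s) with missing quantities")
    rel = rel[ok]
    meta = meta.loc[rel.index]

    day = meta["day"]
    levels = day.cat.categories if hasattr(day, "cat") else pd.unique(day)
    cal = calibrate_day if calibrate_day is not None else levels[0]
    cal_vals = rel[day == cal]
    if len(cal_vals) == 0:
        raise ValueError(f"no samples in calibrator day {cal!r}")
    rel = rel / gmean(cal_vals)
    return RelativeExpression(
        rel=rel, log2_rel=np.log2(rel), meta=meta, target=target, refs=refs
    )


def one_way_anova(x: pd.Series, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA of (log2) expression across days.

    Five day groups of four replicates give df = (4, 15).  A degenerate
    input with zero within- and between-group variance is reported as
    F = 0, p = 1.
    """
    x = pd.Series(np.asarray(x, float))
    groups = pd.Series(np.asarray(groups), index=x.index)
    keep = x.notna()
    x, groups = x[keep], groups[keep]
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [x[groups == g].to_numpy() for g in levels]
    if min(len(a) for a in arrays) < 2:
        raise ValueError("every group needs at least 2 observations")
    n = sum(len(a) for a in arrays)
    df = (len(levels) - 1, n - len(levels))
    grand = x.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0:
        if ss_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df[0]) / (ss_within / df[1])
        p = float(stats.f.sf(f_stat, *df))
    means = pd.Series({g: float(np.mean(a)) for g, a in zip(levels, arrays)})
    return AnovaResult(F=float(f_stat), df=df, p=float(p), group_means=means)
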