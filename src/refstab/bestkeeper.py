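"""BestKeeper descriptive statistics, index and index correlations.

BestKeeper treats the candidates descriptively on the raw Ct scale: per
gene it reports location (geometric/arithmetic mean), range, and a
dispersion "SD" which in the original spreadsheet tool is the *mean
absolute deviation* from the arithmetic mean (mode ``mad`` here; the
conventional sample standard deviation is available as mode ``stdev``).
The BestKeeper index is the per-sample geometric mean of all candidates'
Ct; each gene is additionally scored by its Pearson correlation with the
index (higher |r| = better agreement with the consensus profile).

Genes with SD above 1 cycle are flagged as "inconsistent" following the
original tool's heuristic; the flag is informational and nothing is
filtered.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import gmean

from .ct_io import CtMatrix

__all__ = ["bestkeeper_stats", "bestkeeper_index", "index_correlation", "bestkeeper_table"]


def bestkeeper_stats(mat: CtMatrix | pd.DataFrame, sd_mode: str = "mad") -> pd.DataFrame:
    """Per-gene dispersion statistics on the Ct scale.

    ``sd_mode='mad'`` reproduces the original tool's "SD (+/- CP)" (mean
    absolute deviation from the arithmetic mean); ``'stdev'`` uses the
    sample standard deviation.  CV is 100 * SD / arithmetic mean.
    """
    if sd_mode not in ("mad", "stdev"):
        raise ValueError(f"sd_mode must be 'mad' or 'stdev', got {sd_mode!r}")
    ct = mat.ct if isinstance(mat, CtMatrix) else mat
    rows = {}
    for gene in ct.index:
        x = ct.loc[gene].dropna().to_numpy(float)
        if x.size < 3:
            raise ValueError(f"gene {gene!r} has fewer than 3 Ct values")
        if (x <= 0).any():
            raise ValueError(f"gene {gene!r} has nonpositive Ct")
        amean = x.mean()
        sd = float(np.abs(x - amean).mean()) if sd_mode == "mad" else float(x.std(ddof=1))
        rows[gene] = {
            "n": x.size,
            "geo_mean": float(gmean(x)),
            "ar_mean": float(amean),
            "min": float(x.min()),
            "max": float(x.max()),
            "sd": sd,
            "cv_pct": 100.0 * sd / amean,
            "inconsistent": sd > 1.0,
        }
    return pd.DataFrame(rows).T


def bestkeeper_index(mat: CtMatrix | pd.DataFrame) -> pd.Series:
    """BestKeeper index: per-sample geometric mean of all candidates' Ct.

    Requires at least 2 genes; a sample is indexed over its present genes
    and is missing only when no gene is observed there.
    """
    ct = mat.ct if isinstance(mat, CtMatrix) else mat
    if ct.shape[0] < 2:
        raise ValueError("BestKeeper index needs at least 2 genes")
    vals = ct.to_numpy(float)
    with np.errstate(invalid="ignore"):
        idx = np.exp(np.nanmean(np.log(vals), axis=0))
    idx[np.isnan(vals).all(axis=0)] = np.nan
    return pd.Series(idx, index=ct.columns, name="bestkeeper_index")


def index_correlation(mat: CtMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and two-sided p, t transform with n-2 df) of each gene vs the index.

    A zero-variance gene has no defined correlation; it is reported as
    missing with a warning rather than coerced to 0.
    """
    ct = mat.ct if isinstance(mat, CtMatrix) else mat
    idx = bestkeeper_index(ct)
    rows = {}
    for gene in ct.index:
        paired = pd.concat([ct.loc[gene], idx], axis=1).dropna()
        x, y = paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy()
        if len(x) < 3:
            raise ValueError(f"gene {gene!r}: fewer than 3 paired values with index")
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"gene {gene!r} has zero variance; correlation undefined")
            rows[gene] = {"r": np.nan, "p": np.nan, "n": len(x)}
            continue
        r, p = stats.pearsonr(x, y)
        rows[gene] = {"r": float(r), "p": float(p), "n": len(x)}
    return pd.DataFrame(rows).T


def bestkeeper_table(mat: CtMatrix | pd.DataFrame, sd_mode: str = "mad") -> pd.DataFrame:
    """Combined per-gene BestKeeper report (dispersion + index correlation)."""
    stats_tab = bestkeeper_stats(mat, sd_mode=sd_mode)
    corr = index_correlation(mat)
    return stats_tab.join(corr[["r", "p"]])
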