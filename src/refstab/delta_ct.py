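"""Comparative delta-Ct method.

The simplest of the four stability algorithms: for every ordered gene
pair (i, i'), form the per-sample Ct difference and take its standard
deviation across samples; a gene's stability value is the mean of those
SDs over all partners.  A gene whose Ct moves in lockstep with the
others (up to an additive offset) scores 0.

When every assay amplifies with perfect doubling (E = 2),
log2(q_i / q_i') = -(Ct_i - Ct_i') up to a constant, so these values
coincide exactly with the geNorm M values on the full gene set — a
useful cross-check between the two modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ct_io import CtMatrix
from .genorm import StabilityScore
from .consensus import competition_ranks

__all__ = ["deltact_stability", "deltact_rank"]


def deltact_stability(mat: CtMatrix | pd.DataFrame) -> pd.Series:
    """Mean pairwise-difference SD per gene (lower = more stable).

    Operates on raw Ct values; pairwise SDs use pairwise-complete samples
    with the n-1 denominator.
    """
    ct = mat.ct if isinstance(mat, CtMatrix) else mat
    genes = list(ct.index)
    if len(genes) < 2:
        raise ValueError("delta-Ct method needs at least 2 genes")
    out = {}
    for i in genes:
        sds = []
        for j in genes:
            if j == i:
                continue
            d = (ct.loc[i] - ct.loc[j]).dropna()
            if len(d) < 2:
                raise ValueError(
                    f"fewer than 2 overlapping samples for pair ({i}, {j})"
                )
            sds.append(d.std(ddof=1))
        out[i] = float(np.mean(sds))
    return pd.Series(out, name="delta_ct")


def deltact_rank(mat: CtMatrix | pd.DataFrame) -> list[StabilityScore]:
    """Stability scores with competition ranks, ascending stability."""
    stab = deltact_stability(mat)
    ranks = competition_ranks(stab, direction="asc")
    return [
        StabilityScore(g, "delta_ct", float(stab[g]), int(ranks[g]))
        for g in stab.index
    ]
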