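"""geNorm: pairwise stability value M, stepwise ranking, NF and V-series.

geNorm scores a candidate reference gene by how constant its expression
ratio is to every other candidate.  For genes j and k, the pairwise
variation V_jk is the standard deviation across samples of
log2(q_j / q_k); a gene's stability value M_j is the mean of V_jk over
all partners k.  Perfectly co-regulated (or perfectly stable) genes give
M = 0, and lower M means more stable.

The full algorithm ranks genes by repeatedly discarding the gene with the
largest M and recomputing on the remainder until two genes are left;
these two are algorithmically indistinguishable and share rank 1.  The
pairwise variation V_{n/n+1} between normalization factors built from the
top n and n+1 genes decides how many reference genes are needed: the
smallest n with V below 0.15 (conventional threshold) suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "StabilityScore",
    "PairwiseVariationSeries",
    "genorm_m",
    "genorm_rank",
    "normalization_factor",
    "pairwise_variation_series",
]


@dataclass
class StabilityScore:
    """One gene's stability value under one method, with its competition rank."""

    gene: str
    method: str
    value: float
    rank: int


@dataclass
class PairwiseVariationSeries:
    """V_{n/n+1} entries (n = 2..k-1) and the resulting gene-count advice."""

    v: dict[int, float]  # n -> V_{n/n+1}
    threshold: float
    recommended_n: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": list(self.v), "V": list(self.v.values())}
        ).set_index("n")


def recommend_n(v: dict[int, float], threshold: float = 0.15) -> int | None:
    """Smallest n whose V_{n/n+1} is below the threshold (None if none is).

    The conventional cut-off is 0.15: adding the (n+1)-th reference gene
    changes the normalization factor negligibly once V drops below it.
    """
    for n in sorted(v):
        if v[n] < threshold:
            return n
    return None


def _pair_sd(log_q: pd.DataFrame, j: str, k: str) -> float:
    a = log_q.loc[j] - log_q.loc[k]
    a = a.dropna()
    if len(a) < 2:
        raise ValueError(f"fewer than 2 overlapping samples for pair ({j}, {k})")
    return float(a.std(ddof=1))


def genorm_m(q: pd.DataFrame, genes: list[str] | None = None) -> pd.Series:
    """Stability value M per gene over the given subset (default: all genes).

    ``q`` is a genes x samples quantity matrix.  Pairwise SDs use the
    samples where both genes are observed; the sample SD uses the n-1
    denominator throughout.
    """
    genes = list(q.index) if genes is None else list(genes)
    if len(genes) < 2:
        raise ValueError("geNorm needs at least 2 genes")
    log_q = np.log2(q.loc[genes])
    m = {}
    for j in genes:
        sds = [_pair_sd(log_q, j, k) for k in genes if k != j]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm_rank(q: pd.DataFrame) -> tuple[list[StabilityScore], pd.DataFrame]:
    """Stepwise-exclusion geNorm ranking.

    Iteratively removes the gene with the largest M (its M at removal is
    its stability value) until two remain; the final pair is tied at
    rank 1 with the final-pair M, and the next gene takes rank 3
    (competition ranking).  Ties in M during exclusion are broken by
    removing the later gene in input order.

    Returns the scores (input order) and a trace of M values per stage.
    """
    genes = list(q.index)
    if len(genes) < 2:
        raise ValueError("geNorm needs at least 2 genes")
    remaining = list(genes)
    removal_value: dict[str, float] = {}
    order_out: list[str] = []
    trace_rows = []
    while len(remaining) > 2:
        m = genorm_m(q, remaining)
        trace_rows.append(m.rename(f"stage_k{len(remaining)}"))
        worst_val = m.max()
        # later gene in input order among ties
        worst = [g for g in remaining if m[g] == worst_val][-1]
        removal_value[worst] = float(m[worst])
        order_out.append(worst)
        remaining.remove(worst)
    m_final = genorm_m(q, remaining)
    trace_rows.append(m_final.rename(f"stage_k{len(remaining)}"))
    for g in remaining:
        removal_value[g] = float(m_final[g])

    # final pair shares rank 1; the rest take competition ranks 3, 4, ...
    ranks: dict[str, int] = {g: 1 for g in remaining}
    for pos, g in enumerate(reversed(order_out)):
        ranks[g] = 3 + pos
    scores = [
        StabilityScore(g, "genorm", removal_value[g], ranks[g]) for g in genes
    ]
    trace = pd.concat(trace_rows, axis=1)
    return scores, trace


def normalization_factor(q: pd.DataFrame, genes: list[str]) -> pd.Series:
    """NF_n per sample: geometric mean of the n listed genes' quantities.

    A missing quantity for any listed gene makes NF missing at that sample.
    """
    if not genes:
        raise ValueError("need at least one reference gene")
    missing = set(genes) - set(q.index)
    if missing:
        raise ValueError(f"genes not in quantity matrix: {sorted(missing)}")
    sub = q.loc[list(genes)]
    nf = pd.Series(gmean(sub, axis=0), index=q.columns, name="NF")
    nf[sub.isna().any(axis=0)] = np.nan
    return nf


def pairwise_variation_series(
    q: pd.DataFrame, ranking: list[str], threshold: float = 0.15
) -> PairwiseVariationSeries:
    """V_{n/n+1} series along a stability ranking, with the gene-count rule.

    V_{n/n+1} is the sample SD over samples of log2(NF_n / NF_{n+1}),
    adding genes in ranking order.  ``recommended_n`` is the smallest n
    whose V falls below ``threshold`` (none if the series never does).
    """
    k = len(ranking)
    if k < 3:
        raise ValueError("pairwise variation needs at least 3 ranked genes")
    v: dict[int, float] = {}
    for n in range(2, k):
        nf_n = normalization_factor(q, ranking[:n])
        nf_n1 = normalization_factor(q, ranking[: n + 1])
        ratio = np.log2(nf_n / nf_n1).dropna()
        v[n] = float(ratio.std(ddof=1))
    recommended = recommend_n(v, threshold)
    return PairwiseVariationSeries(v=v, threshold=threshold, recommended_n=recommended)
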