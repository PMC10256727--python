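"""Consensus ranking (geometric mean of method ranks) and pair selection.

The four stability algorithms rarely agree exactly, so the accepted
practice is to aggregate them: each gene receives a competition rank
under each method, and the comprehensive stability value GM is the
geometric mean of the four ranks (delta-Ct, NormFinder, geNorm,
BestKeeper-SD).  GM ranges from 1 (unanimously best) to k (unanimously
worst) and orders the final consensus.

Choosing the actual normalization plan adds two rules on top of the
consensus order: the geNorm V_{n/n+1} series recommends how many
reference genes to use (capped by practicality, default 2), and a
candidate partner for the top gene is accepted only if the two genes'
raw-Ct Pearson correlation is strictly below a threshold (default 0.9) —
two highly correlated references carry the same information and buy no
reduction in technical variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ct_io import CtMatrix
from .genorm import PairwiseVariationSeries

__all__ = [
    "ConsensusRanking",
    "NormalizationPlan",
    "competition_ranks",
    "reffinder_gm",
    "passes_correlation_gate",
    "select_pair",
]

#: Aggregated methods, in report order.
METHODS = ("delta_ct", "normfinder", "genorm", "bestkeeper")


@dataclass
class ConsensusRanking:
    """Per-gene method ranks and their geometric mean, ascending GM order."""

    table: pd.DataFrame  # columns: rank_<method>..., gm; index: gene, ordered

    @property
    def order(self) -> list[str]:
        return list(self.table.index)

    @property
    def top(self) -> str:
        return self.table.index[0]


@dataclass
class NormalizationPlan:
    primary_ref: str
    partner_ref: str | None
    partner_r: float | None
    rejected: list[tuple[str, float]] = field(default_factory=list)
    recommended_n: int | None = None
    capped_n: int | None = None

    @property
    def references(self) -> list[str]:
        refs = [self.primary_ref]
        if self.partner_ref is not None:
            refs.append(self.partner_ref)
        return refs

    def to_dict(self) -> dict:
        return {
            "primary_ref": self.primary_ref,
            "partner_ref": self.partner_ref,
            "partner_r": self.partner_r,
            "rejected": [{"gene": g, "r": r} for g, r in self.rejected],
            "recommended_n": self.recommended_n,
            "capped_n": self.capped_n,
        }


def competition_ranks(
    values: pd.Series,
    direction: str = "asc",
    shared_rank_pairs: set[str] | None = None,
) -> pd.Series:
    """Competition ("1224") ranks of a per-gene statistic.

    Tied genes share the lowest rank and the next gene skips accordingly.
    ``direction='desc'`` ranks larger values better (used for
    BestKeeper's |r|).  Genes in ``shared_rank_pairs`` are forced to share
    rank 1 regardless of their values (the geNorm final pair, which the
    stepwise algorithm cannot separate).
    """
    if direction not in ("asc", "desc"):
        raise ValueError("direction must be 'asc' or 'desc'")
    key = values.astype(float)
    if direction == "desc":
        key = -key
    if shared_rank_pairs:
        unknown = set(shared_rank_pairs) - set(values.index)
        if unknown:
            raise ValueError(f"shared-rank genes not present: {sorted(unknown)}")
        key = key.copy()
        key[list(shared_rank_pairs)] = -np.inf
    ranks = stats.rankdata(key.to_numpy(), method="min")
    return pd.Series(ranks.astype(int), index=values.index, name="rank")


def ranks_from_ordering(
    ordering: list, shared_rank_pairs: set[str] | None = None
) -> pd.Series:
    """Competition ranks from a published most-stable-first ordering.

    ``ordering`` is a list of gene names or (gene, value) pairs, most
    stable first.  Published tables print values to limited precision, so
    apparent value ties are resolved by row order; genes in
    ``shared_rank_pairs`` (a genuine tie, e.g. the geNorm final pair at
    the head of the list) all receive rank 1, and the following gene's
    rank skips accordingly by its row position.
    """
    genes = [g[0] if isinstance(g, (tuple, list)) else g for g in ordering]
    ranks = {g: i + 1 for i, g in enumerate(genes)}
    if shared_rank_pairs:
        unknown = set(shared_rank_pairs) - set(genes)
        if unknown:
            raise ValueError(f"shared-rank genes not present: {sorted(unknown)}")
        for g in shared_rank_pairs:
            ranks[g] = 1
    return pd.Series(ranks, name="rank")


def reffinder_gm(ranks: dict[str, pd.Series]) -> ConsensusRanking:
    """Geometric mean of the four method ranks, ordered ascending.

    ``ranks`` maps each method in ``METHODS`` to an aligned per-gene rank
    Series.  GM ties are broken by the delta-Ct rank; GM is reported to 2
    decimals but ordering uses the unrounded value.
    """
    missing = set(METHODS) - set(ranks)
    if missing:
        raise ValueError(f"missing method ranks: {sorted(missing)}")
    gene_sets = {m: set(r.index) for m, r in ranks.items()}
    ref = gene_sets[METHODS[0]]
    if any(s != ref for s in gene_sets.values()):
        raise ValueError("method rank vectors cover different gene sets")
    tab = pd.DataFrame({f"rank_{m}": ranks[m] for m in METHODS}).astype(int)
    gm = np.power(tab.prod(axis=1).astype(float), 1.0 / len(METHODS))
    tab["gm_exact"] = gm
    tab["gm"] = gm.round(2)
    tab = tab.sort_values(["gm_exact", "rank_delta_ct"], kind="stable")
    return ConsensusRanking(tab)


def passes_correlation_gate(r: float, r_threshold: float = 0.9) -> bool:
    """True when a partner's correlation with the primary is acceptably low.

    Strict inequality on the unrounded value: r = 0.899 passes at the 0.9
    threshold, r = 0.9 does not.
    """
    return abs(r) < r_threshold


def select_pair(
    mat: CtMatrix | pd.DataFrame,
    consensus: ConsensusRanking,
    v_series: PairwiseVariationSeries | None = None,
    r_threshold: float = 0.9,
    max_refs: int = 2,
) -> NormalizationPlan:
    """Choose the reference gene(s) for normalization.

    The consensus-top gene is always the primary reference.  Remaining
    genes are scanned in ascending GM order; the first whose raw-Ct
    Pearson correlation with the primary passes the gate becomes the
    partner.  If every candidate is too correlated, the plan falls back
    to a single reference.  The geNorm recommendation (number of genes)
    is carried along, capped at ``max_refs`` for practicality.
    """
    ct = mat.ct if isinstance(mat, CtMatrix) else mat
    order = consensus.order
    primary = order[0]
    partner, partner_r = None, None
    rejected: list[tuple[str, float]] = []
    for gene in order[1:]:
        paired = pd.concat([ct.loc[primary], ct.loc[gene]], axis=1).dropna()
        r, _ = stats.pearsonr(paired.iloc[:, 0], paired.iloc[:, 1])
        if passes_correlation_gate(r, r_threshold):
            partner, partner_r = gene, float(r)
            break
        rejected.append((gene, float(r)))
    recommended = v_series.recommended_n if v_series is not None else None
    capped = min(recommended, max_refs) if recommended is not None else None
    return NormalizationPlan(
        primary_ref=primary,
        partner_ref=partner,
        partner_r=partner_r,
        rejected=rejected,
        recommended_n=recommended,
        capped_n=capped,
    )
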