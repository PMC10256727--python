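"""NormFinder: model-based stability from intra- and intergroup variation.

NormFinder models the log-scale expression of gene i in sample j of
group g as

    y_igj = alpha_ig + mu_g + beta_gj + eps_igj

where mu_g + beta_gj is the sample-specific amount common to all genes
(removed by centering each sample across genes), alpha_ig carries a
gene-by-group bias, and eps has gene-by-group variance sigma^2_ig.  A
good reference gene has both a small intragroup variance sigma^2_ig and
a small intergroup bias gamma_ig (deviation of its group means from its
overall mean).  The two are combined per group as

    rho_ig = |gamma_hat_ig| + sqrt(sigma_hat^2_ig / n_g)

and the stability value is the mean of rho_ig over groups (lower =
better).  The intergroup deviations are shrunk toward zero by an
empirical-Bayes factor so that noisy group means in small groups do not
masquerade as bias.

With a single group the bias term vanishes and the stability value
reduces to sqrt(sigma_hat^2_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genorm import StabilityScore
from .consensus import competition_ranks

__all__ = ["NormfinderResult", "normfinder_stability", "normfinder_rank"]


@dataclass
class NormfinderResult:
    stability: pd.Series  # per gene, lower = better
    intra_var: pd.DataFrame  # sigma_hat^2, genes x groups
    inter_dev: pd.DataFrame  # shrunk gamma_hat, genes x groups (0 when G == 1)
    groups: list[str]


def normfinder_stability(y: pd.DataFrame, groups) -> NormfinderResult:
    """NormFinder stability per gene.

    Parameters
    ----------
    y
        Genes x samples matrix on a log2 scale (log2 of relative
        quantities; with perfect doubling this is -Ct up to per-gene
        constants, which cancel).  Samples with any missing gene are
        dropped (the model needs complete gene profiles per sample).
    groups
        Group label per sample (aligned with ``y``'s columns), e.g.
        sampling day.  Needs >= 3 genes; with more than one group every
        group needs >= 2 samples.
    """
    groups = pd.Series(np.asarray(groups), index=y.columns)
    complete = ~y.isna().any(axis=0)
    y = y.loc[:, complete]
    groups = groups[complete]

    k = y.shape[0]
    if k < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    levels = list(pd.unique(groups))
    n_g = {g: int((groups == g).sum()) for g in levels}
    G = len(levels)
    if G > 1 and min(n_g.values()) < 2:
        raise ValueError("every group needs at least 2 samples")

    # remove the sample-specific common amount
    d = y - y.mean(axis=0)

    dbar = pd.DataFrame(index=y.index, columns=levels, dtype=float)
    s2 = pd.DataFrame(index=y.index, columns=levels, dtype=float)
    for g in levels:
        sub = d.loc[:, groups == g]
        dbar[g] = sub.mean(axis=1)
        s2[g] = sub.var(axis=1, ddof=1)

    # separate the common-variance contamination introduced by centering
    sum_s2 = s2.sum(axis=0)  # per group, over genes
    sigma2 = (k / (k - 2)) * (s2 - sum_s2 / (k * (k - 1)))
    sigma2 = sigma2.clip(lower=0.0)

    if G == 1:
        stability = np.sqrt(sigma2[levels[0]])
        stability.name = "normfinder"
        gamma = pd.DataFrame(0.0, index=y.index, columns=levels)
        return NormfinderResult(stability, sigma2, gamma, [str(g) for g in levels])

    z = dbar.sub(dbar.mean(axis=1), axis=0)  # intergroup deviations, sum 0 per gene
    n_vec = pd.Series(n_g)
    var_of_mean = sigma2.div(n_vec, axis=1)  # sigma^2_ig / n_g
    tau2 = max(
        0.0,
        float((z**2).to_numpy().sum() / ((G - 1) * k) - var_of_mean.to_numpy().mean()),
    )
    gamma = z * (tau2 / (tau2 + var_of_mean)) if tau2 > 0 else z * 0.0
    rho = gamma.abs() + np.sqrt(var_of_mean)
    stability = rho.mean(axis=1)
    stability.name = "normfinder"
    return NormfinderResult(stability, sigma2, gamma, [str(g) for g in levels])


def normfinder_rank(result: NormfinderResult) -> list[StabilityScore]:
    """Competition ranks, ascending stability value."""
    ranks = competition_ranks(result.stability, direction="asc")
    return [
        StabilityScore(g, "normfinder", float(result.stability[g]), int(ranks[g]))
        for g in result.stability.index
    ]
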