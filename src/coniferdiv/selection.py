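"""Adjusted SNP A/S ratios, the binomial excess test and PSG calling.

The A/S ratio of a gene is the number of SNPs per nonsynonymous site (A)
divided by the number of SNPs per synonymous site (S) — the intraspecific
analogue of Ka/Ks.  To keep the statistic finite for genes with no
synonymous SNPs the empirical-logit adjusted form is used throughout::

    adj = ((A + 0.5) / (La + 1)) / ((S + 0.5) / (Ls + 1))

A gene is flagged as a putative positively selected gene (PSG) when its
adjusted ratio exceeds 1 AND the probability of an excess of nonsynonymous
SNPs at least as large arising by chance is below ``alpha`` (5% by default).
"Chance" is the neutral allocation null: each of the gene's n = A + S SNPs
falls on a nonsynonymous site with probability p0 = La / (La + Ls), so the
nonsynonymous count K is Binomial(n, p0) and the reported probability is the
exact tail P(K >= max(A, k*)), where k* is the smallest nonsynonymous count
whose adjusted ratio exceeds 1.  For an observed ratio <= 1 this reduces to
the unconditional chance P(adjusted ratio > 1); for a ratio > 1 it is the
usual one-sided exact binomial tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneSelectionRecord:
    gene_id: str
    A: int
    S: int
    La: float
    Ls: float
    adj_ratio: float
    p_null: float
    is_psg: bool = False


@dataclass
class PsgSummary:
    species: str
    n_genes_tested: int
    n_ratio_gt1: int
    n_psg: int
    psg_proportion: float
    mean_psg_ratio: float


def adjusted_as_ratio(A: int, S: int, La: float, Ls: float) -> float:
    """Empirical-logit adjusted A/S ratio; finite for all valid inputs."""
    if A < 0 or S < 0:
        raise ValueError("SNP counts must be non-negative")
    if La <= 0 and Ls <= 0:
        raise ValueError("La or Ls must be positive")
    return ((A + 0.5) / (La + 1.0)) / ((S + 0.5) / (Ls + 1.0))


def min_nonsyn_for_excess(n: int, La: float, Ls: float) -> Optional[int]:
    """Smallest nonsynonymous count k with adjusted ratio of (k, n-k) > 1.

    Returns None when no allocation of n SNPs yields a ratio above 1.
    """
    # (k + 0.5)(Ls + 1) > (n - k + 0.5)(La + 1)
    for k in range(n + 1):
        if (k + 0.5) * (Ls + 1.0) > (n - k + 0.5) * (La + 1.0):
            return k
    return None


def psg_null_probability(A: int, S: int, La: float, Ls: float) -> float:
    """Probability of a chance nonsynonymous excess with adjusted ratio > 1.

    Exact binomial tail P(K >= max(A, k*)) with K ~ Bin(A+S, La/(La+Ls));
    0 when no allocation of the n SNPs can push the adjusted ratio above 1
    (in particular for n = 0).
    """
    if A < 0 or S < 0:
        raise ValueError("SNP counts must be non-negative")
    if La + Ls <= 0:
        raise ValueError("La + Ls must be positive")
    n = A + S
    k_star = min_nonsyn_for_excess(n, La, Ls)
    if k_star is None:
        return 0.0
    p0 = La / (La + Ls)
    lo = max(A, k_star)
    return float(stats.binom.sf(lo - 1, n, p0))


def call_psgs(
    records: pd.DataFrame, alpha: float = 0.05, bh: bool = False
) -> pd.DataFrame:
    """Set the ``is_psg`` flag on a per-gene selection table.

    ``records`` needs columns (adj_ratio, p_null).  With ``bh=True`` the
    significance gate uses Benjamini–Hochberg adjusted probabilities instead
    of the raw per-gene 5% rule.
    """
    out = records.copy()
    p = out["p_null"].to_numpy(float)
    if bh:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        out["p_bh"] = p_adj
        sig = p_adj < alpha
    else:
        sig = p < alpha
    out["is_psg"] = (out["adj_ratio"].to_numpy(float) > 1.0) & sig
    return out


def gene_selection_table(
    as_counts: pd.DataFrame, alpha: float = 0.05, bh: bool = False
) -> pd.DataFrame:
    """Build the per-gene selection table from A/S counts and site counts.

    ``as_counts`` needs columns (gene_id, A, S, La, Ls); adds adj_ratio,
    p_null and is_psg.
    """
    df = as_counts.copy()
    df["adj_ratio"] = [
        adjusted_as_ratio(a, s, la, ls)
        for a, s, la, ls in zip(df["A"], df["S"], df["La"], df["Ls"])
    ]
    df["p_null"] = [
        psg_null_probability(a, s, la, ls)
        for a, s, la, ls in zip(df["A"], df["S"], df["La"], df["Ls"])
    ]
    return call_psgs(df, alpha=alpha, bh=bh)


def summarize_psgs(records: pd.DataFrame, species: str) -> PsgSummary:
    """Per-species PSG summary; proportion is over all ORFs tested."""
    n = len(records)
    gt1 = int((records["adj_ratio"] > 1.0).sum())
    psg = records[records["is_psg"]]
    return PsgSummary(
        species=species,
        n_genes_tested=n,
        n_ratio_gt1=gt1,
        n_psg=len(psg),
        psg_proportion=len(psg) / n if n else float("nan"),
        mean_psg_ratio=float(psg["adj_ratio"].mean()) if len(psg) else float("nan"),
    )


def psg_diversity_regression(
    psg_proportions: Sequence[float], snp_totals: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS of per-species PSG proportion on adjusted SNP total.

    Returns (slope, intercept, R^2, two-sided slope p-value).
    """
    import statsmodels.api as sm

    y = np.asarray(psg_proportions, float)
    x = np.asarray(snp_totals, float)
    if len(x) < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return (
        float(fit.params[1]),
        float(fit.params[0]),
        float(fit.rsquared),
        float(fit.pvalues[1]),
    )
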