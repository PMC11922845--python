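"""Negative-binomial adjustment of per-transcript SNP counts and
cross-species diversity comparison.

Transcript length and read depth vary widely within and between
transcriptome assemblies, and the expected number of SNPs detected in a
transcript grows with both.  Before species can be compared, per-transcript
SNP counts are therefore modelled as negative-binomially distributed with a
log link on log(length), log(depth) and species indicators, and each count
is rescaled to common reference covariates (the median length and depth)::

    adjusted_i = raw_i * exp(eta(ref) - eta(i))   # species term held fixed

Species-level heterogeneity is tested with a Kruskal–Wallis rank test, and
species are partitioned into diversity groups by joining every pair that is
non-significant under BOTH the two-sample Kolmogorov–Smirnov and
Cramér–von Mises tests and taking connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NBFit:
    """Fitted negative-binomial SNP-abundance model (NB2 parameterization)."""

    intercept: float
    log_length_coef: float
    log_depth_coef: float
    species_offsets: dict[str, float]  # relative to the reference species
    alpha: float                       # NB2 dispersion: var = mu + alpha mu^2
    reference_covariates: tuple[float, float]  # (length_ref, depth_ref)
    converged: bool = True
    loglike: float = float("nan")
    bse: Optional[pd.Series] = None
    params: Optional[pd.Series] = None


@dataclass
class SpeciesDiversitySummary:
    species: str
    n_transcripts: int
    n_snps_raw: int
    n_snps_adjusted: float
    n_transcripts_with_snps_adjusted: int
    mean_snps_per_transcript: float      # rounded to 1 decimal
    proportion_transcripts_with_snps: float  # percent, rounded to 0.1


@dataclass
class DiversityGrouping:
    species: list[str]
    ks_pvalues: pd.DataFrame
    cvm_pvalues: pd.DataFrame
    groups: list[list[str]] = field(default_factory=list)
    alpha: float = 0.05


REQUIRED_COLS = ("transcript_id", "species", "snp_count", "coding_length", "mean_depth")


def fit_snp_abundance_model(table: pd.DataFrame) -> NBFit:
    """ML negative-binomial regression of SNP counts on covariates.

    ``table`` needs columns (snp_count, coding_length, mean_depth, species).
    The first species in sorted order is the reference level; its effect is
    absorbed into the intercept.
    """
    import statsmodels.api as sm

    counts = table["snp_count"].to_numpy(float)
    if counts.min() < 0 or np.any(counts != np.round(counts)):
        raise ValueError("snp_count must hold non-negative integers")
    if counts.max() == 0:
        raise ValueError("degenerate fit: all SNP counts are zero")
    lengths = table["coding_length"].to_numpy(float)
    depths = table["mean_depth"].to_numpy(float)
    if lengths.min() <= 0 or depths.min() <= 0:
        raise ValueError("lengths and depths must be positive")

    species = pd.Categorical(table["species"])
    exog = pd.DataFrame({
        "const": 1.0,
        "log_length": np.log(lengths),
        "log_depth": np.log(depths),
    })
    single_species = len(species.categories) < 2
    for cat in species.categories[1:]:
        exog[f"species[{cat}]"] = (species == cat).astype(float)
    varying = [c for c in ("log_length", "log_depth") if exog[c].nunique() > 1]
    if not varying and not single_species:
        raise ValueError("zero-variance covariates")
    exog = exog[["const", *varying, *[c for c in exog if c.startswith("species[")]]]

    model = sm.NegativeBinomial(counts, exog, loglike_method="nb2")
    res = model.fit(disp=False, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"NB fit did not converge: {res.mle_retvals}")
    params = pd.Series(res.params, index=list(exog.columns) + ["alpha"])
    offsets = {
        str(cat): float(params.get(f"species[{cat}]", 0.0))
        for cat in species.categories
    }
    return NBFit(
        intercept=float(params["const"]),
        log_length_coef=float(params.get("log_length", 0.0)),
        log_depth_coef=float(params.get("log_depth", 0.0)),
        species_offsets=offsets,
        alpha=float(params["alpha"]),
        reference_covariates=(float(np.median(lengths)), float(np.median(depths))),
        converged=True,
        loglike=float(res.llf),
        bse=pd.Series(res.bse, index=params.index),
        params=params,
    )


def adjust_counts(fit: NBFit, table: pd.DataFrame) -> np.ndarray:
    """Rescale raw counts to the model's reference length and depth.

    Multiplies each raw count by exp(eta_ref - eta_i) on the length/depth
    part of the linear predictor, leaving the species term untouched; zeros
    stay zero and counts at the reference covariates are returned unchanged.
    """
    lengths = table["coding_length"].to_numpy(float)
    depths = table["mean_depth"].to_numpy(float)
    lref, dref = fit.reference_covariates
    eta_diff = (
        fit.log_length_coef * (np.log(lref) - np.log(lengths))
        + fit.log_depth_coef * (np.log(dref) - np.log(depths))
    )
    return table["snp_count"].to_numpy(float) * np.exp(eta_diff)


def species_heterogeneity_test(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis rank test of SNP-rate heterogeneity among species."""
    if len(groups) < 2:
        raise ValueError("need at least two species")
    arrays = []
    for name, values in groups.items():
        arr = np.asarray(values, float)
        if arr.size < 2:
            raise ValueError(f"species {name!r} has fewer than 2 observations")
        arrays.append(arr)
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        return 0.0, 1.0  # identical samples: H = 0 by definition
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def group_species(
    distributions: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    require_both: bool = True,
) -> DiversityGrouping:
    """Partition species into diversity groups.

    All pairwise two-sample Kolmogorov–Smirnov and Cramér–von Mises tests
    are computed; two species are joined when the pair is non-significant
    under both tests (or under either, with ``require_both=False``), and
    groups are the connected components of the resulting graph, ordered by
    decreasing mean adjusted count.
    """
    names = list(distributions)
    if len(names) < 2:
        raise ValueError("need at least two species")
    data = {k: np.asarray(v, float) for k, v in distributions.items()}
    ks = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    cvm = ks.copy()
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p_ks = float(stats.ks_2samp(data[a], data[b]).pvalue)
            p_cvm = float(stats.cramervonmises_2samp(data[a], data[b]).pvalue)
            ks.loc[a, b] = ks.loc[b, a] = p_ks
            cvm.loc[a, b] = cvm.loc[b, a] = p_cvm
            non_sig = (p_ks > alpha, p_cvm > alpha)
            joined = all(non_sig) if require_both else any(non_sig)
            if joined:
                parent[find(a)] = find(b)

    comps: dict[str, list[str]] = {}
    for n in names:
        comps.setdefault(find(n), []).append(n)
    groups = sorted(
        comps.values(),
        key=lambda g: -float(np.mean([np.mean(data[s]) for s in g])),
    )
    return DiversityGrouping(names, ks, cvm, [sorted(g) for g in groups], alpha)


def summarize_from_counts(
    species: str,
    n_transcripts: int,
    n_snps_raw: int,
    n_snps_adjusted: float,
    n_transcripts_with_snps_adjusted: int,
) -> SpeciesDiversitySummary:
    """Derive the reported per-species diversity metrics from count columns.

    The mean number of SNPs per polymorphic transcript is reported to one
    decimal and the proportion of polymorphic transcripts to 0.1 percent.
    """
    if n_transcripts_with_snps_adjusted > 0:
        mean = round(n_snps_adjusted / n_transcripts_with_snps_adjusted, 1)
    else:
        mean = float("nan")
    prop = round(100.0 * n_transcripts_with_snps_adjusted / n_transcripts, 1)
    return SpeciesDiversitySummary(
        species=species,
        n_transcripts=n_transcripts,
        n_snps_raw=n_snps_raw,
        n_snps_adjusted=n_snps_adjusted,
        n_transcripts_with_snps_adjusted=n_transcripts_with_snps_adjusted,
        mean_snps_per_transcript=mean,
        proportion_transcripts_with_snps=prop,
    )


def summarize_species(table: pd.DataFrame) -> list[SpeciesDiversitySummary]:
    """Per-species summary from a per-transcript table.

    ``table`` needs columns (species, snp_count, adjusted_count).
    """
    out = []
    for sp, grp in table.groupby("species", sort=True):
        adj = grp["adjusted_count"].to_numpy(float)
        out.append(
            summarize_from_counts(
                species=str(sp),
                n_transcripts=len(grp),
                n_snps_raw=int(grp["snp_count"].sum()),
                n_snps_adjusted=float(adj.sum()),
                n_transcripts_with_snps_adjusted=int((adj > 0).sum()),
            )
        )
    return out
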