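"""Calibration and recovery experiments on synthetic data.

Several of the package's guarantees are statistical rather than exact: the
binomial excess test must be conservative, the negative-binomial fit must
recover generative coefficients, the species-grouping procedure must
recover a planted partition, and the PSG caller must recover injected
selection signals.  The experiments here measure those properties under
controlled conditions; they are used by the test suite and by the results
reproduction script.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codon, diversity, filtering, selection
from .data import DIVERSITY_GROUPS, SPECIES_MEAN_SNPS
from .synthetic import SyntheticConfig, generate_species_dataset


def grouping_recovery(
    n_seeds: int = 100,
    n_transcripts: int = 2000,
    means: tuple = SPECIES_MEAN_SNPS,
    dispersion: float = 1.2,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """How often KS/CvM grouping recovers the three-way diversity partition.

    Per-transcript adjusted counts for seven species are drawn from negative
    binomials at the published per-species means, and
    :func:`coniferdiv.diversity.group_species` is scored against the planted
    highest / intermediate / lowest partition.
    """
    target = {
        frozenset(f"sp{i + 1}" for i in grp) for grp in DIVERSITY_GROUPS
    }
    successes = 0
    n_three = 0
    for rep in range(n_seeds):
        rng = np.random.default_rng([seed, 7001, rep])
        dists = {
            f"sp{i + 1}": rng.negative_binomial(
                dispersion, dispersion / (dispersion + m), n_transcripts
            ).astype(float)
            for i, m in enumerate(means)
        }
        grouping = diversity.group_species(dists, alpha=alpha)
        part = {frozenset(g) for g in grouping.groups}
        n_three += len(part) == 3
        successes += part == target
    return dict(
        n_seeds=n_seeds,
        success_rate=successes / n_seeds,
        three_group_rate=n_three / n_seeds,
    )


def psg_recovery(
    n_genes: int = 200,
    n_replicates: int = 5,
    multiplier: float = 3.0,
    mean_snps_per_gene: float = 10.0,
    psg_fraction: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recall and false-positive rate of the full PSG pipeline on truth.

    Each replicate generates one species, runs paralog subtraction, ORF
    prediction, eligibility filtering, SNP classification and PSG calling,
    and scores the calls against the injected truth.
    """
    mean_sites = 894.0  # expected coding sites under the default lengths
    tp = fn = fp = tn = 0
    for rep in range(n_replicates):
        cfg = SyntheticConfig(
            n_species=1,
            n_transcripts_per_species=n_genes,
            snp_rate_per_species=(mean_snps_per_gene / mean_sites,),
            psg_fraction=psg_fraction,
            psg_nonsyn_multiplier=multiplier,
            seed=seed * 1000 + rep,
        )
        ds = generate_species_dataset(cfg, 0)
        kept = filtering.subtract_paralogous(
            ds.embryo_variants, ds.megagametophyte_variants
        )
        orf_tab = codon.orf_table(ds.transcripts)
        elig = filtering.eligible_transcripts(ds.depth_table, orf_tab)
        kept = filtering.restrict_to_eligible(kept, elig)
        orfs = {
            r.transcript_id: codon.OrfInterval(
                r.transcript_id, int(r.start), int(r.end), r.strand, int(r.frame)
            )
            for r in orf_tab.itertuples()
        }
        counts: dict[str, list[int]] = {}
        for v in kept:
            orf = orfs.get(v.transcript_id)
            if orf is None:
                continue
            eff = codon.classify_snp(
                orf, ds.transcripts[v.transcript_id], v.position, v.ref, v.alt
            )
            if eff is None or eff.category == "noncoding":
                continue
            pair = counts.setdefault(v.transcript_id, [0, 0])
            pair[0 if eff.category == "nonsynonymous" else 1] += 1
        sites = orf_tab.set_index("transcript_id")[["La", "Ls"]]
        eligible = set(elig.loc[elig["eligible"], "transcript_id"])
        rows = [
            dict(gene_id=t, A=counts.get(t, (0, 0))[0], S=counts.get(t, (0, 0))[1],
                 La=float(sites.loc[t, "La"]), Ls=float(sites.loc[t, "Ls"]))
            for t in sorted(eligible & set(sites.index))
        ]
        sel = selection.gene_selection_table(pd.DataFrame(rows), alpha=alpha)
        truth = ds.truth.genes.set_index("gene_id")["true_psg"]
        for row in sel.itertuples():
            if truth.loc[row.gene_id]:
                tp += row.is_psg
                fn += not row.is_psg
            else:
                fp += row.is_psg
                tn += not row.is_psg
    return dict(
        recall=tp / (tp + fn) if tp + fn else float("nan"),
        fpr=fp / (fp + tn) if fp + tn else float("nan"),
        n_true=tp + fn,
        n_null=fp + tn,
    )


def null_calibration(
    n_replicates: int = 10_000, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Type-I rate of the binomial excess test under its own null."""
    rng = np.random.default_rng([seed, 7002])
    rejections = 0
    for _ in range(n_replicates):
        la = float(rng.uniform(50, 900))
        ls = la / float(rng.uniform(2.0, 4.0))
        n = int(rng.integers(1, 60))
        a = int(rng.binomial(n, la / (la + ls)))
        ratio = selection.adjusted_as_ratio(a, n - a, la, ls)
        p = selection.psg_null_probability(a, n - a, la, ls)
        rejections += (ratio > 1.0) and (p < alpha)
    rate = rejections / n_replicates
    return dict(
        rate=rate,
        alpha=alpha,
        se=float(np.sqrt(alpha * (1 - alpha) / n_replicates)),
        n_replicates=n_replicates,
    )


def nb_recovery(
    n: int = 5000, b_len: float = 1.0, b_dep: float = 0.3,
    alpha_disp: float = 0.5, seed: int = 0,
) -> dict:
    """Coverage check: NB regression recovers generative coefficients."""
    rng = np.random.default_rng([seed, 7003])
    lengths = rng.uniform(300, 2500, n)
    depths = rng.uniform(10, 120, n)
    species = rng.integers(0, 3, n)
    offsets = np.array([0.0, 0.2, 0.4])
    mu = np.exp(
        -6.0 + b_len * np.log(lengths) + b_dep * np.log(depths) + offsets[species]
    )
    lam = rng.gamma(1.0 / alpha_disp, alpha_disp * mu)
    table = pd.DataFrame({
        "transcript_id": [f"t{i}" for i in range(n)],
        "species": [f"sp{s + 1}" for s in species],
        "snp_count": rng.poisson(lam),
        "coding_length": lengths,
        "mean_depth": depths,
    })
    fit = diversity.fit_snp_abundance_model(table)
    return dict(
        length_coef=fit.log_length_coef,
        length_se=float(fit.bse["log_length"]),
        length_in_ci=abs(fit.log_length_coef - b_len) < 1.96 * fit.bse["log_length"],
        depth_coef=fit.log_depth_coef,
        depth_se=float(fit.bse["log_depth"]),
        depth_in_ci=abs(fit.log_depth_coef - b_dep) < 1.96 * fit.bse["log_depth"],
        alpha=fit.alpha,
        n=n,
    )


def fisher_oracle_discrepancy(max_margin: int = 50) -> dict:
    """Largest deviation between the Fisher tail and exact integer summation.

    Enumerates every 2x2 table with total at most ``max_margin`` and
    compares the implementation's hypergeometric tail with an exact
    cumulative-integer oracle.
    """
    from math import comb

    from scipy import stats

    worst = 0.0
    n_tables = 0
    for N in range(1, max_margin + 1):
        for K in range(N + 1):
            for ncol in range(N + 1):
                lo = max(0, K + ncol - N)
                hi = min(K, ncol)
                ks = np.arange(lo, hi + 1)
                impl = stats.hypergeom.sf(ks - 1, N, K, ncol)
                denom = comb(N, ncol)
                weights = [comb(K, j) * comb(N - K, ncol - j) for j in ks]
                # exact tail by integer suffix sums
                suffix = np.cumsum(weights[::-1])[::-1]
                oracle = suffix / denom
                worst = max(worst, float(np.max(np.abs(impl - oracle))))
                n_tables += len(ks)
    return dict(max_abs_error=worst, n_tables=n_tables, max_margin=max_margin)


def overlap_recovery(
    profile: tuple[float, float, float] = (0.65, 0.97, 0.91),
    n_species: int = 7,
    n_genes: int = 1000,
    seed: int = 0,
) -> dict:
    """Realized versus configured shared fractions of the annotation model."""
    from .convergence import overlap_analysis
    from .synthetic import generate_annotation_assignments

    cfg = SyntheticConfig(
        n_species=n_species, n_transcripts_per_species=n_genes,
        convergence_profile=profile, seed=seed,
    )
    genes = {
        cfg.species_name(i): [f"{cfg.species_name(i)}_g{j}" for j in range(n_genes)]
        for i in range(n_species)
    }
    sets, _ = generate_annotation_assignments(cfg, genes)
    out = {}
    for level, target in zip(("orthogroup", "family", "process"), profile):
        ov = overlap_analysis(sets[level])
        out[level] = dict(target=target, realized=ov.shared_pct / 100.0)
    out["max_abs_error"] = max(
        abs(v["realized"] - v["target"]) for v in out.values() if isinstance(v, dict)
    )
    return out
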