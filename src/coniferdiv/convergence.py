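"""Cross-species molecular and functional convergence statistics.

Convergence is quantified at three hierarchy levels — orthogroups, protein
families and Gene Ontology biological processes — by asking how many
annotation elements are shared by two or more species versus restricted to
a single species, both for the complete gene sets and for the positively
selected subsets.  Over-representation of individual terms among PSGs is
tested per species with one-sided Fisher exact tests (hypergeometric tail),
and homology tables against outgroup gene sets are reduced to one-to-one
best-match pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

LEVELS = ("orthogroup", "family", "process")


@dataclass
class AnnotationSets:
    """Per-species element-id sets at one hierarchy level."""

    level: str
    sets: dict[str, set[str]]

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


@dataclass
class OverlapResult:
    level: str
    intersection_counts: dict[frozenset, int]
    shared_count: int            # present in >= 2 species
    species_specific_count: int  # present in exactly 1 species
    in_all_count: int            # present in every species
    shared_pct: float
    species_specific_pct: float
    universe_size: int


def overlap_analysis(sets: AnnotationSets) -> OverlapResult:
    """Intersection structure of per-species element sets.

    Every universe element falls in exactly one species-subset cell (the
    set of species that carry it); "shared" means carried by two or more
    species, per the convention used for orthogroup overlap summaries.
    """
    if len(sets.sets) < 2:
        raise ValueError("need at least two species")
    universe = sets.universe
    if not universe:
        raise ValueError("empty universe")
    membership: dict[str, set[str]] = {e: set() for e in universe}
    for sp, elements in sets.sets.items():
        for e in elements:
            membership[e].add(sp)
    cells: dict[frozenset, int] = {}
    for e, sps in membership.items():
        cells[frozenset(sps)] = cells.get(frozenset(sps), 0) + 1
    shared = sum(c for k, c in cells.items() if len(k) >= 2)
    specific = sum(c for k, c in cells.items() if len(k) == 1)
    n_all = cells.get(frozenset(sets.sets.keys()), 0)
    n = len(universe)
    return OverlapResult(
        level=sets.level,
        intersection_counts=cells,
        shared_count=shared,
        species_specific_count=specific,
        in_all_count=n_all,
        shared_pct=100.0 * shared / n,
        species_specific_pct=100.0 * specific / n,
        universe_size=n,
    )


def annotation_sets_from_table(
    table: pd.DataFrame, level: str, column: str, gene_ids: Mapping[str, set[str]] | None = None
) -> AnnotationSets:
    """Build per-species element sets from a gene->annotation table.

    ``table`` needs columns (gene_id, species, ``column``); empty/NaN cells
    are ignored (genes lacking annotation at a level do not enter that
    level's universe).  ``gene_ids`` optionally restricts each species to a
    gene subset (e.g. its PSGs).
    """
    sets: dict[str, set[str]] = {}
    sub = table.dropna(subset=[column])
    sub = sub[sub[column] != ""]
    for sp, grp in sub.groupby("species"):
        if gene_ids is not None:
            grp = grp[grp["gene_id"].isin(gene_ids.get(str(sp), set()))]
        sets[str(sp)] = set(grp[column].astype(str))
    return AnnotationSets(level=level, sets=sets)


def fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher exact probability.

    2x2 table [[a, b], [c, d]]: a = PSG genes carrying the term, b = PSG
    genes without it, c/d likewise for the non-PSG background.  Equals the
    hypergeometric tail P(X >= a) with X ~ Hypergeom(N=a+b+c+d, K=a+c,
    n=a+b).
    """
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def enrichment_test(
    psg_genes: Mapping[str, Iterable[str]],
    annotations: pd.DataFrame,
    term_column: str = "process_id",
    threshold: float = 0.005,
) -> pd.DataFrame:
    """Per-term, per-species over-representation among PSGs.

    ``annotations`` is the background gene->term table with columns
    (gene_id, species, ``term_column``); the background of a species is the
    set of its annotated genes and PSGs must be a subset of it.  Returns a
    DataFrame with one row per (species, term): the 2x2 counts, the sample
    odds ratio, the one-sided Fisher probability and a significance mask at
    ``threshold``.
    """
    sub = annotations.dropna(subset=[term_column])
    sub = sub[sub[term_column] != ""]
    rows = []
    for sp, grp in sub.groupby("species"):
        sp = str(sp)
        gene_terms = grp.groupby("gene_id")[term_column].agg(set)
        background = set(gene_terms.index)
        psg = set(map(str, psg_genes.get(sp, [])))
        missing = psg - background
        if missing:
            raise ValueError(
                f"{sp}: {len(missing)} PSG genes absent from the annotated background"
            )
        n_psg = len(psg)
        n_bg = len(background)
        term_to_genes: dict[str, set[str]] = {}
        for g, terms in gene_terms.items():
            for t in terms:
                term_to_genes.setdefault(str(t), set()).add(str(g))
        for term, genes in sorted(term_to_genes.items()):
            a = len(genes & psg)
            k = len(genes)
            b = n_psg - a
            c = k - a
            d = n_bg - n_psg - c
            p = fisher_enrichment_p(a, b, c, d)
            odds = (a * d) / (b * c) if b * c > 0 else float("inf")
            rows.append(
                dict(species=sp, term=term, n_psg_with=a, n_psg_without=b,
                     n_bg_with=c, n_bg_without=d, odds_ratio=odds,
                     p_value=p, significant=p < threshold)
            )
    return pd.DataFrame(
        rows, columns=["species", "term", "n_psg_with", "n_psg_without",
                       "n_bg_with", "n_bg_without", "odds_ratio", "p_value",
                       "significant"],
    )


BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_table(path) -> pd.DataFrame:
    """Read a blast tabular (outfmt 6) similarity table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected 12 blast outfmt-6 columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = BLAST6_COLUMNS
    for col, line0 in (("evalue", 10), ("bitscore", 11)):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: malformed numeric field {col!r} at line {bad.index[0] + 1}"
            )
    return df


def best_match_pairing(
    table: pd.DataFrame, evalue_threshold: float = 1e-30
) -> pd.DataFrame:
    """Reduce a similarity table to one-to-one best-match pairs.

    Rows at or above the E-value threshold are dropped; remaining rows are
    greedily paired in order of increasing E-value (ties broken by higher
    bit-score, then lexicographic ids), so each query and each subject
    appears at most once and a query whose best subject is already claimed
    falls back to its next-best available subject.  Invariant to input row
    order.
    """
    df = table[table["evalue"] < evalue_threshold].copy()
    df = df.sort_values(
        by=["evalue", "bitscore", "qseqid", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    used_q: set[str] = set()
    used_s: set[str] = set()
    rows = []
    for row in df.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        if q in used_q or s in used_s:
            continue
        used_q.add(q)
        used_s.add(s)
        rows.append(dict(qseqid=q, sseqid=s, evalue=row.evalue, bitscore=row.bitscore))
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])
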