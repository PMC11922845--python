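"""Synthetic multi-species transcriptome datasets with known truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage of the pipeline can be exercised and validated
without any sequencing data:

* per species, transcripts with an internal ATG-initiated ORF, heterogeneous
  lengths and per-transcript read depths (with ramped ends so the
  depth-eligibility rule has work to do);
* per-transcript SNP totals drawn from a negative binomial around a
  rate x sites x depth-effect expectation, allocated binomially between
  nonsynonymous and synonymous substitution opportunities — with the
  nonsynonymous rate multiplied for a configurable fraction of true
  positively selected genes;
* paralogous false-positive SNPs injected into the embryo pool and into at
  least one haploid megagametophyte library each, so the paralog filter can
  be validated against ground truth;
* nested annotation labels (orthogroup -> protein family -> biological
  process) with configurable shared fractions per hierarchy level.

All randomness flows from ``SyntheticConfig.seed`` through per-species
substreams; a fixed seed yields byte-identical serialized output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codon import BASES, OrfInterval, codon_substitution_effects, count_sites
from .convergence import LEVELS, AnnotationSets
from .filtering import VariantRecord, write_vcf

log = logging.getLogger(__name__)

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in _STOPS
)

#: per-transcript mean SNP magnitudes the default rates emulate
_DEFAULT_MEANS = (6.0, 5.8, 5.3, 5.2, 5.3, 4.5, 4.5)
_DEFAULT_ORF_NT = 900.0  # expected coding length under the default config


class ConfigError(ValueError):
    """A synthetic configuration field is out of range."""


@dataclass
class SyntheticConfig:
    n_species: int = 7
    n_transcripts_per_species: int = 2000
    length_distribution: tuple[int, int] = (500, 2500)
    depth_distribution: tuple[float, float] = (40.0, 4.0)  # (mean, gamma shape)
    snp_rate_per_species: Optional[Sequence[float]] = None  # per coding site
    nb_dispersion: float = 1.2
    psg_fraction: float = 0.1
    psg_nonsyn_multiplier: float = 3.0
    paralog_snp_rate: float = 0.1
    n_megagametophytes: int = 4
    convergence_profile: tuple[float, float, float] = (0.65, 0.97, 0.91)
    seed: int = 0
    orf_fraction: float = 0.6
    depth_effect_exponent: float = 0.3
    depth_ramp: int = 100

    def __post_init__(self) -> None:
        if self.snp_rate_per_species is None:
            means = [
                _DEFAULT_MEANS[i % len(_DEFAULT_MEANS)] for i in range(self.n_species)
            ]
            self.snp_rate_per_species = tuple(m / _DEFAULT_ORF_NT for m in means)
        self.validate()

    def validate(self) -> None:
        def positive(name: str, value) -> None:
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value!r}")

        def proportion(name: str, value) -> None:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value!r}")

        positive("n_species", self.n_species)
        positive("n_transcripts_per_species", self.n_transcripts_per_species)
        lo, hi = self.length_distribution
        positive("length_distribution[0]", lo)
        if hi < lo:
            raise ConfigError("length_distribution must satisfy min <= max")
        positive("depth_distribution[0]", self.depth_distribution[0])
        positive("depth_distribution[1]", self.depth_distribution[1])
        if len(self.snp_rate_per_species) != self.n_species:
            raise ConfigError("snp_rate_per_species must have n_species entries")
        for i, r in enumerate(self.snp_rate_per_species):
            positive(f"snp_rate_per_species[{i}]", r)
        positive("nb_dispersion", self.nb_dispersion)
        proportion("psg_fraction", self.psg_fraction)
        if self.psg_nonsyn_multiplier < 1.0:
            raise ConfigError("psg_nonsyn_multiplier must be >= 1")
        proportion("paralog_snp_rate", self.paralog_snp_rate)
        if self.paralog_snp_rate >= 1.0:
            raise ConfigError("paralog_snp_rate must be < 1")
        if self.n_megagametophytes < 1:
            raise ConfigError("n_megagametophytes must be >= 1")
        if len(self.convergence_profile) != len(LEVELS):
            raise ConfigError("convergence_profile needs one entry per hierarchy level")
        for q in self.convergence_profile:
            proportion("convergence_profile", q)
        if not 0.1 <= self.orf_fraction <= 0.9:
            raise ConfigError("orf_fraction must be in [0.1, 0.9]")

    def species_name(self, index: int) -> str:
        return f"sp{index + 1}"


@dataclass
class TruthTable:
    """Ground truth injected by the generator."""

    genes: pd.DataFrame  # gene_id, true_psg
    true_paralog_snp_ids: set[tuple[str, int]]
    true_mean_snp_rate: float


@dataclass
class SpeciesDataset:
    species: str
    transcripts: dict[str, str]
    orfs: dict[str, OrfInterval]
    depth_table: pd.DataFrame
    embryo_variants: list[VariantRecord]
    megagametophyte_variants: list[list[VariantRecord]]
    truth: TruthTable


def _site_opportunities(seq: str, orf: OrfInterval) -> tuple[list, list]:
    """Substitution opportunities inside the ORF, split by effect.

    Returns (nonsyn, syn): lists of (position, alts, weight) where weight is
    the number of alternative bases with that effect (the terminal stop
    codon is excluded, mirroring the site counts).
    """
    cds = orf.coding_sequence(seq)
    nonsyn, syn = [], []
    for ci in range(len(cds) // 3):
        effects = codon_substitution_effects(cds[ci * 3: ci * 3 + 3])
        if effects is None:
            continue
        for within, (n_alts, s_alts) in enumerate(effects):
            pos = orf.start + ci * 3 + within  # forward-strand generator ORFs
            if n_alts:
                nonsyn.append((pos, n_alts, len(n_alts)))
            if s_alts:
                syn.append((pos, s_alts, len(s_alts)))
    return nonsyn, syn


def _sample_substitutions(rng, opportunities, count, taken: set[int]):
    """Draw ``count`` distinct-position substitutions, weighted by the number
    of alternative bases, avoiding already-used positions."""
    avail = [o for o in opportunities if o[0] not in taken]
    if count > len(avail):
        count = len(avail)
    if count == 0:
        return []
    weights = np.array([o[2] for o in avail], float)
    idx = rng.choice(len(avail), size=count, replace=False, p=weights / weights.sum())
    out = []
    for i in idx:
        pos, alts, _ = avail[i]
        alt = alts[rng.integers(len(alts))] if len(alts) > 1 else alts[0]
        out.append((pos, alt))
        taken.add(pos)
    return out


def generate_species_dataset(
    config: SyntheticConfig, species_index: int
) -> SpeciesDataset:
    """Generate one species' transcripts, variant sets and truth table."""
    if species_index >= config.n_species:
        raise ValueError("species_index out of range")
    rng = np.random.default_rng([int(config.seed), int(species_index)])
    sp = config.species_name(species_index)
    rate = float(config.snp_rate_per_species[species_index])
    depth_mean, depth_shape = config.depth_distribution
    k = config.nb_dispersion
    w = config.psg_nonsyn_multiplier

    n = config.n_transcripts_per_species
    n_psg = int(round(config.psg_fraction * n))
    psg_flags = np.zeros(n, bool)
    psg_flags[rng.choice(n, size=n_psg, replace=False)] = True

    transcripts: dict[str, str] = {}
    orfs: dict[str, OrfInterval] = {}
    depth_rows = []
    truth_rows = []
    embryo: list[VariantRecord] = []
    megas: list[list[VariantRecord]] = [[] for _ in range(config.n_megagametophytes)]
    paralog_ids: set[tuple[str, int]] = set()
    total_true = 0
    total_sites = 0.0

    lo, hi = config.length_distribution
    for gi in range(n):
        tid = f"{sp}_t{gi:05d}"
        L = int(rng.integers(lo, hi + 1))
        orf_nt = max(30, (int(config.orf_fraction * L) // 3) * 3)
        inner = max((orf_nt - 6) // 3, 8)
        orf_len = 6 + 3 * inner
        start = int(rng.integers(0, L - orf_len + 1))
        utr5 = "".join(rng.choice(list(BASES), size=start))
        if start >= 3:
            # in-frame stop just upstream, so no 5'UTR ATG extends the ORF
            utr5 = utr5[:-3] + "TAA"
        codons = rng.choice(len(_SENSE_CODONS), size=inner)
        cds = "ATG" + "".join(_SENSE_CODONS[c] for c in codons) + _STOPS[rng.integers(3)]
        utr3 = "".join(rng.choice(list(BASES), size=L - start - orf_len))
        seq = utr5 + cds + utr3
        orf = OrfInterval(tid, start, start + orf_len, "+", start % 3)
        transcripts[tid] = seq
        orfs[tid] = orf

        # depth profile: constant with linear ramps at both ends
        d = float(rng.gamma(depth_shape, depth_mean / depth_shape))
        r = min(config.depth_ramp, L // 4)
        mean_depth = d * (L - r) / L
        interior = L - 2 * r
        n_ge10 = interior * (d >= 10) + int(2 * r * max(0.0, 1.0 - 10.0 / d)) if d > 0 else 0
        depth_rows.append((tid, mean_depth, int(n_ge10)))

        sc = count_sites(orf.coding_sequence(seq))
        La, Ls = sc.La, sc.Ls
        deff = (d / depth_mean) ** config.depth_effect_exponent
        w_g = w if psg_flags[gi] else 1.0
        mu = rate * (w_g * La + Ls) * deff
        n_snps = int(rng.negative_binomial(k, k / (k + mu))) if mu > 0 else 0
        p_nonsyn = w_g * La / (w_g * La + Ls)
        A = int(rng.binomial(n_snps, p_nonsyn))
        taken: set[int] = set()
        nonsyn_opp, syn_opp = _site_opportunities(seq, orf)
        subs = [(pos, alt) for pos, alt in _sample_substitutions(rng, nonsyn_opp, A, taken)]
        subs += _sample_substitutions(rng, syn_opp, n_snps - A, taken)
        for pos, alt in subs:
            embryo.append(VariantRecord(tid, pos, seq[pos], alt, source="embryo"))
        total_true += len(subs)
        total_sites += La + Ls

        # paralogous false positives: seen in the embryo pool AND >= 1 mega
        p = config.paralog_snp_rate
        if p > 0:
            m = int(rng.poisson(mu * p / (1.0 - p)))
            placed = 0
            while placed < m:
                pos = int(rng.integers(0, L))
                if pos in taken:
                    continue
                taken.add(pos)
                ref = seq[pos]
                alt = BASES[(BASES.index(ref) + 1 + rng.integers(3)) % 4]
                embryo.append(VariantRecord(tid, pos, ref, alt, source="embryo"))
                n_m = 1 + int(rng.binomial(config.n_megagametophytes - 1, 0.3))
                for mi in rng.choice(config.n_megagametophytes, size=n_m, replace=False):
                    megas[mi].append(
                        VariantRecord(tid, pos, ref, alt, source=f"mega{mi + 1}")
                    )
                paralog_ids.add((tid, pos))
                placed += 1

        truth_rows.append((tid, bool(psg_flags[gi])))

    truth = TruthTable(
        genes=pd.DataFrame(truth_rows, columns=["gene_id", "true_psg"]),
        true_paralog_snp_ids=paralog_ids,
        true_mean_snp_rate=total_true / total_sites if total_sites else 0.0,
    )
    depth_table = pd.DataFrame(
        depth_rows, columns=["transcript_id", "mean_depth", "n_bases_depth_ge10"]
    )
    return SpeciesDataset(sp, transcripts, orfs, depth_table, embryo, megas, truth)


# ---------------------------------------------------------------------------
# annotation hierarchy


def generate_annotation_assignments(
    config: SyntheticConfig, gene_ids_per_species: Mapping[str, Sequence[str]]
) -> tuple[dict[str, AnnotationSets], pd.DataFrame]:
    """Assign genes to a nested orthogroup/family/process hierarchy.

    Shared elements are placed in every species and species-specific
    elements in exactly one, so the realized shared fraction at each level
    matches the configured ``convergence_profile`` up to rounding.  Nesting
    holds by construction: all genes of an orthogroup share one family, and
    every family maps to at least one process.

    Returns the per-level AnnotationSets and a tidy gene->annotation table
    (gene_id, species, orthogroup_id, family_id, process_id; a gene may
    occupy several rows when its family feeds several processes).
    """
    species = list(gene_ids_per_species)
    if not species or any(len(v) == 0 for v in gene_ids_per_species.values()):
        raise ValueError("every species needs a non-empty gene set")
    q_og, q_f, q_p = config.convergence_profile
    rng = np.random.default_rng([int(config.seed), 999_983])
    total_genes = sum(len(v) for v in gene_ids_per_species.values())
    S = len(species)

    n_og = max(S, total_genes // 8)
    n_shared_og = int(round(q_og * n_og))
    n_spec_og = n_og - n_shared_og
    og_species: list[list[str]] = [species[:] for _ in range(n_shared_og)]
    for j in range(n_spec_og):
        og_species.append([species[j % S]])
    og_ids = [f"OG{j:05d}" for j in range(n_og)]
    shared_og = list(range(n_shared_og))
    spec_og = list(range(n_shared_og, n_og))

    # families: partition of orthogroups
    n_f = max(2, n_og // 2)
    n_spec_f = min(int(round((1.0 - q_f) * n_f)), len(spec_og))
    n_shared_f = min(n_f - n_spec_f, len(shared_og))
    fam_members: list[list[int]] = []
    spec_by_species: dict[str, list[int]] = {s: [] for s in species}
    for j in spec_og:
        spec_by_species[og_species[j][0]].append(j)
    spec_fams: list[list[int]] = []
    cycle = [s for s in species if spec_by_species[s]]
    ci = 0
    for _ in range(n_spec_f):
        while not spec_by_species[cycle[ci % len(cycle)]]:
            ci += 1
        s = cycle[ci % len(cycle)]
        spec_fams.append([spec_by_species[s].pop()])
        ci += 1
    shared_fams: list[list[int]] = [[j] for j in shared_og[:n_shared_f]]
    leftovers = shared_og[n_shared_f:] + [j for s in species for j in spec_by_species[s]]
    for i, j in enumerate(leftovers):
        if shared_fams:
            shared_fams[i % len(shared_fams)].append(j)
        else:
            # no shared families (degenerate profile): keep specific ogs with
            # a same-species specific family
            s = og_species[j][0]
            home = next((f for f in spec_fams if og_species[f[0]][0] == s), None)
            (home.append(j) if home is not None else spec_fams.append([j]))
    fam_members = spec_fams + shared_fams
    fam_is_spec = [True] * len(spec_fams) + [False] * len(shared_fams)
    fam_ids = [f"FAM{j:05d}" for j in range(len(fam_members))]
    og_to_fam = {}
    for fi, members in enumerate(fam_members):
        for j in members:
            og_to_fam[j] = fi

    # processes: each maps to >= 1 family; every family reaches >= 1 process
    n_p = max(2, len(fam_members) // 2)
    spec_f_idx = [i for i, s in enumerate(fam_is_spec) if s]
    shared_f_idx = [i for i, s in enumerate(fam_is_spec) if not s]
    n_spec_p = int(round((1.0 - q_p) * n_p)) if spec_f_idx else 0
    n_shared_p = n_p - n_spec_p if shared_f_idx else 0
    proc_members: list[list[int]] = []
    for j in range(n_spec_p):
        proc_members.append([spec_f_idx[j % len(spec_f_idx)]])
    for j in range(n_shared_p):
        proc_members.append([shared_f_idx[j % len(shared_f_idx)]])
    # attach families not yet covered: a specific family joining a shared
    # process leaves the process shared, so coverage never shifts fractions
    covered = {f for members in proc_members for f in members}
    shared_p_idx = list(range(n_spec_p, n_spec_p + n_shared_p))
    for fi in range(len(fam_members)):
        if fi in covered:
            continue
        if shared_p_idx:
            proc_members[shared_p_idx[fi % len(shared_p_idx)]].append(fi)
        elif fam_is_spec[fi] and n_spec_p:
            # no shared processes exist; reuse a same-species specific process
            home = next(
                (pi for pi in range(n_spec_p)
                 if og_species[fam_members[proc_members[pi][0]][0]][0]
                 == og_species[fam_members[fi][0]][0]),
                None,
            )
            (proc_members[home].append(fi) if home is not None
             else proc_members.append([fi]))
        else:
            proc_members.append([fi])
    proc_ids = [f"BP{j:05d}" for j in range(len(proc_members))]
    fam_to_procs: dict[int, list[int]] = {}
    for pi, fams in enumerate(proc_members):
        for fi in fams:
            fam_to_procs.setdefault(fi, []).append(pi)

    # assign genes to orthogroups: cover each orthogroup once per member
    # species, then spread the rest
    rows = []
    for s in species:
        genes = list(gene_ids_per_species[s])
        ogs_s = [j for j in range(n_og) if s in og_species[j]]
        if len(genes) < len(ogs_s):
            log.warning(
                "%s: %d genes for %d orthogroups; realized sharing will drift",
                s, len(genes), len(ogs_s),
            )
        assignment = {}
        for i, g in enumerate(genes):
            j = ogs_s[i] if i < len(ogs_s) else ogs_s[int(rng.integers(len(ogs_s)))]
            assignment[g] = j
        # per family and species, cycle genes over the family's processes so
        # every (family, process) link is realized in every member species
        fam_genes: dict[int, list[str]] = {}
        for g, j in assignment.items():
            fam_genes.setdefault(og_to_fam[j], []).append(g)
        for g, j in assignment.items():
            fi = og_to_fam[j]
            procs = fam_to_procs[fi]
            glist = fam_genes[fi]
            base = procs[glist.index(g) % len(procs)]
            rows.append((g, s, og_ids[j], fam_ids[fi], proc_ids[base]))
        for fi, glist in fam_genes.items():
            # families with fewer genes than linked processes: reuse a gene
            # so every (family, process) link is realized for this species
            if len(glist) < len(fam_to_procs[fi]):
                for pi in fam_to_procs[fi][len(glist):]:
                    g = glist[0]
                    j = assignment[g]
                    rows.append((g, s, og_ids[j], fam_ids[og_to_fam[j]], proc_ids[pi]))

    table = pd.DataFrame(
        rows, columns=["gene_id", "species", "orthogroup_id", "family_id", "process_id"]
    ).drop_duplicates(ignore_index=True)

    from .convergence import annotation_sets_from_table

    level_sets = {
        "orthogroup": annotation_sets_from_table(table, "orthogroup", "orthogroup_id"),
        "family": annotation_sets_from_table(table, "family", "family_id"),
        "process": annotation_sets_from_table(table, "process", "process_id"),
    }
    return level_sets, table


# ---------------------------------------------------------------------------
# serialization


def write_species_dataset(ds: SpeciesDataset, outdir) -> None:
    """Serialize one species (FASTA + VCFs + depth and truth tables)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=tid, description="")
        for tid, seq in ds.transcripts.items()
    ]
    seqio_write(records, str(outdir / "transcripts.fasta"), "fasta")
    write_vcf(ds.embryo_variants, outdir / "embryo.vcf", source="embryo")
    for i, mset in enumerate(ds.megagametophyte_variants):
        write_vcf(mset, outdir / f"mega{i + 1}.vcf", source=f"mega{i + 1}")
    ds.depth_table.to_csv(outdir / "depth.tsv", sep="\t", index=False)
    truth = ds.truth.genes.copy()
    truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    with open(outdir / "truth_paralogs.tsv", "w") as fh:
        fh.write("transcript_id\tpos_1based\n")
        for tid, pos in sorted(ds.truth.true_paralog_snp_ids):
            fh.write(f"{tid}\t{pos + 1}\n")


def write_dataset(config: SyntheticConfig, outdir) -> Path:
    """Generate and serialize a full multi-species dataset directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_ids: dict[str, list[str]] = {}
    for i in range(config.n_species):
        ds = generate_species_dataset(config, i)
        write_species_dataset(ds, outdir / ds.species)
        gene_ids[ds.species] = list(ds.transcripts)
    _, table = generate_annotation_assignments(config, gene_ids)
    table.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=list)
    return outdir
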