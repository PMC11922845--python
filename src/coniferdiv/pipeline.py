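"""End-to-end orchestration: filtering -> codon/site -> selection ->
diversity -> convergence, with file I/O and a machine-readable run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import codon, convergence, diversity, filtering, selection
from .synthetic import SyntheticConfig, write_dataset

log = logging.getLogger(__name__)


@dataclass
class SpeciesInputs:
    species: str
    fasta: Path
    embryo_vcf: Path
    megagametophyte_vcfs: list[Path]


@dataclass
class PipelineConfig:
    species_inputs: list[SpeciesInputs]
    depth_tables: dict[str, Path]
    annotation_table: Optional[Path] = None
    output_dir: Path = Path("run")
    min_mean_depth: float = 10.0
    min_bases_depth_ge10: int = 300
    alpha: float = 0.05
    enrichment_threshold: float = 0.005
    evalue_threshold: float = 1e-30
    genetic_code: int = 1
    seed: int = 0

    def validate(self) -> None:
        missing = []
        for si in self.species_inputs:
            for p in [si.fasta, si.embryo_vcf, *si.megagametophyte_vcfs]:
                if not Path(p).exists():
                    missing.append(str(p))
        for p in self.depth_tables.values():
            if not Path(p).exists():
                missing.append(str(p))
        if self.annotation_table and not Path(self.annotation_table).exists():
            missing.append(str(self.annotation_table))
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")
        for name in ("min_mean_depth", "min_bases_depth_ge10", "alpha",
                     "enrichment_threshold", "evalue_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def config_for_dataset(dataset_dir, output_dir=None, **kwargs) -> PipelineConfig:
    """Build a PipelineConfig for a directory written by ``simulate``."""
    dataset_dir = Path(dataset_dir)
    species_dirs = sorted(
        d for d in dataset_dir.iterdir() if d.is_dir() and (d / "embryo.vcf").exists()
    )
    inputs, depths = [], {}
    for d in species_dirs:
        megas = sorted(d.glob("mega*.vcf"))
        inputs.append(SpeciesInputs(d.name, d / "transcripts.fasta", d / "embryo.vcf", megas))
        depths[d.name] = d / "depth.tsv"
    ann = dataset_dir / "annotations.tsv"
    return PipelineConfig(
        species_inputs=inputs,
        depth_tables=depths,
        annotation_table=ann if ann.exists() else None,
        output_dir=Path(output_dir) if output_dir else dataset_dir / "run",
        **kwargs,
    )


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_species(cfg: PipelineConfig, si: SpeciesInputs) -> dict:
    """Filtering, ORF/site counting and PSG calling for one species."""
    transcripts = _read_fasta(si.fasta)
    embryo = filtering.read_vcf(si.embryo_vcf, source="embryo")
    megas = [filtering.read_vcf(p) for p in si.megagametophyte_vcfs]
    kept = filtering.subtract_paralogous(embryo, megas)

    orf_tab = codon.orf_table(transcripts, table_id=cfg.genetic_code)
    depth = pd.read_csv(cfg.depth_tables[si.species], sep="\t")
    elig = filtering.eligible_transcripts(
        depth, orf_tab, cfg.min_mean_depth, cfg.min_bases_depth_ge10
    )
    kept_elig = filtering.restrict_to_eligible(kept, elig)

    orfs = {
        row.transcript_id: codon.OrfInterval(
            row.transcript_id, int(row.start), int(row.end), row.strand, int(row.frame)
        )
        for row in orf_tab.itertuples()
    }
    site_counts = orf_tab.set_index("transcript_id")[["La", "Ls"]]

    by_gene: dict[str, list[int]] = {}
    n_noncoding = 0
    for v in kept_elig:
        orf = orfs.get(v.transcript_id)
        if orf is None:
            continue
        eff = codon.classify_snp(
            orf, transcripts[v.transcript_id], v.position, v.ref, v.alt,
            table_id=cfg.genetic_code,
        )
        if eff is None:
            continue
        a, s = by_gene.setdefault(v.transcript_id, [0, 0])
        if eff.category == "nonsynonymous":
            by_gene[v.transcript_id][0] = a + 1
        elif eff.category == "synonymous":
            by_gene[v.transcript_id][1] = s + 1
        else:
            n_noncoding += 1

    eligible_ids = set(elig.loc[elig["eligible"], "transcript_id"])
    rows = []
    for tid in sorted(eligible_ids & set(site_counts.index)):
        a, s = by_gene.get(tid, (0, 0))
        rows.append(dict(gene_id=tid, A=a, S=s,
                         La=float(site_counts.loc[tid, "La"]),
                         Ls=float(site_counts.loc[tid, "Ls"])))
    sel = selection.gene_selection_table(pd.DataFrame(rows), alpha=cfg.alpha)

    coding = {v for v in kept_elig
              if (orf := orfs.get(v.transcript_id)) and orf.start <= v.position < orf.end}
    per_transcript = []
    orf_info = orf_tab.set_index("transcript_id")
    depth_idx = depth.set_index("transcript_id")
    snp_per_tid: dict[str, int] = {}
    for v in coding:
        snp_per_tid[v.transcript_id] = snp_per_tid.get(v.transcript_id, 0) + 1
    for tid in sorted(eligible_ids & set(orf_info.index)):
        per_transcript.append(dict(
            transcript_id=tid, species=si.species,
            snp_count=snp_per_tid.get(tid, 0),
            coding_length=int(orf_info.loc[tid, "end"] - orf_info.loc[tid, "start"]),
            mean_depth=float(depth_idx.loc[tid, "mean_depth"]),
        ))

    return dict(
        species=si.species,
        counts=dict(
            raw=len(embryo), post_paralog=len(kept), post_eligibility=len(kept_elig),
            coding=len(coding), noncoding_dropped=n_noncoding,
        ),
        orf_table=orf_tab,
        selection_table=sel,
        per_transcript=pd.DataFrame(per_transcript),
        psg_summary=selection.summarize_psgs(sel, si.species),
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage over all species and write tables under output_dir.

    Returns the run report (also written as ``run_report.json``).
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = dict(
        parameters=dict(
            min_mean_depth=cfg.min_mean_depth,
            min_bases_depth_ge10=cfg.min_bases_depth_ge10,
            alpha=cfg.alpha,
            enrichment_threshold=cfg.enrichment_threshold,
            genetic_code=cfg.genetic_code,
            seed=cfg.seed,
        ),
        stages=[],
    )
    t0 = time.time()

    species_results = [run_species(cfg, si) for si in cfg.species_inputs]
    per_transcript = pd.concat(
        [r["per_transcript"] for r in species_results], ignore_index=True
    )
    sel_all = pd.concat(
        [r["selection_table"].assign(species=r["species"]) for r in species_results],
        ignore_index=True,
    )
    for r in species_results:
        report["stages"].append(dict(stage=f"filter[{r['species']}]", **r["counts"]))
        r["orf_table"].to_csv(out / f"orfs_{r['species']}.tsv", sep="\t", index=False)
    sel_all.to_csv(out / "selection.tsv", sep="\t", index=False)

    # diversity: NB adjustment, heterogeneity, grouping, summary
    fit = diversity.fit_snp_abundance_model(per_transcript)
    per_transcript["adjusted_count"] = diversity.adjust_counts(fit, per_transcript)
    per_transcript.to_csv(out / "per_transcript.tsv", sep="\t", index=False)
    dists = {
        sp: grp["adjusted_count"].to_numpy()
        for sp, grp in per_transcript.groupby("species")
    }
    h, p_kw = diversity.species_heterogeneity_test(dists)
    grouping = diversity.group_species(dists, alpha=cfg.alpha)
    summaries = diversity.summarize_species(per_transcript)
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        out / "species_summary.tsv", sep="\t", index=False
    )
    grouping.ks_pvalues.to_csv(out / "ks_pvalues.tsv", sep="\t")
    grouping.cvm_pvalues.to_csv(out / "cvm_pvalues.tsv", sep="\t")
    report["stages"].append(dict(
        stage="diversity", kruskal_H=h, kruskal_p=p_kw,
        groups=[list(g) for g in grouping.groups],
        nb_alpha=fit.alpha,
    ))

    # selection summary + PSG-vs-diversity regression
    psg_rows = [dataclasses.asdict(r["psg_summary"]) for r in species_results]
    pd.DataFrame(psg_rows).to_csv(out / "psg_summary.tsv", sep="\t", index=False)
    if len(species_results) >= 3:
        props = [r["psg_summary"].psg_proportion for r in species_results]
        totals = [
            float(per_transcript.loc[per_transcript["species"] == r["species"],
                                     "adjusted_count"].sum())
            for r in species_results
        ]
        try:
            slope, intercept, r2, p = selection.psg_diversity_regression(props, totals)
            report["stages"].append(dict(
                stage="psg_regression", slope=slope, intercept=intercept, r2=r2, p=p
            ))
        except ValueError as exc:
            log.warning("PSG regression skipped: %s", exc)

    # convergence over annotation levels, all genes vs PSGs
    if cfg.annotation_table is not None:
        ann = pd.read_csv(cfg.annotation_table, sep="\t")
        psg_genes = {
            r["species"]: set(
                r["selection_table"].loc[r["selection_table"]["is_psg"], "gene_id"]
            )
            for r in species_results
        }
        conv_rows = []
        for level, column in (("orthogroup", "orthogroup_id"),
                              ("family", "family_id"), ("process", "process_id")):
            for label, subset in (("all", None), ("psg", psg_genes)):
                sets = convergence.annotation_sets_from_table(ann, level, column, subset)
                if sum(len(s) for s in sets.sets.values()) == 0:
                    continue
                ov = convergence.overlap_analysis(sets)
                conv_rows.append(dict(
                    level=level, gene_set=label, universe=ov.universe_size,
                    shared_pct=round(ov.shared_pct, 1),
                    species_specific_pct=round(ov.species_specific_pct, 1),
                    in_all=ov.in_all_count,
                ))
        pd.DataFrame(conv_rows).to_csv(out / "convergence.tsv", sep="\t", index=False)
        enr = convergence.enrichment_test(
            psg_genes, ann, threshold=cfg.enrichment_threshold
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["stages"].append(dict(stage="convergence", levels=len(conv_rows)))

    report["wall_seconds"] = round(time.time() - t0, 3)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def simulate(config: SyntheticConfig, outdir) -> Path:
    """Write a complete pipeline-ready synthetic dataset plus truth tables."""
    return write_dataset(config, outdir)
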