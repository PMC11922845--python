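"""Variant records, VCF I/O and the paralog / eligibility filters.

Conifer seeds carry a haploid maternal tissue (the megagametophyte), so a
"heterozygous" SNP called inside a megagametophyte library cannot be a real
segregating site — it marks divergence between collapsed paralogous gene
copies.  Any SNP called both in the diploid embryo pool and in at least one
megagametophyte is therefore discarded as a paralogous false positive.

Downstream per-transcript statistics are further restricted to transcripts
with a mean coverage of at least 10 reads, at least 300 nucleotides at depth
10 or more, and a predicted coding sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic SNP on a transcript (0-based ``position``)."""

    transcript_id: str
    position: int
    ref: str
    alt: str
    source: str = "embryo"  # 'embryo' or 'mega<k>'
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.position)


@dataclass
class TranscriptEligibility:
    transcript_id: str
    mean_depth: float
    n_bases_depth_ge10: int
    has_cds: bool
    eligible: bool


def write_vcf(records: Iterable[VariantRecord], path, source: str | None = None) -> None:
    """Write SNPs as minimal VCF v4.2 (1-based POS, INFO key SRC)."""
    path = Path(path)
    records = sorted(records, key=lambda r: (r.transcript_id, r.position))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SRC,Number=1,Type=String,'
                 'Description="Source library (embryo pool or megagametophyte)">\n')
        for tid in sorted({r.transcript_id for r in records}):
            fh.write(f"##contig=<ID={tid}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            src = source if source is not None else r.source
            filt = "PASS" if r.qc_pass else "FAIL"
            fh.write(
                f"{r.transcript_id}\t{r.position + 1}\t.\t{r.ref}\t{r.alt}\t.\t{filt}\tSRC={src}\n"
            )


def read_vcf(path, source: str | None = None, drop_filtered: bool = True) -> list[VariantRecord]:
    """Read SNP records from a VCF; only PASS/'.' records are retained.

    Multi-allelic records are split; non-SNP alleles are skipped with a
    warning.  The SRC INFO key is used as the record source when present.
    """
    from cyvcf2 import VCF

    out: list[VariantRecord] = []
    for v in VCF(str(path)):
        qc = v.FILTER is None or v.FILTER == "PASS"
        if drop_filtered and not qc:
            continue
        src = v.INFO.get("SRC") or source or "embryo"
        for alt in v.ALT:
            if len(v.REF) != 1 or len(alt) != 1 or alt not in "ACGT":
                log.warning("skipping non-SNP record %s:%d", v.CHROM, v.POS)
                continue
            out.append(
                VariantRecord(v.CHROM, v.POS - 1, v.REF, alt, source=str(src), qc_pass=qc)
            )
    return out


def subtract_paralogous(
    embryo_variants: Sequence[VariantRecord],
    megagametophyte_sets: Sequence[Sequence[VariantRecord]],
) -> list[VariantRecord]:
    """Remove embryo-pool SNPs observed in any megagametophyte library.

    Matching is by (transcript, position) only — any allele observed in the
    haploid tissue disqualifies the site.  Idempotent; output is a subset of
    the input.
    """
    mega_keys: set[tuple[str, int]] = set()
    for mset in megagametophyte_sets:
        mega_keys.update(r.key for r in mset)
    return [r for r in embryo_variants if r.key not in mega_keys]


def eligible_transcripts(
    depth_table: pd.DataFrame,
    orf_table: pd.DataFrame,
    min_mean_depth: float = 10.0,
    min_bases: int = 300,
) -> pd.DataFrame:
    """Apply the transcript eligibility rule.

    ``depth_table`` needs columns (transcript_id, mean_depth,
    n_bases_depth_ge10); a transcript has a CDS when it appears in
    ``orf_table``.  Returns the depth table with has_cds and eligible flags.
    """
    out = depth_table.copy()
    with_cds = set(orf_table["transcript_id"])
    out["has_cds"] = out["transcript_id"].isin(with_cds)
    out["eligible"] = (
        (out["mean_depth"] >= min_mean_depth)
        & (out["n_bases_depth_ge10"] >= min_bases)
        & out["has_cds"]
    )
    return out


def restrict_to_eligible(
    variants: Sequence[VariantRecord], eligibility: pd.DataFrame
) -> list[VariantRecord]:
    """Keep variants on eligible transcripts.

    Raises when a variant's transcript is missing from the depth table.
    """
    known = set(eligibility["transcript_id"])
    missing = sorted({v.transcript_id for v in variants} - known)
    if missing:
        raise ValueError(
            f"{len(missing)} transcripts present in variants but missing from "
            f"the depth table: {missing[:10]}"
        )
    ok = set(eligibility.loc[eligibility["eligible"], "transcript_id"])
    return [v for v in variants if v.transcript_id in ok]


def filter_stage_report(counts: Mapping[str, int]) -> pd.DataFrame:
    """Per-stage variant counts (raw -> post-paralog -> post-eligibility)."""
    return pd.DataFrame(
        [(k, v) for k, v in counts.items()], columns=["stage", "n_variants"]
    )
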