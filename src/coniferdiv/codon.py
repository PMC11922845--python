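"""ORF prediction, synonymous/nonsynonymous site counting and SNP effect
classification.

The per-gene A/S ratio rests on three sequence-level primitives implemented
here:

* :func:`find_longest_orf` — six-frame search for the longest ATG-initiated
  reading frame of a transcript (3'-truncated ORFs allowed, since assembled
  transcripts are frequently incomplete at their 3' end).
* :func:`count_sites` — Nei–Gojobori (equal-weight) fractional counts of
  nonsynonymous (``La``) and synonymous (``Ls``) sites over an in-frame
  coding sequence.  Every codon position contributes ``s/3`` synonymous
  sites, where ``s`` is the number of the three possible substitutions at
  that position that preserve the amino acid; substitutions to or from a
  stop codon count as nonsynonymous.
* :func:`classify_snp` — assigns a SNP to the synonymous / nonsynonymous /
  noncoding category given the transcript's ORF.

Coordinates are 0-based half-open throughout; VCF conversion happens at I/O
boundaries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from Bio.Data import CodonTable
from Bio.Seq import Seq

log = logging.getLogger(__name__)

BASES = "ACGT"
MIN_ORF_NT = 30

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _code(table_id: int = 1) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


@lru_cache(maxsize=None)
def translate_codon(codon: str, table_id: int = 1) -> Optional[str]:
    """Amino acid for ``codon``, ``'*'`` for stop, None if it contains N."""
    if any(b not in BASES for b in codon):
        return None
    table = _code(table_id)
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str, table_id: int = 1) -> Optional[tuple[float, ...]]:
    """Per-position synonymous fractions (s/3) of a codon; None for stop or
    N-containing codons, which contribute no sites."""
    aa = translate_codon(codon, table_id)
    if aa is None or aa == "*":
        return None
    out = []
    for pos in range(3):
        syn = sum(
            1
            for b in BASES
            if b != codon[pos]
            and translate_codon(codon[:pos] + b + codon[pos + 1:], table_id) == aa
        )
        out.append(syn / 3.0)
    return tuple(out)


@lru_cache(maxsize=None)
def codon_substitution_effects(
    codon: str, table_id: int = 1
) -> Optional[tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]]:
    """Per-position (nonsynonymous_alts, synonymous_alts) partition of the
    three alternative bases; None for stop or N-containing codons."""
    aa = translate_codon(codon, table_id)
    if aa is None or aa == "*":
        return None
    out = []
    for pos in range(3):
        non, syn = [], []
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            (syn if translate_codon(mutant, table_id) == aa else non).append(b)
        out.append((tuple(non), tuple(syn)))
    return tuple(out)


@dataclass(frozen=True)
class OrfInterval:
    """Longest open reading frame of a transcript.

    ``start``/``end`` are 0-based half-open offsets on the forward strand of
    the transcript; for ``strand == '-'`` the coding sequence is the reverse
    complement of ``sequence[start:end]``.
    """

    transcript_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("invalid ORF interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    def coding_sequence(self, sequence: str) -> str:
        sub = sequence[self.start:self.end]
        return reverse_complement(sub) if self.strand == "-" else sub


@dataclass(frozen=True)
class SiteCounts:
    """Fractional nonsynonymous (La) and synonymous (Ls) site counts."""

    La: float
    Ls: float
    n_codons: int  # codons that actually contributed to the counts


@dataclass(frozen=True)
class SnpEffect:
    category: str  # 'synonymous' | 'nonsynonymous' | 'noncoding'
    codon_index: Optional[int]
    ref_codon: Optional[str]
    alt_codon: Optional[str]


class RefMismatchError(ValueError):
    """The VCF REF allele does not match the transcript base."""


def _scan_strand(seq: str, min_len: int, table_id: int) -> list[tuple[int, int, int]]:
    """All maximal ATG-initiated ORFs on one strand as (start, end, frame).

    ``end`` includes the stop codon when one is present; ORFs reaching the
    end of the sequence without a stop are truncated to a codon boundary.
    """
    n = len(seq)
    stops = set(_code(table_id).stop_codons)
    orfs: list[tuple[int, int, int]] = []
    for frame in range(3):
        i = frame
        open_start = None
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in stops:
                end = i + 3
                if end - open_start >= min_len:
                    orfs.append((open_start, end, frame))
                open_start = None
            i += 3
        if open_start is not None:  # 3'-truncated ORF
            end = open_start + ((n - open_start) // 3) * 3
            if end - open_start >= min_len:
                orfs.append((open_start, end, frame))
    return orfs


def find_longest_orf(
    sequence: str,
    transcript_id: str = "",
    min_len: int = MIN_ORF_NT,
    table_id: int = 1,
) -> Optional[OrfInterval]:
    """Longest ATG-initiated reading frame among all six frames.

    Ties are broken in favour of the forward strand, then the smallest start
    offset.  Returns None when no ORF of at least ``min_len`` nt exists.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    n = len(sequence)

    candidates: list[tuple[int, int, int, str, int]] = []
    for s, e, frame in _scan_strand(sequence, min_len, table_id):
        candidates.append((e - s, 0, s, "+", frame))
    rc = reverse_complement(sequence)
    for s, e, frame in _scan_strand(rc, min_len, table_id):
        # map back to forward-strand coordinates
        fwd_start, fwd_end = n - e, n - s
        candidates.append((e - s, 1, fwd_start, "-", frame))
    if not candidates:
        return None
    # longest first; forward strand preferred; then smallest start
    length, _, start, strand, frame = min(
        candidates, key=lambda c: (-c[0], c[1], c[2])
    )
    return OrfInterval(transcript_id, start, start + length, strand, frame)


def count_sites(orf_sequence: str, table_id: int = 1) -> SiteCounts:
    """Nei–Gojobori fractional site counts over an in-frame sequence.

    Codons containing N and stop codons contribute nothing; a terminal stop
    codon is therefore excluded by construction.  ``La + Ls`` equals three
    times the number of counted codons exactly.
    """
    orf_sequence = orf_sequence.upper()
    if len(orf_sequence) % 3 != 0:
        raise ValueError("ORF length not divisible by 3")
    Ls = 0.0
    counted = 0
    for i in range(0, len(orf_sequence), 3):
        fractions = codon_site_fractions(orf_sequence[i:i + 3], table_id)
        if fractions is None:
            continue
        counted += 1
        Ls += sum(fractions)
    return SiteCounts(La=3.0 * counted - Ls, Ls=Ls, n_codons=counted)


def classify_snp(
    orf: OrfInterval,
    sequence: str,
    position: int,
    ref: str,
    alt: str,
    table_id: int = 1,
) -> Optional[SnpEffect]:
    """Classify a SNP at a 0-based transcript offset.

    A substitution is synonymous iff the reference and alternate codons
    translate to the same amino acid; creating or destroying a stop codon is
    nonsynonymous.  Positions outside the ORF are noncoding.  Returns None
    (with a logged warning) when the affected codon contains an N, since no
    translation can be assigned.
    """
    sequence = sequence.upper()
    ref, alt = ref.upper(), alt.upper()
    if position < 0 or position >= len(sequence):
        raise ValueError(f"position {position} outside transcript")
    if sequence[position] != ref:
        raise RefMismatchError(
            f"{orf.transcript_id}:{position}: REF {ref!r} does not match "
            f"transcript base {sequence[position]!r}"
        )
    if not (orf.start <= position < orf.end):
        return SnpEffect("noncoding", None, None, None)

    if orf.strand == "+":
        offset = position - orf.start
        cds = sequence[orf.start:orf.end]
        ref_c, alt_c = ref, alt
    else:
        cds = reverse_complement(sequence[orf.start:orf.end])
        offset = orf.end - 1 - position
        ref_c = reverse_complement(ref)
        alt_c = reverse_complement(alt)
    codon_index = offset // 3
    within = offset % 3
    ref_codon = cds[codon_index * 3: codon_index * 3 + 3]
    if ref_codon[within] != ref_c:  # defensive; cannot happen
        raise RefMismatchError(f"{orf.transcript_id}:{position}: strand bookkeeping error")
    alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1:]
    aa_ref = translate_codon(ref_codon, table_id)
    aa_alt = translate_codon(alt_codon, table_id)
    if aa_ref is None or aa_alt is None:
        log.warning(
            "dropping SNP %s:%d in codon containing N", orf.transcript_id, position
        )
        return None
    category = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return SnpEffect(category, codon_index, ref_codon, alt_codon)


def orf_table(transcripts: dict[str, str], table_id: int = 1, min_len: int = MIN_ORF_NT):
    """Predict ORFs and site counts for a set of transcripts.

    Returns a pandas DataFrame with columns
    (transcript_id, start, end, strand, frame, La, Ls).
    """
    import pandas as pd

    rows = []
    for tid, seq in transcripts.items():
        orf = find_longest_orf(seq, tid, min_len=min_len, table_id=table_id)
        if orf is None:
            continue
        sc = count_sites(orf.coding_sequence(seq), table_id)
        rows.append(
            dict(transcript_id=tid, start=orf.start, end=orf.end,
                 strand=orf.strand, frame=orf.frame, La=sc.La, Ls=sc.Ls)
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "start", "end", "strand", "frame", "La", "Ls"]
    )
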