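"""Coordinate-aware core types: variants, transcript models, exon contexts.

All genomic coordinates are 1-based inclusive (the VCF convention). BED input
is converted from 0-based half-open at the reader boundary (:mod:`synsplice.io`).
Distances inside an exon are expressed in transcript orientation:
``dist_to_acceptor`` counts from the 5' (acceptor-side) exon boundary and
``dist_to_donor`` from the 3' (donor-side) boundary, both starting at 1, so
that ``dist_to_donor + dist_to_acceptor == exon_len + 1`` always holds.

A variant sitting on the last three exonic bases before the donor junction,
or on the first exonic base after the acceptor junction, is classified as a
splice-site-consensus variant (VSS); every other exonic variant is a variant
in internal exon (VIE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import (
    AmbiguousTranscript,
    FeatureNotApplicable,
    VariantNotExonic,
)

NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

VSS = "VSS"
VIE = "VIE"

LABELS = ("disease", "neutral", "unknown")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class Variant:
    """A synonymous single-nucleotide variant.

    ``pos`` is the 1-based genomic position; ``ref``/``alt`` are single
    nucleotides on the forward genomic strand; ``maf`` is the minor allele
    frequency in [0, 1] or ``None`` when unknown.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    maf: Optional[float] = None
    label: str = "unknown"
    variant_id: Optional[str] = None

    def __post_init__(self):
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"ref/alt must be single nucleotides in ACGT, got "
                f"{self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf {self.maf} outside [0, 1]")
        if self.label not in LABELS:
            raise ValueError(f"label {self.label!r} not in {LABELS}")

    @property
    def key(self) -> str:
        return self.variant_id or f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered list of exon intervals.

    ``exons`` are (start, end) 1-based inclusive genomic intervals stored in
    ascending genomic order; for minus-strand transcripts the transcript
    (5'->3') order is the reverse. Exons must be non-overlapping and the
    transcript must contain at least one exon.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple  # tuple[tuple[int, int], ...] genomic order
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError("transcript needs >= 1 exon")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = -1
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon interval ({start}, {end}) reversed")
            if start <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_transcript_order(self) -> list:
        """Exon intervals in 5'->3' transcript orientation."""
        return list(self.exons) if self.strand == "+" else list(self.exons[::-1])

    def exon_lengths_transcript_order(self) -> list:
        return [e - s + 1 for s, e in self.exons_transcript_order()]

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def intron_lengths_transcript_order(self) -> list:
        """Intron lengths between consecutive exons, transcript orientation."""
        ex = self.exons_transcript_order()
        out = []
        for a, b in zip(ex, ex[1:]):
            if self.strand == "+":
                out.append(b[0] - a[1] - 1)
            else:
                out.append(a[0] - b[1] - 1)
        return out

    def residue_range(self, exon_index: int) -> tuple:
        """1-based inclusive [first_aa, last_aa] coded by the exon.

        A residue belongs to the exon if at least one of its three coding
        nucleotides lies in the exon, so junction-spanning codons are
        assigned to both flanking exons.
        """
        lens = self.exon_lengths_transcript_order()
        c0 = sum(lens[:exon_index])  # coding nt before this exon
        c1 = c0 + lens[exon_index]  # coding nt through this exon
        first_aa = c0 // 3 + 1
        last_aa = (c1 - 1) // 3 + 1
        return (first_aa, last_aa)

    def protein_length(self) -> int:
        return self.cds_length() // 3


@dataclass(frozen=True)
class ExonContext:
    """A variant located within one exon of one transcript."""

    variant: Variant
    transcript: TranscriptModel
    exon_index: int  # 0-based, transcript orientation
    exon_len_nt: int
    dist_to_donor: int
    dist_to_acceptor: int
    upstream_intron_len: Optional[int]
    downstream_intron_len: Optional[int]
    residue_range: tuple
    site_class: str = field(init=False)
    is_first_exon: bool = field(init=False)
    is_last_exon: bool = field(init=False)

    def __post_init__(self):
        if self.dist_to_donor + self.dist_to_acceptor != self.exon_len_nt + 1:
            raise ValueError(
                "dist_to_donor + dist_to_acceptor must equal exon_len + 1"
            )
        object.__setattr__(self, "site_class", _site_class(self))
        object.__setattr__(self, "is_first_exon", self.exon_index == 0)
        object.__setattr__(
            self, "is_last_exon", self.exon_index == self.transcript.n_exons - 1
        )

    @property
    def exon_id(self) -> str:
        return f"{self.transcript.transcript_id}:exon{self.exon_index}"


def _site_class(ctx: ExonContext) -> str:
    return VSS if (ctx.dist_to_donor <= 3 or ctx.dist_to_acceptor <= 1) else VIE


def map_variant_to_exon(
    v: Variant,
    transcripts,
    transcript_id: Optional[str] = None,
) -> ExonContext:
    """Locate a variant inside a transcript's exon and derive distances.

    ``transcripts`` may be a single :class:`TranscriptModel` or a sequence of
    them; if the variant is exonic in more than one supplied transcript and
    no ``transcript_id`` is given, :class:`AmbiguousTranscript` is raised.
    """
    if isinstance(transcripts, TranscriptModel):
        candidates = [transcripts]
    else:
        candidates = list(transcripts)
    if transcript_id is not None:
        candidates = [t for t in candidates if t.transcript_id == transcript_id]

    hits = []
    for t in candidates:
        if t.chrom != v.chrom:
            continue
        for gi, (start, end) in enumerate(t.exons):
            if start <= v.pos <= end:
                hits.append((t, gi))
                break
    if not hits:
        raise VariantNotExonic(
            f"variant {v.key} is not exonic in the supplied transcript(s)"
        )
    if len(hits) > 1:
        ids = sorted(t.transcript_id for t, _ in hits)
        raise AmbiguousTranscript(
            f"variant {v.key} is exonic in multiple transcripts {ids}; "
            "pass transcript_id"
        )
    t, genomic_index = hits[0]
    start, end = t.exons[genomic_index]
    exon_len = end - start + 1
    if t.strand == "+":
        exon_index = genomic_index
        dist_to_acceptor = v.pos - start + 1
    else:
        exon_index = t.n_exons - 1 - genomic_index
        dist_to_acceptor = end - v.pos + 1
    dist_to_donor = exon_len - dist_to_acceptor + 1

    introns = t.intron_lengths_transcript_order()
    upstream = introns[exon_index - 1] if exon_index > 0 else None
    downstream = introns[exon_index] if exon_index < t.n_exons - 1 else None

    return ExonContext(
        variant=v,
        transcript=t,
        exon_index=exon_index,
        exon_len_nt=exon_len,
        dist_to_donor=dist_to_donor,
        dist_to_acceptor=dist_to_acceptor,
        upstream_intron_len=upstream,
        downstream_intron_len=downstream,
        residue_range=t.residue_range(exon_index),
    )


def classify_variant(ctx: ExonContext) -> str:
    """VSS iff within 3 nt of the donor or 1 nt of the acceptor (exonic side)."""
    return _site_class(ctx)


def proximity_feature(ctx: ExonContext) -> int:
    """Distance to the nearer splice junction; defined for VIE variants only."""
    if ctx.site_class == VSS:
        raise FeatureNotApplicable(
            "proximity is not used for splice-site-consensus (VSS) variants"
        )
    return min(ctx.dist_to_donor, ctx.dist_to_acceptor)


# --- codon-table validation filter (optional, off by default) -------------

_CODON_TABLE = {}


def _build_codon_table():
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        _CODON_TABLE[stop] = "*"


def is_synonymous(codon_ref: str, codon_alt: str) -> bool:
    """True when two codons encode the same residue (standard code)."""
    if not _CODON_TABLE:
        _build_codon_table()
    return _CODON_TABLE[codon_ref.upper()] == _CODON_TABLE[codon_alt.upper()]
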