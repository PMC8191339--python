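"""Genomic coordinate primitives: intervals, splice junctions/sites, transcript models.

All coordinates are 0-based half-open internally. File-format conversions
(GTF and STAR SJ.out.tab are 1-based inclusive, BED is native) happen at the
I/O boundary in :mod:`isokit.io`, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

STRANDS = ("+", "-", ".")

DONOR = "donor"
ACCEPTOR = "acceptor"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a chromosome.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", ignore_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if not ignore_strand and "." not in (self.strand, other.strand):
            if self.strand != other.strand:
                return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, order=True)
class SpliceSite:
    """One boundary of an intron, in transcript 5'->3' sense.

    On the plus strand the donor is the intron start (lower coordinate);
    on the minus strand the donor is the intron end (higher coordinate).
    """

    chrom: str
    strand: str
    position: int
    side: str  # DONOR or ACCEPTOR

    def __post_init__(self) -> None:
        if self.side not in (DONOR, ACCEPTOR):
            raise ValueError(f"invalid splice-site side {self.side!r}")


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron: [intron_start, intron_end) of purely intronic bases."""

    chrom: str
    strand: str
    intron_start: int
    intron_end: int

    def __post_init__(self) -> None:
        if not self.intron_start < self.intron_end:
            raise ValueError(
                f"invalid junction {self.chrom}:{self.intron_start}-{self.intron_end}"
            )

    def donor(self) -> SpliceSite:
        pos = self.intron_start if self.strand != "-" else self.intron_end
        return SpliceSite(self.chrom, self.strand, pos, DONOR)

    def acceptor(self) -> SpliceSite:
        pos = self.intron_end if self.strand != "-" else self.intron_start
        return SpliceSite(self.chrom, self.strand, pos, ACCEPTOR)

    def sites(self) -> tuple[SpliceSite, SpliceSite]:
        return (self.donor(), self.acceptor())

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass(frozen=True)
class CdsSegment:
    """One genomic segment of an annotated coding sequence with its GTF frame."""

    interval: GenomicInterval
    frame: int

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError(f"invalid CDS frame {self.frame}")


@dataclass
class TranscriptModel:
    """An exon chain on one chromosome/strand.

    Shared by annotated reference transcripts and observed isoform models.
    Exons are stored sorted by start; the splice-junction chain, the genomic
    span and the strand-aware 5'/3' ends are derived.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    gene_id: str | None = None
    cds: tuple[CdsSegment, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id}: strand must be + or -")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not exons:
            raise ValueError(f"transcript {self.id}: no exons")
        for e in exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.id}: exon on {e.chrom}, transcript on {self.chrom}"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.id}: exons overlap or touch at "
                    f"{a.start}-{a.end} / {b.start}-{b.end}"
                )
        object.__setattr__(self, "exons", exons)

    @cached_property
    def junction_chain(self) -> tuple[SpliceJunction, ...]:
        return tuple(
            SpliceJunction(self.chrom, self.strand, a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def chain_key(self) -> tuple[tuple[int, int], ...]:
        """Hashable junction-chain key (intron coordinate pairs, genomic order)."""
        return tuple((j.intron_start, j.intron_end) for j in self.junction_chain)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the transcript 5' end (TSS position)."""
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the transcript 3' end (polyA position)."""
        return self.span.end if self.strand == "+" else self.span.start

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def splice_sites(self) -> set[SpliceSite]:
        out: set[SpliceSite] = set()
        for j in self.junction_chain:
            out.update(j.sites())
        return out

    def exon_transcript_index(self, genomic_index: int) -> int:
        """Position of an exon in transcript (5'->3') order given its genomic index."""
        if not 0 <= genomic_index < self.n_exons:
            raise IndexError(genomic_index)
        if self.strand == "+":
            return genomic_index
        return self.n_exons - 1 - genomic_index
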