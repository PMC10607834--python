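"""Coordinate data model: intervals, transcripts, genes and read 3' ends.

All internal coordinates are 0-based half-open; GTF/GFF3 I/O converts at the
boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional, Sequence, Tuple

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Overlap as a fraction of the LONGER interval (symmetric)."""
        ov = self.overlap_length(other)
        return ov / max(self.length, other.length)


@dataclass
class TranscriptModel:
    """An ordered exon chain on one chromosome and strand.

    Exons are sorted by genomic start and must not overlap. Introns are the
    gaps between consecutive exons.
    """

    transcript_id: str
    gene_id: Optional[str]
    exons: Tuple[GenomicInterval, ...]

    def __init__(
        self,
        transcript_id: str,
        gene_id: Optional[str],
        exons: Iterable[GenomicInterval],
    ) -> None:
        self.transcript_id = transcript_id
        self.gene_id = gene_id
        exons = tuple(sorted(exons, key=lambda e: e.start))
        if not exons:
            raise ValueError(f"transcript {transcript_id}: no exons")
        chrom, strand = exons[0].chrom, exons[0].strand
        for prev, cur in zip(exons, exons[1:]):
            if cur.chrom != chrom or cur.strand != strand:
                raise ValueError(
                    f"transcript {transcript_id}: exons span multiple "
                    "chromosomes or strands"
                )
            if cur.start < prev.end:
                raise ValueError(
                    f"transcript {transcript_id}: overlapping exons "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
                )
        self.exons = exons

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> Tuple[GenomicInterval, ...]:
        return extract_introns(self)

    def intron_chain(self) -> Tuple[Tuple[int, int], ...]:
        """(start, end) pairs of introns; identity defines a splice isoform."""
        return tuple((p.end, c.start) for p, c in zip(self.exons, self.exons[1:]))

    def three_prime_end(self) -> int:
        """0-based coordinate of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    def exons_5to3(self) -> Tuple[GenomicInterval, ...]:
        """Exons in transcription order."""
        return self.exons if self.strand == "+" else self.exons[::-1]


def extract_introns(t: TranscriptModel) -> Tuple[GenomicInterval, ...]:
    """Gaps between consecutive exons, in genomic order.

    A single-exon transcript yields the empty tuple.
    """
    return tuple(
        GenomicInterval(t.chrom, prev.end, cur.start, t.strand)
        for prev, cur in zip(t.exons, t.exons[1:])
    )


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing a chromosome and strand."""

    gene_id: str
    transcripts: list

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        chrom, strand = self.transcripts[0].chrom, self.transcripts[0].strand
        for t in self.transcripts[1:]:
            if t.chrom != chrom or t.strand != strand:
                raise ValueError(
                    f"gene {self.gene_id}: transcripts on different "
                    "chromosomes or strands"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.start for t in self.transcripts)
        end = max(t.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def three_prime_end(self) -> int:
        """Annotated 3'-most transcribed base over all transcripts."""
        if self.strand == "+":
            return max(t.end for t in self.transcripts) - 1
        return min(t.start for t in self.transcripts)

    def reference_transcript(self) -> TranscriptModel:
        """The transcript with the largest total exon length (ties: smallest id)."""
        return sorted(
            self.transcripts, key=lambda t: (-t.exonic_length, t.transcript_id)
        )[0]


@dataclass(frozen=True)
class CleavageRecord:
    """One read's 3'-most transcribed genomic base."""

    chrom: str
    position: int
    strand: str
    gene_id: Optional[str]
    sample_id: str
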