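"""Collapse of read alignments into distinct splice isoforms by intron chain."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from ..genome.model import GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class IntronChain:
    """Ordered intron coordinates; identity defines a splice isoform."""

    chrom: str
    strand: str
    introns: Tuple[Tuple[int, int], ...]

    @classmethod
    def from_transcript(cls, t: TranscriptModel) -> "IntronChain":
        return cls(t.chrom, t.strand, t.intron_chain())


def _representative(
    chain: IntronChain, reads: List[TranscriptModel], transcript_id: str, gene_id: Optional[str]
) -> TranscriptModel:
    """Exon chain fixed by the introns, termini = widest 5'/3' among reads."""
    start = min(r.start for r in reads)
    end = max(r.end for r in reads)
    boundaries = [start]
    for intron_start, intron_end in chain.introns:
        boundaries.extend((intron_start, intron_end))
    boundaries.append(end)
    exons = [
        GenomicInterval(chain.chrom, boundaries[i], boundaries[i + 1], chain.strand)
        for i in range(0, len(boundaries), 2)
    ]
    return TranscriptModel(transcript_id, gene_id, exons)


def collapse_by_intron_chain(
    reads: Iterable[TranscriptModel],
    id_prefix: str = "ISO",
) -> List[Tuple[TranscriptModel, int]]:
    """One isoform per distinct intron chain, with its read support count.

    Only intron-containing reads are accepted (mono-exonic reads are grouped
    separately by :func:`collapse_mono_exonic`). Representative exon ends are
    the furthest 5'/3' termini among the supporting reads. Output order is
    deterministic: by (chrom, strand, intron chain).
    """
    groups: Dict[IntronChain, List[TranscriptModel]] = {}
    for read in reads:
        chain = IntronChain.from_transcript(read)
        if not chain.introns:
            raise ValueError(
                f"mono-exonic read {read.transcript_id}: use collapse_mono_exonic"
            )
        groups.setdefault(chain, []).append(read)
    out: List[Tuple[TranscriptModel, int]] = []
    ordered = sorted(groups, key=lambda c: (c.chrom, c.strand, c.introns))
    for i, chain in enumerate(ordered, start=1):
        members = groups[chain]
        gene_ids = {r.gene_id for r in members if r.gene_id is not None}
        gene_id = sorted(gene_ids)[0] if gene_ids else None
        rep = _representative(chain, members, f"{id_prefix}.{i:06d}", gene_id)
        out.append((rep, len(members)))
    return out


def collapse_mono_exonic(
    reads: Iterable[TranscriptModel],
    min_reciprocal_overlap: float = 0.5,
    id_prefix: str = "MONO",
) -> List[Tuple[TranscriptModel, int]]:
    """Group mono-exonic reads by >= min reciprocal overlap with the growing
    cluster span; deterministic (reads processed by coordinate)."""
    singles = sorted(
        (r for r in reads),
        key=lambda r: (r.chrom, r.strand, r.start, r.end, r.transcript_id),
    )
    clusters: List[Dict] = []  # {"span": GenomicInterval, "n": int}
    for read in singles:
        if len(read.exons) != 1:
            raise ValueError(f"read {read.transcript_id} is not mono-exonic")
        span = read.span
        placed = False
        for cl in clusters:
            if (
                cl["span"].strand == span.strand
                and cl["span"].reciprocal_overlap(span) >= min_reciprocal_overlap
            ):
                cl["span"] = GenomicInterval(
                    span.chrom,
                    min(cl["span"].start, span.start),
                    max(cl["span"].end, span.end),
                    span.strand,
                )
                cl["n"] += 1
                placed = True
                break
        if not placed:
            clusters.append({"span": span, "n": 1})
    out = []
    for i, cl in enumerate(clusters, start=1):
        iv = cl["span"]
        out.append(
            (TranscriptModel(f"{id_prefix}.{i:06d}", None, [iv]), cl["n"])
        )
    return out
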