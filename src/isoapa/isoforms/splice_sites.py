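"""Splice-site nucleotide frequency matrices and consensus strings.

Donor windows cover (-donor_flank[0] .. +donor_flank[1]-1) around the first
intron base; acceptor windows cover (-acceptor_flank[0] .. +acceptor_flank[1]-1)
around the first exon base after the intron, all in transcription direction.
The default 6|5 and 5|6 windows place the exon|intron boundary inside the
consensus string.
"""
from __future__ import annotations

from typing import Iterable, List, Tuple

from ..genome.fasta import GenomeLike, fetch, reverse_complement
from ..genome.model import GenomicInterval
from ..motifs import PositionFrequencyMatrix, tally_matrix

# base order used for deterministic consensus tie-breaking
BASES = "ACGT"


def _window_sequence(
    genome: GenomeLike, chrom: str, strand: str, anchor: int, up: int, down: int
) -> str:
    """Bases at transcription offsets -up..down-1 relative to anchor (offset 0
    = the anchor base itself)."""
    if strand == "+":
        start, end = anchor - up, anchor + down
        return fetch(genome, chrom, start, end)
    start, end = anchor - down + 1, anchor + up + 1
    return reverse_complement(fetch(genome, chrom, start, end))


def donor_acceptor_anchors(intron: GenomicInterval) -> Tuple[int, int]:
    """(first intron base, first exon base after the intron), strand-aware."""
    if intron.strand == "+":
        return intron.start, intron.end
    return intron.end - 1, intron.start - 1


def splice_site_matrices(
    introns: Iterable[GenomicInterval],
    genome: GenomeLike,
    donor_flank: Tuple[int, int] = (6, 5),
    acceptor_flank: Tuple[int, int] = (5, 6),
) -> Tuple[PositionFrequencyMatrix, PositionFrequencyMatrix, str, str]:
    """Position-frequency matrices and consensus strings for donor/acceptor.

    Returns (donor_pfm, acceptor_pfm, donor_consensus, acceptor_consensus);
    the consensus strings carry a '|' at the exon/intron boundary.
    """
    introns = list(introns)
    if not introns:
        raise ValueError("empty intron set")
    donor_seqs: List[str] = []
    acceptor_seqs: List[str] = []
    for intron in introns:
        donor_anchor, acceptor_anchor = donor_acceptor_anchors(intron)
        donor_seqs.append(
            _window_sequence(
                genome, intron.chrom, intron.strand, donor_anchor, *donor_flank
            )
        )
        acceptor_seqs.append(
            _window_sequence(
                genome, intron.chrom, intron.strand, acceptor_anchor, *acceptor_flank
            )
        )
    donor_pfm = tally_matrix(donor_seqs, first_offset=-donor_flank[0])
    acceptor_pfm = tally_matrix(acceptor_seqs, first_offset=-acceptor_flank[0])
    donor_consensus = _consensus(donor_pfm, boundary_offset=0)
    acceptor_consensus = _consensus(acceptor_pfm, boundary_offset=0)
    return donor_pfm, acceptor_pfm, donor_consensus, acceptor_consensus


def _consensus(pfm: PositionFrequencyMatrix, boundary_offset: int) -> str:
    out = []
    for idx, offset in enumerate(pfm.offsets):
        if offset == boundary_offset:
            out.append("|")
        col = pfm.freqs[idx]
        best = max(range(4), key=lambda b: (col[b], -b))  # ties: A<C<G<T order
        out.append(BASES[best])
    return "".join(out)
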