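"""Genome sequence access: indexed FASTA (pyfaidx) or in-memory dicts.

Soft-masked bases are uppercased on read; N bases are permitted and
propagated unchanged.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

from .model import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

GenomeLike = Union[Mapping[str, str], "pyfaidx.Fasta"]  # noqa: F821


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def open_genome(path: Union[str, Path]) -> "pyfaidx.Fasta":  # noqa: F821
    import pyfaidx

    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def _chrom_length(genome: GenomeLike, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq)


def fetch(genome: GenomeLike, chrom: str, start: int, end: int) -> str:
    """Forward-strand subsequence [start, end), uppercase."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    length = _chrom_length(genome, chrom)
    if start < 0 or end > length or start >= end:
        raise ValueError(
            f"interval {chrom}:{start}-{end} out of bounds (length {length})"
        )
    piece = genome[chrom][start:end]
    seq = piece if isinstance(piece, str) else piece.seq
    return seq.upper()


def extract_sequence(genome: GenomeLike, iv: GenomicInterval) -> str:
    """Sequence of an interval in transcription orientation (revcomp on -)."""
    seq = fetch(genome, iv.chrom, iv.start, iv.end)
    return reverse_complement(seq) if iv.strand == "-" else seq


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
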