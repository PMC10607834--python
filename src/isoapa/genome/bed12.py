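"""BED12 reader/writer; blocks define the exon chains of aligned reads."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, List, Union

from .model import GenomicInterval, TranscriptModel


class Bed12ParseError(ValueError):
    def __init__(self, line_number: int, message: str) -> None:
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


def read_bed12(path: Union[str, Path]) -> Iterator[TranscriptModel]:
    """Yield one TranscriptModel per BED12 record (gene_id unset)."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise Bed12ParseError(lineno, f"expected 12 fields, got {len(fields)}")
            chrom, start_s, end_s, name, _, strand = fields[:6]
            try:
                start = int(start_s)
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise Bed12ParseError(lineno, str(exc)) from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise Bed12ParseError(lineno, "blockCount does not match block lists")
            if strand not in ("+", "-"):
                raise Bed12ParseError(lineno, f"invalid strand {strand!r}")
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            yield TranscriptModel(name, None, exons)


def write_bed12(reads: Iterable[TranscriptModel], path: Union[str, Path]) -> int:
    """Write read models as BED12; returns the number of records written."""
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            start, end = read.start, read.end
            sizes = ",".join(str(e.length) for e in read.exons)
            offsets = ",".join(str(e.start - start) for e in read.exons)
            fh.write(
                f"{read.chrom}\t{start}\t{end}\t{read.transcript_id}\t0\t"
                f"{read.strand}\t{start}\t{end}\t0\t{len(read.exons)}\t"
                f"{sizes}\t{offsets}\n"
            )
            n += 1
    return n
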