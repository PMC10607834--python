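"""GTF / GFF3 readers and a GTF writer for gene models.

Input coordinates (1-based closed) are converted to the internal 0-based
half-open convention at the boundary; the writer converts back, so
parse -> write -> parse is the identity on well-formed input.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, TextIO, Tuple, Union

from .model import GenomicInterval, GeneModel, TranscriptModel

log = logging.getLogger(__name__)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation line; carries the line number."""

    def __init__(self, line_number: int, message: str) -> None:
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


def _parse_gtf_attrs(field: str) -> Dict[str, str]:
    return {k: v for k, v in _GTF_ATTR.findall(field)}


def _parse_gff3_attrs(field: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for item in field.strip().strip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _open_lines(source: Union[str, Path, TextIO, Iterable[str]]) -> Iterable[str]:
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and "\t" not in source
    ):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, str):
        yield from source.splitlines()
    else:
        yield from source


def parse_annotation(
    source: Union[str, Path, TextIO, Iterable[str]]
) -> List[GeneModel]:
    """Parse GTF or GFF3 text into GeneModels (exon features only).

    The attribute syntax is sniffed per line (``key "value"`` vs ``key=value``).
    For GFF3, exons reference transcripts via ``Parent`` and transcripts
    reference genes via their own ``Parent``. Exons lacking a transcript
    attribute are skipped with a logged warning; structurally malformed lines
    raise :class:`AnnotationParseError` naming the line number.
    """
    # exon lists keyed by (transcript_id, gene_id or None)
    exons: Dict[str, List[GenomicInterval]] = {}
    tx_gene: Dict[str, Optional[str]] = {}
    tx_order: List[str] = []

    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise AnnotationParseError(lineno, f"expected >= 8 tab fields, got {len(fields)}")
        chrom, _, feature, start_s, end_s, _, strand = fields[:7]
        attr_field = fields[8] if len(fields) > 8 else ""
        is_gff3 = "=" in attr_field and '"' not in attr_field
        attrs = _parse_gff3_attrs(attr_field) if is_gff3 else _parse_gtf_attrs(attr_field)

        if feature in ("mRNA", "transcript"):
            tid = attrs.get("ID") or attrs.get("transcript_id")
            gid = attrs.get("Parent") or attrs.get("gene_id")
            if tid is not None:
                tx_gene.setdefault(tid, gid)
            continue
        if feature != "exon":
            continue

        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
        if strand not in ("+", "-"):
            raise AnnotationParseError(lineno, f"invalid strand {strand!r}")
        if start < 1 or end < start:
            raise AnnotationParseError(lineno, f"invalid 1-based coordinates {start}-{end}")

        tid = attrs.get("transcript_id") or attrs.get("Parent")
        if tid is None:
            log.warning("line %d: exon without transcript attribute skipped", lineno)
            continue
        gid = attrs.get("gene_id")
        if gid is not None:
            tx_gene.setdefault(tid, gid)
        else:
            tx_gene.setdefault(tid, None)
        if tid not in exons:
            exons[tid] = []
            tx_order.append(tid)
        exons[tid].append(GenomicInterval(chrom, start - 1, end, strand))

    genes: Dict[str, List[TranscriptModel]] = {}
    gene_order: List[str] = []
    for tid in tx_order:
        gid = tx_gene.get(tid) or tid  # orphan transcripts become their own locus
        t = TranscriptModel(tid, gid, exons[tid])
        if gid not in genes:
            genes[gid] = []
            gene_order.append(gid)
        genes[gid].append(t)
    return [GeneModel(gid, genes[gid]) for gid in gene_order]


def write_gtf(
    genes: Iterable[GeneModel],
    path: Union[str, Path],
    source: str = "isoapa",
    extra_transcript_attrs: Optional[Dict[str, Dict[str, str]]] = None,
) -> None:
    """Write gene models as GTF (transcript + exon lines, 1-based closed)."""
    extra_transcript_attrs = extra_transcript_attrs or {}
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                for k, v in extra_transcript_attrs.get(t.transcript_id, {}).items():
                    attrs += f' {k} "{v}";'
                fh.write(
                    f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )
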