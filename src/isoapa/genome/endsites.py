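"""Read 3'-terminus extraction and gene assignment."""
from __future__ import annotations

import logging
from bisect import bisect_right
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import CleavageRecord, GeneModel, TranscriptModel

log = logging.getLogger(__name__)

DEFAULT_DOWNSTREAM_SLACK = 1000


class GeneIndex:
    """Per (chrom, strand) interval lookup over gene spans with downstream slack.

    The slack extends the span only past the annotated 3' end, since cleavage
    can occur beyond annotated gene ends but not upstream of the 5' end.
    """

    def __init__(self, genes: Iterable[GeneModel], downstream_slack: int = DEFAULT_DOWNSTREAM_SLACK):
        self._by_key: Dict[Tuple[str, str], List[Tuple[int, int, GeneModel]]] = {}
        self._starts: Dict[Tuple[str, str], List[int]] = {}
        self._maxlen: Dict[Tuple[str, str], int] = {}
        for gene in genes:
            span = gene.span
            if gene.strand == "+":
                lo, hi = span.start, span.end + downstream_slack
            else:
                lo, hi = max(0, span.start - downstream_slack), span.end
            self._by_key.setdefault((gene.chrom, gene.strand), []).append((lo, hi, gene))
        for key, entries in self._by_key.items():
            entries.sort(key=lambda e: e[0])
            self._starts[key] = [e[0] for e in entries]
            self._maxlen[key] = max(e[1] - e[0] for e in entries)

    def candidates(self, chrom: str, strand: str, position: int) -> List[GeneModel]:
        key = (chrom, strand)
        if key not in self._by_key:
            return []
        entries = self._by_key[key]
        idx = bisect_right(self._starts[key], position)
        # scan left only while an interval could still reach the position
        cutoff = position - self._maxlen[key]
        out = []
        for lo, hi, gene in reversed(entries[:idx]):
            if lo < cutoff:
                break
            if position < hi:
                out.append(gene)
        return out


def assign_gene(
    index: GeneIndex, chrom: str, strand: str, position: int
) -> Optional[GeneModel]:
    """Containing gene; among several, the one with the closest annotated 3' end.

    An exact distance tie leaves the read unassigned.
    """
    hits = index.candidates(chrom, strand, position)
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0]
    ranked = sorted(hits, key=lambda g: abs(position - g.three_prime_end()))
    d0 = abs(position - ranked[0].three_prime_end())
    d1 = abs(position - ranked[1].three_prime_end())
    if d0 == d1:
        return None
    return ranked[0]


def read_end_sites(
    reads: Iterable[TranscriptModel],
    genes: Sequence[GeneModel],
    sample_id: str = "sample",
    downstream_slack: int = DEFAULT_DOWNSTREAM_SLACK,
    sample_from_name: bool = False,
) -> Tuple[List[CleavageRecord], int]:
    """One CleavageRecord per read; returns (records, n_unassigned).

    The 3' terminus is the read's last transcribed base: highest covered
    coordinate on +, lowest on -. With ``sample_from_name`` the sample id is
    the read-name prefix before the first ':'.
    """
    index = GeneIndex(genes, downstream_slack)
    records: List[CleavageRecord] = []
    n_unassigned = 0
    for read in reads:
        position = read.three_prime_end()
        gene = assign_gene(index, read.chrom, read.strand, position)
        if gene is None:
            n_unassigned += 1
        sid = sample_id
        if sample_from_name and ":" in read.transcript_id:
            sid = read.transcript_id.split(":", 1)[0]
        records.append(
            CleavageRecord(
                chrom=read.chrom,
                position=position,
                strand=read.strand,
                gene_id=gene.gene_id if gene is not None else None,
                sample_id=sid,
            )
        )
    if n_unassigned:
        log.info("read_end_sites: %d reads unassigned to any gene", n_unassigned)
    return records, n_unassigned
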