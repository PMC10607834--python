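"""Local alternative-splicing event classification (seven types).

Events are defined pairwise between isoforms of one gene, in the local-event
style of transcript-based AS catalogs:

RI  - an intron of one isoform lies inside a single exon of the other, and the
      flanking exon boundaries (outer start/end) are shared.
SE  - an internal exon of one isoform is absent from the other, which joins
      the two flanking exons with one intron (shared outer splice sites).
A5  - two introns share their transcriptional 3' (acceptor) boundary but
      differ at the 5' (donor) boundary; the variable-boundary exons overlap.
A3  - mirror image of A5 (shared donor, variable acceptor).
AF  - the two isoforms' first exons do not overlap and both splice into the
      same downstream acceptor.
AL  - the two isoforms' last exons do not overlap and both are reached from
      the same upstream donor.
MX  - two internal exons, one per isoform, mutually exclusive between shared
      outer splice sites.

Type naming is strand-aware: on the minus strand the genomically-right intron
boundary is the donor, so a variable right boundary is an A5 event there.

Inclusion-form conventions (deterministic): RI = intron-retained form; SE =
exon-included form; A5/A3 = shorter-intron form; AF/AL = form whose terminal
exon is transcriptionally more distal; MX = form whose middle exon is
transcriptionally proximal. Duplicate events from different isoform pairs are
merged by (gene, type, defining coordinates).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set, Tuple

from ..genome.model import GeneModel, TranscriptModel

EVENT_TYPES = ("RI", "SE", "A5", "A3", "AF", "AL", "MX")


@dataclass
class ASEvent:
    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    defining_coords: Tuple[int, ...]
    inclusion_isoforms: Set[str] = field(default_factory=set)
    exclusion_isoforms: Set[str] = field(default_factory=set)

    def validate(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_isoforms or not self.exclusion_isoforms:
            raise ValueError(f"event {self.event_id}: empty isoform set")
        if self.inclusion_isoforms & self.exclusion_isoforms:
            raise ValueError(
                f"event {self.event_id}: inclusion/exclusion sets overlap"
            )


# (event_type, coords, inclusion_tid, exclusion_tid)
_RawEvent = Tuple[str, Tuple[int, ...], str, str]


def _exon_pairs_overlap(e1: Tuple[int, int], e2: Tuple[int, int]) -> bool:
    return e1[0] < e2[1] and e2[0] < e1[1]


def _pair_events(t1: TranscriptModel, t2: TranscriptModel) -> Iterator[_RawEvent]:
    strand = t1.strand
    ex1 = [(e.start, e.end) for e in t1.exons]
    ex2 = [(e.start, e.end) for e in t2.exons]
    in1 = t1.intron_chain()
    in2 = t2.intron_chain()
    exset1, exset2 = set(ex1), set(ex2)

    # --- RI: intron of one inside a boundary-sharing exon of the other
    for (introns, other_exons, other_set, retained, spliced) in (
        (in1, ex2, exset2, t2, t1),
        (in2, ex1, exset1, t1, t2),
    ):
        spliced_exons = [(e.start, e.end) for e in spliced.exons]
        for i, (b, c) in enumerate(introns):
            a = spliced_exons[i][0]
            d = spliced_exons[i + 1][1]
            if (a, d) in other_set:
                yield (
                    "RI",
                    (a, b, c, d),
                    retained.transcript_id,
                    spliced.transcript_id,
                )

    # --- SE: internal exon of one skipped by a single intron of the other
    for (exons, introns, other_introns, included, skipped) in (
        (ex1, in1, set(in2), t1, t2),
        (ex2, in2, set(in1), t2, t1),
    ):
        for i in range(1, len(exons) - 1):
            b = introns[i - 1][0]
            e = introns[i][1]
            c, d = exons[i]
            if (b, e) in other_introns:
                yield (
                    "SE",
                    (b, c, d, e),
                    included.transcript_id,
                    skipped.transcript_id,
                )

    # --- A5 / A3: introns sharing one boundary, variable-side exons overlap
    end_exon1 = {e[1]: e for e in ex1}
    end_exon2 = {e[1]: e for e in ex2}
    start_exon1 = {e[0]: e for e in ex1}
    start_exon2 = {e[0]: e for e in ex2}
    for (b1, c1) in in1:
        for (b2, c2) in in2:
            if c1 == c2 and b1 != b2:
                # variable left (genomic) boundary
                if _exon_pairs_overlap(end_exon1[b1], end_exon2[b2]):
                    etype = "A5" if strand == "+" else "A3"
                    shorter = t1 if b1 > b2 else t2
                    longer = t2 if shorter is t1 else t1
                    yield (
                        etype,
                        (min(b1, b2), max(b1, b2), c1),
                        shorter.transcript_id,
                        longer.transcript_id,
                    )
            elif b1 == b2 and c1 != c2:
                # variable right (genomic) boundary
                if _exon_pairs_overlap(start_exon1[c1], start_exon2[c2]):
                    etype = "A3" if strand == "+" else "A5"
                    shorter = t1 if c1 < c2 else t2
                    longer = t2 if shorter is t1 else t1
                    yield (
                        etype,
                        (b1, min(c1, c2), max(c1, c2)),
                        shorter.transcript_id,
                        longer.transcript_id,
                    )

    # --- AF / AL: non-overlapping terminal exons, shared internal boundary
    if len(ex1) >= 2 and len(ex2) >= 2:
        if strand == "+":
            f1, f2 = ex1[0], ex2[0]
            if f1 != f2 and not _exon_pairs_overlap(f1, f2):
                if in1[0][1] == in2[0][1]:  # shared acceptor
                    distal = t1 if f1[0] < f2[0] else t2
                    proximal = t2 if distal is t1 else t1
                    coords = tuple(sorted([f1, f2])[0] + sorted([f1, f2])[1]) + (
                        in1[0][1],
                    )
                    yield ("AF", coords, distal.transcript_id, proximal.transcript_id)
            l1, l2 = ex1[-1], ex2[-1]
            if l1 != l2 and not _exon_pairs_overlap(l1, l2):
                if in1[-1][0] == in2[-1][0]:  # shared donor
                    distal = t1 if l1[1] > l2[1] else t2
                    proximal = t2 if distal is t1 else t1
                    coords = (in1[-1][0],) + tuple(
                        sorted([l1, l2])[0] + sorted([l1, l2])[1]
                    )
                    yield ("AL", coords, distal.transcript_id, proximal.transcript_id)
        else:
            # first exon is genomically last on the minus strand
            f1, f2 = ex1[-1], ex2[-1]
            if f1 != f2 and not _exon_pairs_overlap(f1, f2):
                if in1[-1][0] == in2[-1][0]:  # shared acceptor (genomic left of intron)
                    distal = t1 if f1[1] > f2[1] else t2
                    proximal = t2 if distal is t1 else t1
                    coords = (in1[-1][0],) + tuple(
                        sorted([f1, f2])[0] + sorted([f1, f2])[1]
                    )
                    yield ("AF", coords, distal.transcript_id, proximal.transcript_id)
            l1, l2 = ex1[0], ex2[0]
            if l1 != l2 and not _exon_pairs_overlap(l1, l2):
                if in1[0][1] == in2[0][1]:  # shared donor
                    distal = t1 if l1[0] < l2[0] else t2
                    proximal = t2 if distal is t1 else t1
                    coords = tuple(sorted([l1, l2])[0] + sorted([l1, l2])[1]) + (
                        in1[0][1],
                    )
                    yield ("AL", coords, distal.transcript_id, proximal.transcript_id)

    # --- MX: mutually exclusive internal exons with shared outer splice sites
    for i in range(len(in1) - 1):
        b, c1 = in1[i]
        d1, e = in1[i + 1]
        for j in range(len(in2) - 1):
            b2, c2 = in2[j]
            d2, e2 = in2[j + 1]
            if b2 != b or e2 != e:
                continue
            m1, m2 = (c1, d1), (c2, d2)
            if m1 == m2 or _exon_pairs_overlap(m1, m2):
                continue
            first, second = sorted([m1, m2])
            coords = (b,) + first + second + (e,)
            if strand == "+":
                proximal_form = t1 if m1 < m2 else t2
            else:
                proximal_form = t1 if m1 > m2 else t2
            other = t2 if proximal_form is t1 else t1
            yield ("MX", coords, proximal_form.transcript_id, other.transcript_id)


def classify_as_events(gene: GeneModel) -> List[ASEvent]:
    """All deduplicated local AS events among a gene's transcripts.

    A single-transcript gene yields an empty list.
    """
    events: Dict[Tuple[str, Tuple[int, ...]], ASEvent] = {}
    txs = gene.transcripts
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            for etype, coords, inc, exc in _pair_events(txs[i], txs[j]):
                key = (etype, coords)
                if key not in events:
                    coord_str = "-".join(str(c) for c in coords)
                    events[key] = ASEvent(
                        event_id=f"{gene.gene_id};{etype}:{gene.chrom}:{coord_str}:{gene.strand}",
                        event_type=etype,
                        gene_id=gene.gene_id,
                        chrom=gene.chrom,
                        strand=gene.strand,
                        defining_coords=coords,
                    )
                events[key].inclusion_isoforms.add(inc)
                events[key].exclusion_isoforms.add(exc)
    out = sorted(events.values(), key=lambda e: (e.event_type, e.defining_coords))
    for ev in out:
        ev.validate()
    return out


def write_ioe(events: List[ASEvent], transcripts_per_gene: Dict[str, List[str]], path) -> None:
    """Tab-separated event table (seqname, gene, event, inclusion, total)."""
    with open(path, "w") as fh:
        fh.write("seqname\tgene_id\tevent_id\talternative_transcripts\ttotal_transcripts\n")
        for ev in events:
            inc = ",".join(sorted(ev.inclusion_isoforms))
            total = ",".join(sorted(ev.inclusion_isoforms | ev.exclusion_isoforms))
            fh.write(f"{ev.chrom}\t{ev.gene_id}\t{ev.event_id}\t{inc}\t{total}\n")
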