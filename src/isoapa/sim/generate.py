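"""Toy genome + annotation generator with planted PAS and AS ground truth.

All introns are written with canonical GT..AG dinucleotides (strand-aware),
AATAAA hexamers are planted upstream of signal-bearing poly(A) sites, and
seven dedicated genes carry one canonical AS event each. Deterministic for a
given seed.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..genome.model import GeneModel, GenomicInterval, TranscriptModel
from .config import PlantedEvent, SimulationConfig, SimulationGroundTruth, TrueGene, TruePAS

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# (type, transcript exon templates, defining coords, transcript end offsets)
_AS_TEMPLATES: List[Tuple[str, List[List[Tuple[int, int]]], Tuple[int, ...]]] = [
    ("RI", [[(0, 100), (200, 300)], [(0, 300)]], (0, 100, 200, 300)),
    ("SE", [[(0, 100), (200, 250), (400, 500)], [(0, 100), (400, 500)]], (100, 200, 250, 400)),
    ("A5", [[(0, 100), (200, 300)], [(0, 150), (200, 300)]], (100, 150, 200)),
    ("A3", [[(0, 100), (200, 300)], [(0, 100), (250, 300)]], (100, 200, 250)),
    ("AF", [[(0, 100), (400, 500)], [(200, 300), (400, 500)]], (0, 100, 200, 300, 400)),
    ("AL", [[(0, 100), (200, 300)], [(0, 100), (400, 500)]], (100, 200, 300, 400, 500)),
    ("MX", [[(0, 100), (200, 300), (600, 700)], [(0, 100), (400, 500), (600, 700)]],
     (100, 200, 300, 400, 500, 600)),
]


def _stage_usages(
    config: SimulationConfig, n_pas: int, shifted: bool
) -> Dict[str, List[float]]:
    if n_pas == 1:
        return {stage: [1.0] for stage in config.stages}
    base = list(config.usage_two_site)  # (proximal, distal)
    flipped = base[::-1]
    out: Dict[str, List[float]] = {}
    cut = len(config.stages) // 2
    for i, stage in enumerate(config.stages):
        out[stage] = flipped if (shifted and i >= cut) else list(base)
    return out


def _build_regular_gene(
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_id: str,
    cursor: int,
) -> Tuple[GeneModel, TrueGene, List[Tuple[int, str]], int]:
    """Returns (gene model, truth, sequence edits, gene length)."""
    strand = "+" if rng.random() < 0.5 else "-"
    pas_counts = sorted(config.pas_per_gene)
    probs = [config.pas_per_gene[k] for k in pas_counts]
    n_pas = int(rng.choice(pas_counts, p=probs))
    intronic = n_pas >= 2 and rng.random() < config.intronic_fraction
    shifted = n_pas >= 2 and rng.random() < config.shift_fraction
    signal = rng.random() < config.signal_fraction

    n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
    if intronic:
        n_exons = max(n_exons, 3)
    # transcription-order structure
    exon_lengths = [
        int(rng.integers(config.exon_length_range[0], config.exon_length_range[1] + 1))
        for _ in range(n_exons)
    ]
    spacing_extra = int(rng.integers(0, 41))
    proximal_offset = config.min_pas_spacing + spacing_extra
    # terminal exon must host the distal PAS, its signal window and (for
    # exonic two-PAS genes) the proximal PAS with margin
    exon_lengths[-1] = proximal_offset + 40 + int(rng.integers(0, 61))
    intron_lengths = [
        int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1))
        for _ in range(n_exons - 1)
    ]
    host_intron_tx: Optional[int] = None
    if intronic:
        host_intron_tx = (n_exons - 1) // 2
        intron_lengths[host_intron_tx] = int(
            rng.integers(config.long_intron_length_range[0], config.long_intron_length_range[1] + 1)
        )
    gene_length = sum(exon_lengths) + sum(intron_lengths)

    # genomic exon intervals (transcription order == genomic order on +)
    ex_lens = exon_lengths if strand == "+" else exon_lengths[::-1]
    in_lens = intron_lengths if strand == "+" else intron_lengths[::-1]
    exons: List[GenomicInterval] = []
    pos = cursor
    for i, el in enumerate(ex_lens):
        exons.append(GenomicInterval(config.chrom_name, pos, pos + el, strand))
        pos += el
        if i < len(in_lens):
            pos += in_lens[i]
    transcript = TranscriptModel(f"{gene_id}.t1", gene_id, exons)
    gene = GeneModel(gene_id, [transcript])

    # PAS positions (genomic), ordered 5'->3' in transcription direction
    distal = transcript.three_prime_end()
    pas_positions: List[int] = []
    if n_pas >= 2:
        if intronic:
            introns = transcript.introns()
            idx = host_intron_tx if strand == "+" else len(introns) - 1 - host_intron_tx
            host = introns[idx]
            pas_positions.append(host.start + host.length // 2)
        else:
            pas_positions.append(
                distal - proximal_offset if strand == "+" else distal + proximal_offset
            )
    pas_positions.append(distal)
    if len(pas_positions) == 2 and abs(pas_positions[0] - pas_positions[1]) < config.min_pas_spacing:
        raise ValueError(f"gene {gene_id}: planted PAS closer than min spacing")

    usages = _stage_usages(config, n_pas, shifted)
    truth = TrueGene(
        gene_id=gene_id,
        chrom=config.chrom_name,
        strand=strand,
        transcript_ids=[transcript.transcript_id],
        pas=[
            TruePAS(
                position=p,
                usage_by_stage={s: u[i] for s, u in usages.items()},
                is_intronic=bool(intronic and i == 0 and n_pas >= 2),
                has_signal=signal,
            )
            for i, p in enumerate(pas_positions)
        ],
        shifted=shifted,
    )
    edits = _sequence_edits(config, transcript, truth)
    return gene, truth, edits, gene_length


def _sequence_edits(
    config: SimulationConfig, transcript: TranscriptModel, truth: TrueGene
) -> List[Tuple[int, str]]:
    """(genomic position, replacement string) edits: GT/AG introns + signals."""
    edits: List[Tuple[int, str]] = []
    for intron in transcript.introns():
        if intron.strand == "+":
            edits.append((intron.start, "GT"))
            edits.append((intron.end - 2, "AG"))
        else:
            edits.append((intron.start, "CT"))  # revcomp(AG)
            edits.append((intron.end - 2, "AC"))  # revcomp(GT)
    for pas in truth.pas:
        if not pas.has_signal:
            continue
        off = config.signal_offset
        if transcript.strand == "+":
            edits.append((pas.position + off, "AATAAA"))
        else:
            edits.append((pas.position - off - 5, "TTTATT"))  # revcomp(AATAAA)
    return edits


def _build_as_gene(
    config: SimulationConfig,
    event_type: str,
    templates: List[List[Tuple[int, int]]],
    coords: Tuple[int, ...],
    cursor: int,
    signal: bool,
) -> Tuple[GeneModel, TrueGene, PlantedEvent, List[Tuple[int, str]], int]:
    gene_id = f"GAS_{event_type}"
    strand = "+"
    transcripts = []
    for k, template in enumerate(templates, start=1):
        exons = [
            GenomicInterval(config.chrom_name, cursor + s, cursor + e, strand)
            for s, e in template
        ]
        transcripts.append(TranscriptModel(f"{gene_id}.t{k}", gene_id, exons))
    gene = GeneModel(gene_id, transcripts)
    gene_length = max(e for tpl in templates for _, e in tpl)
    # PAS truth: one per distinct transcript end, uniform usage
    ends = sorted({t.three_prime_end() for t in transcripts})
    usage = 1.0 / len(ends)
    truth = TrueGene(
        gene_id=gene_id,
        chrom=config.chrom_name,
        strand=strand,
        transcript_ids=[t.transcript_id for t in transcripts],
        pas=[
            TruePAS(
                position=p,
                usage_by_stage={s: usage for s in config.stages},
                has_signal=signal,
            )
            for p in ends
        ],
        is_as_gene=True,
    )
    event = PlantedEvent(gene_id, event_type, tuple(cursor + c for c in coords))
    edits: List[Tuple[int, str]] = []
    for t in transcripts:
        edits.extend(_sequence_edits(config, t, TrueGene(
            gene_id, config.chrom_name, strand, [], [], False, True
        )))
    if signal:
        for pas in truth.pas:
            edits.append((pas.position + config.signal_offset, "AATAAA"))
    return gene, truth, event, edits, gene_length


def generate_genome_and_annotation(
    config: SimulationConfig, seed: int
) -> Tuple[Dict[str, str], List[GeneModel], SimulationGroundTruth]:
    """Random-base genome, gene models and planted ground truth.

    Byte-identical output for identical (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    genes: List[GeneModel] = []
    truth_genes: Dict[str, TrueGene] = {}
    events: List[PlantedEvent] = []
    all_edits: List[Tuple[int, str]] = []
    cursor = config.chrom_pad
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:04d}"
        gene, truth, edits, length = _build_regular_gene(config, rng, gene_id, cursor)
        genes.append(gene)
        truth_genes[gene_id] = truth
        all_edits.extend(edits)
        cursor += length + int(rng.integers(config.gene_gap_range[0], config.gene_gap_range[1] + 1))
    if config.plant_as_genes:
        for event_type, templates, coords in _AS_TEMPLATES:
            gene, truth, event, edits, length = _build_as_gene(
                config, event_type, templates, coords, cursor,
                signal=rng.random() < config.signal_fraction,
            )
            genes.append(gene)
            truth_genes[gene.gene_id] = truth
            events.append(event)
            all_edits.extend(edits)
            cursor += length + int(
                rng.integers(config.gene_gap_range[0], config.gene_gap_range[1] + 1)
            )
    chrom_length = cursor + config.chrom_pad
    seq = _BASES[rng.integers(0, 4, size=chrom_length)]
    for pos, replacement in all_edits:
        if pos < 0 or pos + len(replacement) > chrom_length:
            raise ValueError("sequence edit out of chromosome bounds")
        for j, ch in enumerate(replacement):
            seq[pos + j] = ch.encode()
    genome = {config.chrom_name: seq.tobytes().decode()}
    return genome, genes, SimulationGroundTruth(truth_genes, events)
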