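"""FLNC read simulation: isoform choice, PAS choice, 3' jitter, 5' truncation."""
from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ..genome.model import CleavageRecord, GeneModel, GenomicInterval, TranscriptModel
from .config import SimulationConfig, SimulationGroundTruth, TrueGene

Ledger = Dict[str, Dict[str, int]]  # gene_id -> {str(pas position): n reads}


def _replicate_rng(seed: int, stage_index: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage_index, replicate]))


def _clip_3prime(exons: Sequence[GenomicInterval], strand: str, terminus: int) -> List[GenomicInterval]:
    """Truncate an exon chain at a genomic 3' terminus.

    A terminus inside an intron extends the preceding exon into the intron
    (the downstream part of the intron is unspliced in such a read).
    """
    chrom = exons[0].chrom
    out: List[GenomicInterval] = []
    if strand == "+":
        for e in exons:
            if e.end <= terminus:  # wholly upstream, keep and continue
                out.append(e)
            elif e.start <= terminus:  # terminus inside this exon
                out.append(GenomicInterval(chrom, e.start, terminus + 1, strand))
                break
            else:  # terminus fell in the intron before this exon
                last = out[-1]
                out[-1] = GenomicInterval(chrom, last.start, terminus + 1, strand)
                break
        if out and out[-1].end <= terminus:  # terminus past the annotated end
            out[-1] = GenomicInterval(chrom, out[-1].start, terminus + 1, strand)
        return out
    # minus strand: transcription runs right -> left, terminus is genomically low
    for e in reversed(exons):
        if e.start > terminus:
            out.append(e)
        elif e.end > terminus:  # terminus inside this exon
            out.append(GenomicInterval(chrom, terminus, e.end, strand))
            break
        else:  # terminus fell in the intron downstream (right) of this exon
            last = out[-1]
            out[-1] = GenomicInterval(chrom, terminus, last.end, strand)
            break
    if out and out[-1].start > terminus:  # terminus past the annotated end
        out[-1] = GenomicInterval(chrom, terminus, out[-1].end, strand)
    return sorted(out, key=lambda x: x.start)


def _clip_5prime(exons: List[GenomicInterval], strand: str, n_bases: int) -> List[GenomicInterval]:
    """Remove n exonic bases from the transcription 5' end of a chain."""
    if n_bases <= 0:
        return exons
    chrom = exons[0].chrom
    ordered = list(exons) if strand == "+" else list(reversed(exons))
    out: List[GenomicInterval] = []
    remaining = n_bases
    for i, e in enumerate(ordered):
        if remaining >= e.length:
            remaining -= e.length
            continue
        if strand == "+":
            out.append(GenomicInterval(chrom, e.start + remaining, e.end, strand))
        else:
            out.append(GenomicInterval(chrom, e.start, e.end - remaining, strand))
        out.extend(ordered[i + 1 :])
        break
    if not out:
        raise ValueError("5' truncation removed the whole read")
    return sorted(out, key=lambda x: x.start)


def simulate_read(
    transcript: TranscriptModel,
    pas_position: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    read_id: str,
) -> TranscriptModel:
    """One read: 3' terminus = PAS + rounded Gaussian jitter, 5' truncated."""
    strand = transcript.strand
    jitter = int(round(rng.normal(0.0, config.cleavage_jitter_sd))) if config.cleavage_jitter_sd > 0 else 0
    # jitter > 0 moves downstream in transcription direction
    terminus = pas_position + jitter if strand == "+" else pas_position - jitter
    lo = transcript.start + 1 if strand == "+" else 0
    hi = 10**12 if strand == "+" else transcript.end - 2
    terminus = max(lo, min(terminus, hi))
    exons = _clip_3prime(transcript.exons, strand, terminus)
    exonic = sum(e.length for e in exons)
    max_trunc = int(config.max_5p_truncation_fraction * max(0, exonic - config.min_read_exonic_length))
    trunc = int(rng.integers(0, max_trunc + 1)) if max_trunc > 0 else 0
    exons = _clip_5prime(exons, strand, trunc)
    return TranscriptModel(read_id, transcript.gene_id, exons)


def simulate_flnc_alignments(
    config: SimulationConfig,
    truth: SimulationGroundTruth,
    genes: Mapping[str, GeneModel],
    stage: str,
    replicate: int,
    seed: int,
) -> Tuple[List[TranscriptModel], Ledger]:
    """All reads for one (stage, replicate) plus the emitted-count ledger.

    Each read picks a transcript uniformly, then a PAS from the stage's
    usage vector (multinomial per gene); for multi-transcript (AS) genes the
    terminus follows the chosen transcript's own end. Deterministic for a
    given (seed, stage, replicate); the ledger is also stored on ``truth``.
    """
    stage_index = list(config.stages).index(stage)
    rng = _replicate_rng(seed, stage_index, replicate)
    sample_id = f"{stage}-{replicate}"
    reads: List[TranscriptModel] = []
    ledger: Ledger = {}
    for gene_id in sorted(truth.genes):
        tg = truth.genes[gene_id]
        gene = genes[gene_id]
        gene_ledger: Dict[str, int] = {str(p.position): 0 for p in tg.pas}
        n = config.reads_per_gene
        if tg.is_as_gene:
            # terminus dictated by the chosen transcript
            choices = rng.integers(0, len(gene.transcripts), size=n)
            for r, k in enumerate(choices):
                transcript = gene.transcripts[int(k)]
                pas = transcript.three_prime_end()
                read = simulate_read(
                    transcript, pas, config, rng, f"{sample_id}:{gene_id}.r{r}"
                )
                reads.append(read)
                gene_ledger[str(pas)] += 1
        else:
            usages = [p.usage_by_stage[stage] for p in tg.pas]
            counts = rng.multinomial(n, usages)
            transcript = gene.transcripts[0]
            r = 0
            for pas_truth, count in zip(tg.pas, counts):
                for _ in range(int(count)):
                    read = simulate_read(
                        transcript, pas_truth.position, config, rng,
                        f"{sample_id}:{gene_id}.r{r}",
                    )
                    reads.append(read)
                    r += 1
                gene_ledger[str(pas_truth.position)] += int(count)
        ledger[gene_id] = gene_ledger
    truth.ledger[sample_id] = ledger
    return reads, ledger


def simulate_cleavage_records(
    gene_ids: Sequence[str],
    pas_positions: Mapping[str, Sequence[int]],
    usages: Mapping[str, Sequence[float]],
    n_reads: int,
    jitter_sd: float,
    seed: int,
    sample_id: str = "sample",
    chrom: str = "chr1",
    strand: str = "+",
) -> Tuple[List[CleavageRecord], Dict[str, Dict[int, int]]]:
    """Fast path: emit assigned cleavage records directly (no exon chains).

    Used for clustering/recovery experiments where read structure is
    irrelevant. Returns (records, ledger[gene][pas] = intended count).
    """
    rng = np.random.default_rng(seed)
    records: List[CleavageRecord] = []
    ledger: Dict[str, Dict[int, int]] = {}
    for gene_id in gene_ids:
        positions = list(pas_positions[gene_id])
        counts = rng.multinomial(n_reads, list(usages[gene_id]))
        ledger[gene_id] = dict(zip(positions, (int(c) for c in counts)))
        for pas, count in zip(positions, counts):
            if count == 0:
                continue
            jitters = (
                np.rint(rng.normal(0.0, jitter_sd, size=int(count))).astype(int)
                if jitter_sd > 0
                else np.zeros(int(count), dtype=int)
            )
            sign = 1 if strand == "+" else -1
            for j in jitters:
                records.append(
                    CleavageRecord(
                        chrom=chrom,
                        position=int(pas + sign * j),
                        strand=strand,
                        gene_id=gene_id,
                        sample_id=sample_id,
                    )
                )
    return records, ledger
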