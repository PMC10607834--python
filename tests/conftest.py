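from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pytest

from isoapa.genome import GeneModel, GenomicInterval, TranscriptModel


def make_transcript(
    tid: str,
    exons: Sequence[Tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    gene_id: Optional[str] = None,
) -> TranscriptModel:
    return TranscriptModel(
        tid, gene_id, [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    )


def make_gene(
    gene_id: str,
    isoforms: dict,
    strand: str = "+",
    chrom: str = "chr1",
) -> GeneModel:
    txs = [
        make_transcript(tid, exons, strand, chrom, gene_id)
        for tid, exons in isoforms.items()
    ]
    return GeneModel(gene_id, txs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def random_genome(rng) -> dict:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = bases[rng.integers(0, 4, size=5000)].tobytes().decode()
    return {"chr1": seq}
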