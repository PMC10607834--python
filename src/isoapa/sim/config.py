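"""Simulation configuration and ground-truth containers."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union


@dataclass
class SimulationConfig:
    n_genes: int = 200
    stages: Tuple[str, ...] = ("DAP10", "DAP18", "DAP26", "DAP34")
    replicates: int = 3
    reads_per_gene: int = 200
    # distribution over the number of planted PAS per gene
    pas_per_gene: Mapping[int, float] = field(default_factory=lambda: {1: 0.6, 2: 0.4})
    min_pas_spacing: int = 60
    # usage of (proximal, distal) sites in two-PAS genes, first stages
    usage_two_site: Tuple[float, float] = (0.3, 0.7)
    # fraction of two-PAS genes whose usage flips between stages 2 and 3
    shift_fraction: float = 0.25
    cleavage_jitter_sd: float = 5.0
    # fraction of genes with AATAAA planted at offsets -30..-25 of each PAS
    signal_fraction: float = 0.6
    signal_offset: int = -30  # transcription-direction offset of the hexamer start
    # fraction of two-PAS genes whose proximal site sits in a long intron
    intronic_fraction: float = 0.15
    exon_count_range: Tuple[int, int] = (3, 5)
    exon_length_range: Tuple[int, int] = (120, 250)
    intron_length_range: Tuple[int, int] = (80, 300)
    long_intron_length_range: Tuple[int, int] = (1500, 3000)
    gene_gap_range: Tuple[int, int] = (500, 1200)
    chrom_pad: int = 200
    max_5p_truncation_fraction: float = 0.5
    min_read_exonic_length: int = 60
    plant_as_genes: bool = True
    chrom_name: str = "chr1"

    def validate(self) -> None:
        if self.n_genes < 0 or self.replicates < 1 or self.reads_per_gene < 1:
            raise ValueError("n_genes, replicates and reads_per_gene must be positive")
        total = sum(self.pas_per_gene.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("pas_per_gene probabilities must sum to 1")
        if any(k < 1 for k in self.pas_per_gene):
            raise ValueError("pas_per_gene keys must be >= 1")
        if abs(sum(self.usage_two_site) - 1.0) > 1e-9:
            raise ValueError("usage_two_site must sum to 1")
        if self.min_pas_spacing <= 0:
            raise ValueError("min_pas_spacing must be positive")
        if self.cleavage_jitter_sd < 0:
            raise ValueError("cleavage_jitter_sd must be >= 0")
        lo, hi = self.exon_length_range
        if lo + hi < 2 * self.min_pas_spacing:
            # the terminal exon hosts two PAS in exonic two-PAS genes
            raise ValueError(
                "exon_length_range too small for min_pas_spacing: terminal "
                "exons could not host two planted sites"
            )


@dataclass
class TruePAS:
    position: int
    usage_by_stage: Dict[str, float]
    is_intronic: bool = False
    has_signal: bool = False


@dataclass
class TrueGene:
    gene_id: str
    chrom: str
    strand: str
    transcript_ids: List[str]
    pas: List[TruePAS]  # ordered 5' -> 3' in transcription direction
    shifted: bool = False
    is_as_gene: bool = False


@dataclass
class PlantedEvent:
    gene_id: str
    event_type: str
    coords: Tuple[int, ...]


@dataclass
class SimulationGroundTruth:
    genes: Dict[str, TrueGene]
    events: List[PlantedEvent]
    # ledger["stage/replicate"][gene_id][str(position)] = emitted read count
    ledger: Dict[str, Dict[str, Dict[str, int]]] = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "genes": {g: asdict(v) for g, v in self.genes.items()},
            "events": [asdict(e) for e in self.events],
            "ledger": self.ledger,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SimulationGroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = {
            g: TrueGene(
                gene_id=v["gene_id"],
                chrom=v["chrom"],
                strand=v["strand"],
                transcript_ids=list(v["transcript_ids"]),
                pas=[TruePAS(**p) for p in v["pas"]],
                shifted=v["shifted"],
                is_as_gene=v["is_as_gene"],
            )
            for g, v in payload["genes"].items()
        }
        events = [
            PlantedEvent(e["gene_id"], e["event_type"], tuple(e["coords"]))
            for e in payload["events"]
        ]
        return cls(genes, events, payload.get("ledger", {}))
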