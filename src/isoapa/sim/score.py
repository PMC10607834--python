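"""Recovery scoring of pipeline outputs against planted ground truth."""
from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from ..differential import DifferentialCall
from ..isoforms.events import ASEvent
from ..pas import GenePASProfile
from .config import SimulationGroundTruth

DEFAULT_TOLERANCE = 12


@dataclass
class PrecisionRecall:
    n_true: int
    n_called: int
    n_matched: int

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_called if self.n_called else float("nan")

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")


def match_positions(
    true_positions: Sequence[int],
    called_positions: Sequence[int],
    tolerance: int = DEFAULT_TOLERANCE,
) -> List[Tuple[int, int]]:
    """Greedy one-to-one matching by distance; ties by called then true pos.

    Only pairs within +/- tolerance are eligible.
    """
    pairs = sorted(
        (abs(c - t), c, t)
        for t in true_positions
        for c in called_positions
        if abs(c - t) <= tolerance
    )
    used_true, used_called = set(), set()
    matches: List[Tuple[int, int]] = []
    for _, c, t in pairs:
        if t in used_true or c in used_called:
            continue
        used_true.add(t)
        used_called.add(c)
        matches.append((t, c))
    return matches


def score_pas(
    profiles: Mapping[str, GenePASProfile],
    truth: SimulationGroundTruth,
    tolerance: int = DEFAULT_TOLERANCE,
) -> Dict[str, object]:
    """PAS-level precision/recall plus usage errors on matched sites.

    Scored over genes with PAS ground truth; called sites in unknown genes
    are ignored (they cannot be adjudicated).
    """
    n_true = n_called = n_matched = 0
    usage_errors: List[float] = []
    per_gene_full_recovery: Dict[str, bool] = {}
    for gene_id, tg in truth.genes.items():
        true_sites = tg.pas
        profile = profiles.get(gene_id)
        called = profile.sites if profile is not None else []
        n_true += len(true_sites)
        n_called += len(called)
        matches = match_positions(
            [p.position for p in true_sites],
            [s.position for s in called],
            tolerance,
        )
        n_matched += len(matches)
        called_by_pos = {s.position: s for s in called}
        true_by_pos = {p.position: p for p in true_sites}
        all_matched_within_usage = len(matches) == len(true_sites)
        for t_pos, c_pos in matches:
            true_usage = _pooled_true_usage(true_by_pos[t_pos])
            err = abs(called_by_pos[c_pos].usage - true_usage)
            usage_errors.append(err)
            if err > 0.05:
                all_matched_within_usage = False
        per_gene_full_recovery[gene_id] = (
            all_matched_within_usage and len(called) == len(true_sites)
        )
    return {
        "sites": PrecisionRecall(n_true, n_called, n_matched),
        "usage_errors": usage_errors,
        "per_gene_full_recovery": per_gene_full_recovery,
    }


def _pooled_true_usage(true_pas) -> float:
    vals = list(true_pas.usage_by_stage.values())
    return sum(vals) / len(vals)


def score_apa_genes(
    profiles: Mapping[str, GenePASProfile], truth: SimulationGroundTruth
) -> PrecisionRecall:
    true_apa = {g for g, tg in truth.genes.items() if len(tg.pas) >= 2}
    called_apa = {
        g for g, p in profiles.items()
        if len(p.sites) >= 2 and g in truth.genes
    }
    return PrecisionRecall(len(true_apa), len(called_apa), len(true_apa & called_apa))


def score_intronic(
    profiles: Mapping[str, GenePASProfile],
    truth: SimulationGroundTruth,
    tolerance: int = DEFAULT_TOLERANCE,
) -> PrecisionRecall:
    n_true = n_called = n_matched = 0
    for gene_id, tg in truth.genes.items():
        true_intronic = [p.position for p in tg.pas if p.is_intronic]
        profile = profiles.get(gene_id)
        called_intronic = (
            [s.position for s in profile.sites if s.is_intronic] if profile else []
        )
        n_true += len(true_intronic)
        n_called += len(called_intronic)
        n_matched += len(match_positions(true_intronic, called_intronic, tolerance))
    return PrecisionRecall(n_true, n_called, n_matched)


def score_events(
    called_events: Iterable[ASEvent], truth: SimulationGroundTruth
) -> Dict[str, object]:
    """Exact matching on (gene, type, defining coordinates)."""
    true_keys = {(e.gene_id, e.event_type, tuple(e.coords)) for e in truth.events}
    called_keys = {
        (e.gene_id, e.event_type, tuple(e.defining_coords)) for e in called_events
    }
    matched = true_keys & called_keys
    by_type: Dict[str, bool] = {}
    for gene_id, etype, coords in true_keys:
        by_type[etype] = (gene_id, etype, coords) in matched
    return {
        "events": PrecisionRecall(len(true_keys), len(called_keys), len(matched)),
        "recovered_by_type": by_type,
    }


def score_differential(
    calls: Sequence[DifferentialCall],
    truth: SimulationGroundTruth,
    comparison: str,
) -> PrecisionRecall:
    """Gene-level detection of planted usage shifts in one comparison."""
    true_shifted = {g for g, tg in truth.genes.items() if tg.shifted}
    called = {
        c.gene_id for c in calls
        if c.comparison == comparison and c.significant and c.gene_id in truth.genes
    }
    return PrecisionRecall(len(true_shifted), len(called), len(true_shifted & called))


def score_recovery(
    profiles: Mapping[str, GenePASProfile],
    truth: SimulationGroundTruth,
    called_events: Iterable[ASEvent] = (),
    differential_calls: Sequence[DifferentialCall] = (),
    shift_comparison: Optional[str] = None,
    tolerance: int = DEFAULT_TOLERANCE,
) -> Dict[str, object]:
    """Combined recovery report for PAS, APA genes, intronic PAS, AS events
    and differential calls."""
    report: Dict[str, object] = {}
    report["pas"] = score_pas(profiles, truth, tolerance)
    report["apa_genes"] = score_apa_genes(profiles, truth)
    report["intronic_pas"] = score_intronic(profiles, truth, tolerance)
    report["as_events"] = score_events(called_events, truth)
    if differential_calls and shift_comparison:
        report["differential"] = score_differential(
            differential_calls, truth, shift_comparison
        )
    return report


def report_to_jsonable(report: Mapping[str, object]) -> Dict[str, object]:
    def convert(value):
        if isinstance(value, PrecisionRecall):
            d = asdict(value)
            d["precision"] = value.precision
            d["recall"] = value.recall
            return d
        if isinstance(value, dict):
            return {str(k): convert(v) for k, v in value.items()}
        if isinstance(value, (list, tuple)):
            return [convert(v) for v in value]
        return value

    return {k: convert(v) for k, v in report.items()}
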