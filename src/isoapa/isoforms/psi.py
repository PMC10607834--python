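"""Percent-spliced-in (PSI) from isoform abundances."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd

from .events import ASEvent


@dataclass(frozen=True)
class PsiValue:
    event_id: str
    sample_id: str
    psi: Optional[float]  # None when the event has zero total abundance

    def __post_init__(self) -> None:
        if self.psi is not None and not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"psi out of [0,1]: {self.psi}")


def compute_psi(
    event: ASEvent,
    abundances: Mapping[str, float],
    sample_id: str = "sample",
) -> PsiValue:
    """PSI = inclusion / (inclusion + exclusion); None when total is 0."""
    for tid in event.inclusion_isoforms | event.exclusion_isoforms:
        if tid not in abundances:
            raise KeyError(
                f"event {event.event_id}: no abundance for transcript {tid}"
            )
    inc = sum(abundances[t] for t in event.inclusion_isoforms)
    exc = sum(abundances[t] for t in event.exclusion_isoforms)
    total = inc + exc
    if total <= 0:
        return PsiValue(event.event_id, sample_id, None)
    return PsiValue(event.event_id, sample_id, inc / total)


def psi_table(
    events: Iterable[ASEvent],
    abundance_table: pd.DataFrame,
) -> pd.DataFrame:
    """PSI per event (rows) and sample (columns).

    ``abundance_table`` is transcripts x samples. Undefined PSI becomes NaN.
    """
    rows: Dict[str, List[Optional[float]]] = {}
    for event in events:
        vals = []
        for sample in abundance_table.columns:
            ab = abundance_table[sample].to_dict()
            vals.append(compute_psi(event, ab, sample).psi)
        rows[event.event_id] = vals
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(abundance_table.columns)
    )
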