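"""Structural pre-filters for lncRNA candidates and exon-length comparison.

Coding-potential prediction is deliberately not part of this package; only
the structural rule (mono-exonic transcripts shorter than 200 nt are
removed) and the lncRNA-vs-coding exon length contrast are implemented.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy.stats import mannwhitneyu

from .genome.model import TranscriptModel

DEFAULT_MIN_EXON_LENGTH = 200

REASON_MONOEXONIC_SHORT = "monoexonic_short"
REASON_MONOEXONIC = "monoexonic"
REASON_SHORT = "short"


@dataclass
class FilterReport:
    input_count: int
    retained: List[TranscriptModel]
    removed: List[TranscriptModel]
    reasons: Dict[str, str] = field(default_factory=dict)  # transcript_id -> reason

    def __post_init__(self) -> None:
        if self.input_count != len(self.retained) + len(self.removed):
            raise ValueError("filter report counts are not conserved")


def structural_filter(
    transcripts: Iterable[TranscriptModel],
    min_exon_length: int = DEFAULT_MIN_EXON_LENGTH,
    mode: str = "conjunctive",
) -> FilterReport:
    """Remove structurally implausible lncRNA candidates.

    conjunctive (default): remove transcripts that are mono-exonic AND have
    total exon length < min_exon_length. disjunctive: remove transcripts
    that are mono-exonic OR shorter than min_exon_length (the alternative
    reading of the rule). A transcript of exactly min_exon_length is kept.
    """
    if mode not in ("conjunctive", "disjunctive"):
        raise ValueError(f"unknown filter mode {mode!r}")
    retained: List[TranscriptModel] = []
    removed: List[TranscriptModel] = []
    reasons: Dict[str, str] = {}
    n = 0
    for t in transcripts:
        n += 1
        mono = len(t.exons) == 1
        short = t.exonic_length < min_exon_length
        if mode == "conjunctive":
            drop = mono and short
            reason = REASON_MONOEXONIC_SHORT
        else:
            drop = mono or short
            reason = REASON_MONOEXONIC if mono else REASON_SHORT
        if drop:
            removed.append(t)
            reasons[t.transcript_id] = reason
        else:
            retained.append(t)
    return FilterReport(n, retained, removed, reasons)


@dataclass
class ExonLengthComparison:
    lnc_lengths: List[int]
    coding_lengths: List[int]
    lnc_median: float
    coding_median: float
    lnc_quartiles: Tuple[float, float]
    coding_quartiles: Tuple[float, float]
    p_value: Optional[float]


def exon_length_density(
    lnc_transcripts: Iterable[TranscriptModel],
    coding_transcripts: Iterable[TranscriptModel],
) -> ExonLengthComparison:
    """Pooled per-exon length distributions with a two-sided rank-sum test.

    Degenerate inputs (a single exon per group) still yield the summary; the
    test p-value is None when it cannot be computed.
    """
    lnc = [e.length for t in lnc_transcripts for e in t.exons]
    coding = [e.length for t in coding_transcripts for e in t.exons]
    if not lnc or not coding:
        raise ValueError("both transcript sets must be non-empty")

    def _q(lengths: List[int]) -> Tuple[float, Tuple[float, float]]:
        arr = np.asarray(lengths)
        return float(np.median(arr)), (
            float(np.percentile(arr, 25)),
            float(np.percentile(arr, 75)),
        )

    lnc_median, lnc_q = _q(lnc)
    coding_median, coding_q = _q(coding)
    try:
        p = float(mannwhitneyu(lnc, coding, alternative="two-sided").pvalue)
    except ValueError:
        p = None
    return ExonLengthComparison(lnc, coding, lnc_median, coding_median, lnc_q, coding_q, p)
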