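"""Nucleotide-composition profiles around poly(A) sites and fixed k-mer
signal counting (AATAAA / TGTA by default, RNA alphabet accepted)."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome.fasta import GenomeLike, fetch, reverse_complement

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"

DEFAULT_SIGNAL_KMERS = ("AATAAA", "TGTA")
DEFAULT_SIGNAL_WINDOW = (-40, -10)


@dataclass
class PositionFrequencyMatrix:
    """Per-offset base probabilities over {A,C,G,T}.

    ``offsets[i]`` is the transcription-direction offset of column ``i``
    relative to the anchor (negative = upstream). Columns are renormalized
    after excluding N bases; an all-N column is left as zeros.
    """

    offsets: np.ndarray  # (n_cols,)
    freqs: np.ndarray  # (n_cols, 4)
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, index=self.offsets, columns=list(BASES))

    def column(self, offset: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.offsets == offset)[0])
        return self.freqs[idx]


def tally_matrix(sequences: Sequence[str], first_offset: int) -> PositionFrequencyMatrix:
    """Column-wise base tally of equal-length sequences, N-excluded."""
    if not sequences:
        raise ValueError("no sequences to tally")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences have unequal lengths")
    counts = np.zeros((length, 4), dtype=float)
    for seq in sequences:
        for i, base in enumerate(seq.upper()):
            j = _BASE_INDEX.get(base)
            if j is not None:
                counts[i, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freqs = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    offsets = np.arange(first_offset, first_offset + length)
    return PositionFrequencyMatrix(offsets, freqs, len(sequences))


def _site_window(
    genome: GenomeLike, chrom: str, strand: str, position: int, lo: int, hi: int
) -> Optional[str]:
    """Bases at transcription offsets lo..hi (inclusive) around a site, or
    None when out of chromosome bounds."""
    if strand == "+":
        start, end = position + lo, position + hi + 1
    else:
        start, end = position - hi, position - lo + 1
    try:
        seq = fetch(genome, chrom, start, end)
    except (ValueError, KeyError):
        return None
    return reverse_complement(seq) if strand == "-" else seq


def nucleotide_composition(
    sites: Iterable,
    genome: GenomeLike,
    flank: int = 50,
) -> PositionFrequencyMatrix:
    """Composition profile at offsets -flank..+flank around cleavage sites.

    Sites provide ``chrom``, ``position`` and ``strand`` attributes. Minus
    strand windows are reverse-complemented so negative offsets are upstream
    in transcription direction. Out-of-bounds sites are skipped;
    ``n_sequences`` reflects only the tallied sites.
    """
    seqs: List[str] = []
    n_skipped = 0
    for site in sites:
        window = _site_window(genome, site.chrom, site.strand, site.position, -flank, flank)
        if window is None:
            n_skipped += 1
            continue
        seqs.append(window)
    if not seqs:
        raise ValueError("no in-bounds sites to profile")
    pfm = tally_matrix(seqs, first_offset=-flank)
    pfm.n_sequences = len(seqs)
    return pfm


def normalize_kmer(kmer: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return kmer.upper().replace("U", "T")


def count_overlapping(seq: str, kmer: str) -> int:
    """Occurrences of kmer in seq, overlapping scan."""
    count = start = 0
    while True:
        idx = seq.find(kmer, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def kmer_window_counts(
    sites: Iterable,
    genome: GenomeLike,
    kmers: Sequence[str] = DEFAULT_SIGNAL_KMERS,
    window: Tuple[int, int] = DEFAULT_SIGNAL_WINDOW,
    flank: Optional[int] = None,
) -> pd.DataFrame:
    """Occurrences of each k-mer in the upstream signal window of each site.

    ``window`` gives inclusive transcription-direction offsets (default
    -40..-10). Returns a table per k-mer with total occurrence count, number
    of sites with >= 1 hit, and the fraction of scanned sites hit.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"invalid window {window}: requires lo <= hi")
    if flank is not None and (abs(lo) > flank or abs(hi) > flank):
        raise ValueError(f"window {window} wider than flank {flank}")
    kmers = [normalize_kmer(k) for k in kmers]
    totals = {k: 0 for k in kmers}
    hit_sites = {k: 0 for k in kmers}
    n_sites = 0
    for site in sites:
        seq = _site_window(genome, site.chrom, site.strand, site.position, lo, hi)
        if seq is None:
            continue
        n_sites += 1
        for k in kmers:
            c = count_overlapping(seq, k)
            totals[k] += c
            if c:
                hit_sites[k] += 1
    rows = []
    for k in kmers:
        frac = hit_sites[k] / n_sites if n_sites else float("nan")
        rows.append(
            {"kmer": k, "n_sites": n_sites, "total_hits": totals[k],
             "sites_with_hit": hit_sites[k], "fraction_with_hit": frac}
        )
    return pd.DataFrame(rows).set_index("kmer")


def plot_composition(pfm: PositionFrequencyMatrix, path, title: str = "") -> None:
    """Optional line plot of a composition profile (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for j, base in enumerate(BASES):
        ax.plot(pfm.offsets, pfm.freqs[:, j], label=base)
    ax.set_xlabel("offset from cleavage site (nt)")
    ax.set_ylabel("base frequency")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
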