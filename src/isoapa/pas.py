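"""Poly(A)-site identification from read 3' ends.

Per gene: exact-position cleavage histograms are clustered greedily
(absorption window +/- 12 nt, retained sites > 30 nt apart), sites with
usage > 5% of the gene's pooled reads are kept, the highest-abundance site
is flagged major, and abundances are normalized by median library size.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import mannwhitneyu

from .genome.model import CleavageRecord, GeneModel, extract_introns

log = logging.getLogger(__name__)

DEFAULT_MIN_USAGE = 0.05
DEFAULT_MIN_SEPARATION = 30
DEFAULT_ASSIGNMENT_HALFWIDTH = 12


@dataclass
class PolyASite:
    chrom: str
    position: int
    strand: str
    gene_id: str
    raw_count: int  # pooled over samples
    usage: float = 0.0
    is_major: bool = False
    is_intronic: bool = False
    per_sample_counts: Dict[str, int] = field(default_factory=dict)
    normalized_abundance: Dict[str, float] = field(default_factory=dict)
    major_ratio: Optional[float] = None


@dataclass
class GenePASProfile:
    gene_id: str
    chrom: str
    strand: str
    sites: List[PolyASite]  # ordered 5' -> 3' in transcription direction
    samples: List[str]
    total_assigned: int  # pre-filter pooled read count for the gene

    def counts_matrix(self) -> np.ndarray:
        """Sites x samples matrix of raw per-sample counts."""
        mat = np.zeros((len(self.sites), len(self.samples)), dtype=int)
        for i, site in enumerate(self.sites):
            for j, sample in enumerate(self.samples):
                mat[i, j] = site.per_sample_counts.get(sample, 0)
        return mat

    @property
    def major_site(self) -> PolyASite:
        majors = [s for s in self.sites if s.is_major]
        if len(majors) != 1:
            raise ValueError(f"gene {self.gene_id}: {len(majors)} major sites")
        return majors[0]


def collect_cleavage_counts(
    records: Iterable[CleavageRecord],
) -> Tuple[Dict[str, Dict[int, Counter]], Dict[str, Tuple[str, str]], int]:
    """Exact position histograms per gene per sample.

    Returns (counts[gene][position] -> Counter(sample), gene -> (chrom,
    strand), n_unassigned). Unassigned records are excluded and tallied.
    """
    counts: Dict[str, Dict[int, Counter]] = defaultdict(lambda: defaultdict(Counter))
    locations: Dict[str, Tuple[str, str]] = {}
    n_unassigned = 0
    for rec in records:
        if rec.gene_id is None:
            n_unassigned += 1
            continue
        counts[rec.gene_id][rec.position][rec.sample_id] += 1
        locations.setdefault(rec.gene_id, (rec.chrom, rec.strand))
    return {g: dict(v) for g, v in counts.items()}, locations, n_unassigned


def cluster_cleavage_sites(
    position_counts: Mapping[int, int],
    assignment_halfwidth: int = DEFAULT_ASSIGNMENT_HALFWIDTH,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> Tuple[List[Tuple[int, int]], Dict[int, int]]:
    """Greedy clustering of one gene's cleavage-position histogram.

    Repeatedly takes the unconsumed position with the highest count (ties:
    lowest coordinate) as a representative and absorbs every unconsumed
    position within +/- ``assignment_halfwidth``. Afterwards any
    representative within ``min_separation`` of a higher-ranked kept
    representative is re-absorbed by the closest kept one (ties: higher
    count, then lower coordinate), so retained representatives are pairwise
    > ``min_separation`` apart.

    Returns (sites, assignment): sites as (position, count) sorted by
    position, and the raw-position -> representative map.
    """
    if assignment_halfwidth <= 0 or min_separation <= 0:
        raise ValueError(
            "assignment_halfwidth and min_separation must be positive "
            f"(got {assignment_halfwidth}, {min_separation})"
        )
    if any(c <= 0 for c in position_counts.values()):
        raise ValueError("position counts must be positive")
    remaining = dict(position_counts)
    order = sorted(remaining, key=lambda p: (-remaining[p], p))
    consumed = set()
    reps: List[int] = []  # selection order = descending count
    assign: Dict[int, int] = {}
    rep_count: Dict[int, int] = {}
    for pos in order:
        if pos in consumed:
            continue
        members = [
            p for p in position_counts
            if p not in consumed and abs(p - pos) <= assignment_halfwidth
        ]
        for m in members:
            consumed.add(m)
            assign[m] = pos
        reps.append(pos)
        rep_count[pos] = sum(position_counts[m] for m in members)
    initial_count = dict(rep_count)
    kept: List[int] = []
    for rep in reps:
        close = [k for k in kept if abs(k - rep) <= min_separation]
        if close:
            winner = min(close, key=lambda k: (abs(k - rep), -initial_count[k], k))
            rep_count[winner] += rep_count.pop(rep)
            for p, r in list(assign.items()):
                if r == rep:
                    assign[p] = winner
        else:
            kept.append(rep)
    sites = sorted((k, rep_count[k]) for k in kept)
    return sites, assign


def build_profile(
    gene_id: str,
    chrom: str,
    strand: str,
    position_sample_counts: Mapping[int, Counter],
    samples: Sequence[str],
    assignment_halfwidth: int = DEFAULT_ASSIGNMENT_HALFWIDTH,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> GenePASProfile:
    """Cluster one gene's histogram and assemble its (pre-filter) profile."""
    pooled = {pos: sum(c.values()) for pos, c in position_sample_counts.items()}
    sites, assign = cluster_cleavage_sites(pooled, assignment_halfwidth, min_separation)
    per_site_sample: Dict[int, Counter] = defaultdict(Counter)
    for pos, sample_counter in position_sample_counts.items():
        per_site_sample[assign[pos]].update(sample_counter)
    total = sum(pooled.values())
    pas = [
        PolyASite(
            chrom=chrom,
            position=pos,
            strand=strand,
            gene_id=gene_id,
            raw_count=count,
            usage=count / total,
            per_sample_counts=dict(per_site_sample[pos]),
        )
        for pos, count in sites
    ]
    if strand == "-":
        pas = pas[::-1]  # 5' -> 3' in transcription direction
    return GenePASProfile(gene_id, chrom, strand, pas, list(samples), total)


def filter_by_usage(
    profile: GenePASProfile, min_usage: float = DEFAULT_MIN_USAGE
) -> Optional[GenePASProfile]:
    """Keep sites with pooled usage strictly > min_usage; renormalize.

    Usage is computed once from the pre-filter pooled counts (no iteration).
    Returns None when no site survives (caller drops the gene).
    """
    kept = [
        s for s in profile.sites if s.raw_count / profile.total_assigned > min_usage
    ]
    if not kept:
        log.warning("gene %s: no poly(A) site above usage threshold", profile.gene_id)
        return None
    retained_total = sum(s.raw_count for s in kept)
    for s in kept:
        s.usage = s.raw_count / retained_total
    return GenePASProfile(
        profile.gene_id, profile.chrom, profile.strand, kept,
        profile.samples, profile.total_assigned,
    )


def select_major_site(profile: GenePASProfile) -> GenePASProfile:
    """Flag the highest-count site as major; ties go to the 3'-most site.

    Sites are ordered 5'->3' in transcription direction, so the last site
    with the maximal count is the distal tie-winner on either strand.
    """
    best = max(s.raw_count for s in profile.sites)
    major_idx = max(i for i, s in enumerate(profile.sites) if s.raw_count == best)
    for i, s in enumerate(profile.sites):
        s.is_major = i == major_idx
    return profile


def normalize_abundance(
    profiles: Iterable[GenePASProfile],
    library_sizes: Mapping[str, float],
) -> None:
    """Median-library scaling plus per-gene major-site ratios (in place)."""
    for sample, size in library_sizes.items():
        if size <= 0:
            raise ValueError(f"library size for {sample} must be positive")
    median_size = float(np.median(list(library_sizes.values())))
    for profile in profiles:
        major_count = max(s.raw_count for s in profile.sites)
        for site in profile.sites:
            site.normalized_abundance = {
                sample: site.per_sample_counts.get(sample, 0) * median_size / size
                for sample, size in library_sizes.items()
            }
            site.major_ratio = site.raw_count / major_count


def classify_apa_genes(
    profiles: Iterable[GenePASProfile],
) -> Dict[str, object]:
    """Partition genes into single-PAS vs APA; PAS-count histogram included."""
    single, apa = [], []
    histogram: Counter = Counter()
    for profile in profiles:
        histogram[len(profile.sites)] += 1
        (apa if len(profile.sites) >= 2 else single).append(profile.gene_id)
    return {
        "single_pas_genes": single,
        "apa_genes": apa,
        "histogram": dict(sorted(histogram.items())),
    }


def locate_intronic_pas(
    profiles: Iterable[GenePASProfile],
    genes: Mapping[str, GeneModel],
) -> List[PolyASite]:
    """Flag sites falling within an intron of the gene's reference transcript.

    The reference transcript is the gene's largest-exonic-length transcript.
    """
    intronic: List[PolyASite] = []
    for profile in profiles:
        gene = genes.get(profile.gene_id)
        if gene is None:
            continue
        introns = extract_introns(gene.reference_transcript())
        for site in profile.sites:
            site.is_intronic = any(iv.contains(site.position) for iv in introns)
            if site.is_intronic:
                intronic.append(site)
    return intronic


@dataclass
class IntronLengthComparison:
    pas_intron_lengths: List[int]
    all_intron_lengths: List[int]
    pas_median: Optional[float]
    all_median: Optional[float]
    pas_quartiles: Optional[Tuple[float, float]]
    all_quartiles: Optional[Tuple[float, float]]
    p_value: Optional[float]


def intron_length_comparison(
    genes: Mapping[str, GeneModel],
    intronic_sites: Sequence[PolyASite],
) -> IntronLengthComparison:
    """Lengths of PAS-containing introns vs all introns + rank-sum test.

    Introns come from each gene's reference transcript. An empty group makes
    the test undefined (p None) and is logged.
    """
    sites_by_gene: Dict[str, List[int]] = defaultdict(list)
    for site in intronic_sites:
        sites_by_gene[site.gene_id].append(site.position)
    all_lengths: List[int] = []
    pas_lengths: List[int] = []
    for gene_id, gene in genes.items():
        introns = extract_introns(gene.reference_transcript())
        positions = sites_by_gene.get(gene_id, [])
        for iv in introns:
            all_lengths.append(iv.length)
            if any(iv.contains(p) for p in positions):
                pas_lengths.append(iv.length)

    def _stats(lengths: List[int]):
        if not lengths:
            return None, None
        arr = np.asarray(lengths)
        return float(np.median(arr)), (
            float(np.percentile(arr, 25)),
            float(np.percentile(arr, 75)),
        )

    pas_median, pas_q = _stats(pas_lengths)
    all_median, all_q = _stats(all_lengths)
    if not pas_lengths or not all_lengths:
        log.warning("intron length comparison: empty group, test undefined")
        p_value = None
    else:
        p_value = float(
            mannwhitneyu(pas_lengths, all_lengths, alternative="two-sided").pvalue
        )
    return IntronLengthComparison(
        pas_lengths, all_lengths, pas_median, all_median, pas_q, all_q, p_value
    )


def write_pas_bed(profiles: Mapping[str, GenePASProfile], path) -> None:
    """BED6: name = gene:ordinal (5'->3'), score = pooled raw count."""
    rows = []
    for gene_id in sorted(profiles):
        profile = profiles[gene_id]
        for ordinal, site in enumerate(profile.sites, start=1):
            rows.append(
                (site.chrom, site.position, site.position + 1,
                 f"{gene_id}:{ordinal}", site.raw_count, site.strand)
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_site_table(profiles: Mapping[str, GenePASProfile], path) -> None:
    """TSV site table with per-sample raw counts and normalized abundances."""
    samples: List[str] = []
    for profile in profiles.values():
        samples = list(profile.samples)
        break
    with open(path, "w") as fh:
        header = [
            "gene_id", "chrom", "position", "strand", "raw_count", "usage",
            "is_major", "is_intronic", "major_ratio", "total_assigned",
        ]
        header += [f"n_{s}" for s in samples]
        header += [f"norm_{s}" for s in samples]
        fh.write("\t".join(header) + "\n")
        for gene_id in sorted(profiles):
            profile = profiles[gene_id]
            for site in profile.sites:
                row = [
                    gene_id, site.chrom, site.position, site.strand,
                    site.raw_count, f"{site.usage:.6g}",
                    int(site.is_major), int(site.is_intronic),
                    "" if site.major_ratio is None else f"{site.major_ratio:.6g}",
                    profile.total_assigned,
                ]
                row += [site.per_sample_counts.get(s, 0) for s in samples]
                row += [
                    f"{site.normalized_abundance.get(s, 0.0):.6g}" for s in samples
                ]
                fh.write("\t".join(str(x) for x in row) + "\n")


def read_site_table(path) -> Dict[str, GenePASProfile]:
    """Rebuild profiles from a site table written by :func:`write_site_table`."""
    import csv

    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fieldnames = reader.fieldnames or []
        samples = [f[2:] for f in fieldnames if f.startswith("n_")]
        rows = list(reader)
    grouped: Dict[str, List[dict]] = defaultdict(list)
    for row in rows:
        grouped[row["gene_id"]].append(row)
    profiles: Dict[str, GenePASProfile] = {}
    for gene_id, gene_rows in grouped.items():
        sites = []
        for row in gene_rows:
            sites.append(
                PolyASite(
                    chrom=row["chrom"],
                    position=int(row["position"]),
                    strand=row["strand"],
                    gene_id=gene_id,
                    raw_count=int(row["raw_count"]),
                    usage=float(row["usage"]),
                    is_major=bool(int(row["is_major"])),
                    is_intronic=bool(int(row["is_intronic"])),
                    per_sample_counts={s: int(row[f"n_{s}"]) for s in samples},
                    normalized_abundance={
                        s: float(row[f"norm_{s}"]) for s in samples
                    },
                    major_ratio=float(row["major_ratio"]) if row["major_ratio"] else None,
                )
            )
        strand = sites[0].strand
        sites.sort(key=lambda s: s.position, reverse=strand == "-")
        profiles[gene_id] = GenePASProfile(
            gene_id, sites[0].chrom, strand, sites,
            samples, int(gene_rows[0]["total_assigned"]),
        )
    return profiles


def build_all_profiles(
    records: Iterable[CleavageRecord],
    samples: Sequence[str],
    min_usage: float = DEFAULT_MIN_USAGE,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    assignment_halfwidth: int = DEFAULT_ASSIGNMENT_HALFWIDTH,
) -> Tuple[Dict[str, GenePASProfile], int]:
    """Full per-gene pipeline: collect -> cluster -> filter -> major site.

    Returns (profiles keyed by gene, n_unassigned_records). Genes losing all
    sites to the usage filter are dropped.
    """
    counts, locations, n_unassigned = collect_cleavage_counts(records)
    profiles: Dict[str, GenePASProfile] = {}
    for gene_id in sorted(counts):
        chrom, strand = locations[gene_id]
        profile = build_profile(
            gene_id, chrom, strand, counts[gene_id], samples,
            assignment_halfwidth, min_separation,
        )
        profile = filter_by_usage(profile, min_usage)
        if profile is None:
            continue
        profiles[gene_id] = select_major_site(profile)
    return profiles, n_unassigned
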