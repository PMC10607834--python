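"""Differential poly(A)-site usage between consecutive stages (Fisher's
exact test, uncorrected p < alpha as in the source protocol, with a BH
column alongside) and a permutation test for delta-PSI."""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .pas import GenePASProfile, PolyASite

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = stages, columns = (this site, all other sites of the gene)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def testable(self) -> bool:
        return (self.a + self.b) > 0 and (self.c + self.d) > 0


@dataclass
class DifferentialCall:
    unit_id: str
    gene_id: str
    comparison: str
    table: ContingencyTable2x2
    usage_a: float
    usage_b: float
    effect: float  # usage(stage B) - usage(stage A)
    p_value: float
    odds_ratio: float
    significant: bool
    p_adjusted: Optional[float] = None


def apa_contingency(
    profile: GenePASProfile,
    site: PolyASite,
    stage_a_samples: Sequence[str],
    stage_b_samples: Sequence[str],
) -> Optional[ContingencyTable2x2]:
    """Site-vs-rest 2x2 table with replicates pooled within each stage.

    Returns None for single-site genes (nothing to test) or when a stage has
    zero assigned reads for the gene.
    """
    if len(profile.sites) < 2:
        log.debug("gene %s: single site, no contingency table", profile.gene_id)
        return None

    def stage_counts(samples: Sequence[str]) -> Tuple[int, int]:
        site_n = sum(site.per_sample_counts.get(s, 0) for s in samples)
        total = sum(
            s2.per_sample_counts.get(s, 0) for s2 in profile.sites for s in samples
        )
        return site_n, total - site_n

    a, b = stage_counts(stage_a_samples)
    c, d = stage_counts(stage_b_samples)
    table = ContingencyTable2x2(a, b, c, d)
    if not table.testable:
        log.debug("gene %s site %d: zero reads in a stage, untestable",
                  profile.gene_id, site.position)
        return None
    return table


def fisher_exact(table: ContingencyTable2x2) -> Tuple[float, float]:
    """Two-sided Fisher exact p and sample odds ratio.

    The p-value sums hypergeometric probabilities of all margin-preserving
    tables whose probability does not exceed that of the observed table
    (within a 1+1e-7 relative slack for floating-point equality). Degenerate
    margins give p = 1.0 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if b * c == 0:
        odds = math.inf if a * d > 0 else (0.0 if a == 0 or d == 0 else 1.0)
    else:
        odds = (a * d) / (b * c)
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0, odds
    kmin = max(0, c1 - r2)
    kmax = min(c1, r1)
    ks = np.arange(kmin, kmax + 1)
    # hypergeometric log-pmf over the whole support in one vectorized shot
    log_pmf = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(log_pmf)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, p), odds


def benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    """BH-adjusted p-values (monotone step-up)."""
    m = len(p_values)
    if m == 0:
        return []
    order = np.argsort(p_values, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p_values[idx] * m / rank)
        adjusted[idx] = running
    return [float(x) for x in adjusted]


def stage_sample_map(sample_sheet: pd.DataFrame) -> Dict[str, List[str]]:
    """stage -> sample ids, stages in order of first appearance."""
    stages: Dict[str, List[str]] = {}
    for _, row in sample_sheet.iterrows():
        stages.setdefault(str(row["stage"]), []).append(str(row["sample_id"]))
    return stages


def proximal_distal_contingency(
    profile: GenePASProfile,
    stage_a_samples: Sequence[str],
    stage_b_samples: Sequence[str],
) -> Optional[ContingencyTable2x2]:
    """Alternative table: 5'-most vs 3'-most site, one test per gene."""
    if len(profile.sites) < 2:
        return None
    proximal, distal = profile.sites[0], profile.sites[-1]

    def counts(site: PolyASite, samples: Sequence[str]) -> int:
        return sum(site.per_sample_counts.get(s, 0) for s in samples)

    table = ContingencyTable2x2(
        counts(proximal, stage_a_samples), counts(distal, stage_a_samples),
        counts(proximal, stage_b_samples), counts(distal, stage_b_samples),
    )
    return table if table.testable else None


def differential_apa(
    profiles: Mapping[str, GenePASProfile],
    sample_sheet: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "site_vs_rest",
) -> List[DifferentialCall]:
    """One Fisher call per (testable unit, consecutive-stage comparison).

    ``sample_sheet`` needs columns sample_id and stage; stage order follows
    first appearance. With the default ``site_vs_rest`` mode each retained
    site is tested against the rest of its gene; ``proximal_vs_distal``
    tests the 5'-most against the 3'-most site once per gene. Effect =
    usage(stage B) - usage(stage A). BH-adjusted p-values are filled per
    comparison; ``significant`` uses the uncorrected p < alpha rule.
    """
    if mode not in ("site_vs_rest", "proximal_vs_distal"):
        raise ValueError(f"unknown differential mode {mode!r}")
    stages = stage_sample_map(sample_sheet)
    stage_names = list(stages)
    if len(stage_names) < 2:
        return []
    calls: List[DifferentialCall] = []
    for stage_a, stage_b in zip(stage_names, stage_names[1:]):
        comparison = f"{stage_a}vs{stage_b}"
        batch: List[DifferentialCall] = []
        for gene_id in sorted(profiles):
            profile = profiles[gene_id]
            if mode == "proximal_vs_distal":
                units = [(f"{gene_id}:proximal_vs_distal",
                          proximal_distal_contingency(
                              profile, stages[stage_a], stages[stage_b]))]
            else:
                units = [
                    (f"{gene_id}:{site.position}",
                     apa_contingency(profile, site, stages[stage_a], stages[stage_b]))
                    for site in profile.sites
                ]
            for unit_id, table in units:
                if table is None:
                    continue
                p, odds = fisher_exact(table)
                usage_a = table.a / (table.a + table.b)
                usage_b = table.c / (table.c + table.d)
                batch.append(
                    DifferentialCall(
                        unit_id=unit_id,
                        gene_id=gene_id,
                        comparison=comparison,
                        table=table,
                        usage_a=usage_a,
                        usage_b=usage_b,
                        effect=usage_b - usage_a,
                        p_value=p,
                        odds_ratio=odds,
                        significant=p < alpha,
                    )
                )
        adjusted = benjamini_hochberg([c.p_value for c in batch])
        for call, p_adj in zip(batch, adjusted):
            call.p_adjusted = p_adj
        calls.extend(batch)
    return calls


def calls_to_frame(calls: Sequence[DifferentialCall]) -> pd.DataFrame:
    rows = [
        {
            "unit_id": c.unit_id,
            "gene_id": c.gene_id,
            "comparison": c.comparison,
            "a": c.table.a,
            "b": c.table.b,
            "c": c.table.c,
            "d": c.table.d,
            "usage_a": c.usage_a,
            "usage_b": c.usage_b,
            "effect": c.effect,
            "odds_ratio": c.odds_ratio,
            "p_value": c.p_value,
            "p_adjusted": c.p_adjusted,
            "significant": c.significant,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)


def psi_permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Two-sided label-permutation test on the mean PSI difference.

    Returns (delta_psi = mean(B) - mean(A), p). When the number of distinct
    label arrangements is <= n_perm the null is enumerated exhaustively
    (exact p); otherwise Monte Carlo sampling with the add-one correction is
    used. Deterministic given ``seed``. NaN/None PSIs must be removed by the
    caller; empty groups are untestable.
    """
    a = [float(x) for x in group_a]
    b = [float(x) for x in group_b]
    if not a or not b:
        raise ValueError("both groups need at least one defined PSI")
    pooled = a + b
    n_a = len(a)
    observed = float(np.mean(b)) - float(np.mean(a))
    threshold = abs(observed) - 1e-12
    n_arrangements = math.comb(len(pooled), n_a)
    if n_arrangements <= n_perm:
        hits = 0
        for combo in itertools.combinations(range(len(pooled)), n_a):
            mask = set(combo)
            perm_a = [pooled[i] for i in mask]
            perm_b = [pooled[i] for i in range(len(pooled)) if i not in mask]
            delta = float(np.mean(perm_b)) - float(np.mean(perm_a))
            if abs(delta) >= threshold:
                hits += 1
        return observed, hits / n_arrangements
    rng = np.random.default_rng(seed)
    pooled_arr = np.asarray(pooled)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled_arr)
        delta = float(np.mean(perm[n_a:])) - float(np.mean(perm[:n_a]))
        if abs(delta) >= threshold:
            hits += 1
    return observed, (hits + 1) / (n_perm + 1)
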