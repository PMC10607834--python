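from collections import Counter

import numpy as np
import pytest

from conftest import make_gene
from isoapa.genome import CleavageRecord
from isoapa.pas import (
    GenePASProfile,
    build_all_profiles,
    build_profile,
    classify_apa_genes,
    cluster_cleavage_sites,
    collect_cleavage_counts,
    filter_by_usage,
    intron_length_comparison,
    locate_intronic_pas,
    normalize_abundance,
    read_site_table,
    select_major_site,
    write_site_table,
)
from isoapa.sim import simulate_cleavage_records
from oracle_utils import cluster_trace


def rec(position, gene="g1", sample="s", strand="+", chrom="chr1"):
    return CleavageRecord(chrom, position, strand, gene, sample)


class TestCollect:
    def test_basic(self):
        records = [rec(100), rec(100), rec(100)]
        counts, locations, n_un = collect_cleavage_counts(records)
        assert counts == {"g1": {100: Counter({"s": 3})}}
        assert locations["g1"] == ("chr1", "+")
        assert n_un == 0

    def test_empty(self):
        counts, _, n_un = collect_cleavage_counts([])
        assert counts == {} and n_un == 0

    def test_unassigned_tally(self):
        records = [rec(1, gene=None), rec(2)]
        counts, _, n_un = collect_cleavage_counts(records)
        assert n_un == 1
        assert set(counts) == {"g1"}

    def test_simulator_ledger_totals(self):
        records, ledger = simulate_cleavage_records(
            ["gA", "gB"], {"gA": [500, 600], "gB": [900]},
            {"gA": [0.5, 0.5], "gB": [1.0]}, n_reads=500, jitter_sd=3.0, seed=5,
        )
        counts, _, _ = collect_cleavage_counts(records)
        for gene in ("gA", "gB"):
            total = sum(sum(c.values()) for c in counts[gene].values())
            assert total == sum(ledger[gene].values()) == 500


class TestClustering:
    def test_hand_traced_example(self):
        sites, assign = cluster_cleavage_sites({100: 50, 105: 10, 160: 30})
        assert sites == [(100, 60), (160, 30)]
        assert assign == {100: 100, 105: 100, 160: 160}

    def test_separation_merge(self):
        sites, _ = cluster_cleavage_sites({100: 50, 125: 40})
        assert sites == [(100, 90)]

    def test_single_position(self):
        assert cluster_cleavage_sites({200: 7})[0] == [(200, 7)]

    def test_bad_config(self):
        with pytest.raises(ValueError):
            cluster_cleavage_sites({100: 1}, assignment_halfwidth=0)
        with pytest.raises(ValueError):
            cluster_cleavage_sites({100: 1}, min_separation=0)

    def test_exactly_30_apart_merged(self):
        # "more than 30 nt": distance exactly 30 is not allowed
        sites, _ = cluster_cleavage_sites({100: 50, 130: 40})
        assert sites == [(100, 90)]
        sites, _ = cluster_cleavage_sites({100: 50, 131: 40})
        assert sites == [(100, 50), (131, 40)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_trace_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            n = int(rng.integers(1, 21))
            positions = rng.choice(300, size=n, replace=False)
            counts = {int(p): int(rng.integers(1, 100)) for p in positions}
            got, _ = cluster_cleavage_sites(counts)
            assert got == cluster_trace(counts, 12, 30)

    def test_separation_invariant(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 20))
            positions = rng.choice(200, size=n, replace=False)
            counts = {int(p): int(rng.integers(1, 50)) for p in positions}
            sites, assign = cluster_cleavage_sites(counts)
            reps = [p for p, _ in sites]
            for i in range(len(reps)):
                for j in range(i + 1, len(reps)):
                    assert abs(reps[i] - reps[j]) > 30
            # read conservation
            assert sum(c for _, c in sites) == sum(counts.values())
            assert set(assign) == set(counts)


class TestUsageFilter:
    def _profile(self, pos_counts, strand="+"):
        psc = {p: Counter({"s": c}) for p, c in pos_counts.items()}
        return build_profile("g1", "chr1", strand, psc, ["s"])

    def test_strict_threshold(self):
        profile = self._profile({100: 96, 200: 4})
        out = filter_by_usage(profile)
        assert [s.position for s in out.sites] == [100]
        assert out.sites[0].usage == 1.0

    def test_single_site_retained(self):
        out = filter_by_usage(self._profile({100: 7}))
        assert len(out.sites) == 1 and out.sites[0].usage == 1.0

    def test_exact_five_percent_removed_and_renormalized(self):
        out = filter_by_usage(self._profile({100: 50, 150: 45, 200: 5}))
        assert [s.position for s in out.sites] == [100, 150]
        assert out.sites[0].usage == pytest.approx(50 / 95)
        assert out.sites[1].usage == pytest.approx(45 / 95)

    def test_all_below_threshold_drops_gene(self):
        # 21 positions, far apart, each < 5% usage
        counts = {i * 40: 1 for i in range(21)}
        profile = self._profile(counts)
        assert filter_by_usage(profile) is None


class TestMajorSite:
    def _profile(self, pos_counts, strand="+"):
        psc = {p: Counter({"s": c}) for p, c in pos_counts.items()}
        return build_profile("g1", "chr1", strand, psc, ["s"])

    def test_highest_count_major(self):
        profile = select_major_site(self._profile({100: 80, 200: 20}))
        assert profile.major_site.position == 100

    def test_tie_breaks_three_prime_most_plus(self):
        profile = select_major_site(self._profile({100: 50, 200: 50}))
        assert profile.major_site.position == 200

    def test_tie_breaks_three_prime_most_minus(self):
        profile = select_major_site(self._profile({100: 50, 200: 50}, strand="-"))
        assert profile.major_site.position == 100

    def test_single_site(self):
        assert select_major_site(self._profile({5: 1})).major_site.position == 5


class TestNormalization:
    def _profiles(self):
        psc = {100: Counter({"A": 10, "B": 10}), 200: Counter({"A": 30, "B": 30})}
        profile = select_major_site(build_profile("g1", "chr1", "+", psc, ["A", "B"]))
        return {"g1": profile}

    def test_equal_sizes_identity(self):
        profiles = self._profiles()
        normalize_abundance(profiles.values(), {"A": 100, "B": 100})
        site = profiles["g1"].sites[0]
        assert site.normalized_abundance == {"A": 10.0, "B": 10.0}

    def test_median_scaling(self):
        profiles = self._profiles()
        normalize_abundance(profiles.values(), {"A": 100, "B": 200})
        site = profiles["g1"].sites[0]
        assert site.normalized_abundance["A"] == pytest.approx(10 * 150 / 100)
        assert site.normalized_abundance["B"] == pytest.approx(10 * 150 / 200)

    def test_major_ratio(self):
        profiles = self._profiles()
        normalize_abundance(profiles.values(), {"A": 1, "B": 1})
        major = profiles["g1"].major_site
        assert major.major_ratio == 1.0
        other = [s for s in profiles["g1"].sites if not s.is_major][0]
        assert other.major_ratio == pytest.approx(20 / 60)

    def test_zero_library_size_error(self):
        with pytest.raises(ValueError):
            normalize_abundance(self._profiles().values(), {"A": 0, "B": 1})


class TestApaClassification:
    def test_partition(self):
        p1 = build_profile("g1", "chr1", "+", {100: Counter({"s": 5})}, ["s"])
        p2 = build_profile(
            "g2", "chr1", "+",
            {100: Counter({"s": 5}), 200: Counter({"s": 5}), 300: Counter({"s": 5})},
            ["s"],
        )
        out = classify_apa_genes([p1, p2])
        assert out["single_pas_genes"] == ["g1"]
        assert out["apa_genes"] == ["g2"]
        assert out["histogram"] == {1: 1, 3: 1}

    def test_recovered_apa_fraction(self):
        # 40% of 200 deep-coverage genes have 2 sites
        rng = np.random.default_rng(42)
        gene_ids = [f"g{i}" for i in range(200)]
        truth_apa = {g: rng.random() < 0.4 for g in gene_ids}
        pas = {g: [1000, 1200] if truth_apa[g] else [1000] for g in gene_ids}
        usages = {g: [0.5, 0.5] if truth_apa[g] else [1.0] for g in gene_ids}
        records, _ = simulate_cleavage_records(
            gene_ids, pas, usages, n_reads=300, jitter_sd=5.0, seed=7,
        )
        profiles, _ = build_all_profiles(records, ["sample"])
        called = classify_apa_genes(profiles.values())
        frac = len(called["apa_genes"]) / 200
        true_frac = sum(truth_apa.values()) / 200
        # binomial 95% CI around the planted fraction
        half = 1.96 * np.sqrt(0.4 * 0.6 / 200)
        assert abs(frac - true_frac) <= 0.02
        assert 0.4 - half <= frac <= 0.4 + half


class TestIntronic:
    def _genes(self):
        gene = make_gene(
            "g1", {"t1": [(0, 100), (200, 300), (5000, 5400)]}
        )
        return {"g1": gene}

    def _profile(self, positions):
        psc = {p: Counter({"s": 10}) for p in positions}
        return {"g1": build_profile("g1", "chr1", "+", psc, ["s"])}

    def test_downstream_not_intronic(self):
        profiles = self._profile([5899])
        locate_intronic_pas(profiles.values(), self._genes())
        assert not profiles["g1"].sites[0].is_intronic

    def test_inside_intron(self):
        profiles = self._profile([1000])
        out = locate_intronic_pas(profiles.values(), self._genes())
        assert profiles["g1"].sites[0].is_intronic
        assert len(out) == 1

    def test_random_against_membership_oracle(self, rng):
        genes = self._genes()
        introns = [(100, 200), (300, 5000)]
        positions = sorted(int(p) for p in rng.choice(5800, size=40, replace=False))
        profiles = self._profile(positions)
        locate_intronic_pas(profiles.values(), genes)
        for site in profiles["g1"].sites:
            expected = any(s <= site.position < e for s, e in introns)
            assert site.is_intronic == expected


class TestIntronLengthComparison:
    def test_pas_introns_longer(self):
        genes = {
            "g1": make_gene("g1", {"t": [(0, 100), (10100, 10200)]}),
            "g2": make_gene("g2", {"t": [(0, 100), (200, 300)]}),
        }
        profiles = {"g1": build_profile("g1", "chr1", "+", {5000: Counter({"s": 9})}, ["s"])}
        intronic = locate_intronic_pas(profiles.values(), genes)
        out = intron_length_comparison(genes, intronic)
        assert out.pas_median == 10000
        assert out.all_median == pytest.approx((10000 + 100) / 2)

    def test_empty_group_undefined(self):
        genes = {"g2": make_gene("g2", {"t": [(0, 100), (200, 300)]})}
        out = intron_length_comparison(genes, [])
        assert out.p_value is None
        assert out.pas_median is None

    def test_identical_groups_p_near_one(self):
        genes = {
            f"g{i}": make_gene(f"g{i}", {"t": [(0, 100), (200 + i, 300 + i)]})
            for i in range(10)
        }
        # every intron carries a PAS -> the two groups coincide
        profiles = {
            f"g{i}": build_profile(f"g{i}", "chr1", "+", {150: Counter({"s": 5})}, ["s"])
            for i in range(10)
        }
        intronic = locate_intronic_pas(profiles.values(), genes)
        out = intron_length_comparison(genes, intronic)
        assert out.p_value > 0.9


class TestStrandMirror:
    def test_profiles_mirror(self):
        counts = {100: 30, 150: 20, 400: 50}
        L = 1000
        psc_fwd = {p: Counter({"s": c}) for p, c in counts.items()}
        psc_rev = {L - 1 - p: Counter({"s": c}) for p, c in counts.items()}
        fwd = select_major_site(filter_by_usage(
            build_profile("g", "chr1", "+", psc_fwd, ["s"])
        ))
        rev = select_major_site(filter_by_usage(
            build_profile("g", "chr1", "-", psc_rev, ["s"])
        ))
        assert [L - 1 - s.position for s in rev.sites] == [s.position for s in fwd.sites]
        assert [s.usage for s in rev.sites] == [s.usage for s in fwd.sites]
        assert [s.is_major for s in rev.sites] == [s.is_major for s in fwd.sites]


class TestRecoveryProperty:
    def test_two_site_recovery(self):
        # 200 genes, 2 PAS >= 60 nt apart, usages .7/.3, jitter sd 5, 1000 reads
        gene_ids = [f"g{i}" for i in range(200)]
        pas = {g: [2000, 2080] for g in gene_ids}
        usages = {g: [0.3, 0.7] for g in gene_ids}
        records, _ = simulate_cleavage_records(
            gene_ids, pas, usages, n_reads=1000, jitter_sd=5.0, seed=11,
        )
        profiles, _ = build_all_profiles(records, ["sample"])
        ok = 0
        for g in gene_ids:
            sites = profiles[g].sites
            if len(sites) != 2:
                continue
            by_pos = sorted(sites, key=lambda s: s.position)
            if (
                abs(by_pos[0].position - 2000) <= 12
                and abs(by_pos[1].position - 2080) <= 12
                and abs(by_pos[0].usage - 0.3) <= 0.05
                and abs(by_pos[1].usage - 0.7) <= 0.05
            ):
                ok += 1
        assert ok >= 190  # >= 95% of genes


class TestSiteTableRoundTrip:
    def test_round_trip(self, tmp_path):
        records, _ = simulate_cleavage_records(
            ["g1", "g2"], {"g1": [500, 700], "g2": [900]},
            {"g1": [0.4, 0.6], "g2": [1.0]}, n_reads=200, jitter_sd=2.0, seed=3,
        )
        profiles, _ = build_all_profiles(records, ["sample"])
        normalize_abundance(profiles.values(), {"sample": 400})
        path = tmp_path / "sites.tsv"
        write_site_table(profiles, path)
        again = read_site_table(path)
        assert set(again) == set(profiles)
        for g in profiles:
            orig, back = profiles[g], again[g]
            assert [s.position for s in orig.sites] == [s.position for s in back.sites]
            assert [s.raw_count for s in orig.sites] == [s.raw_count for s in back.sites]
            assert [s.is_major for s in orig.sites] == [s.is_major for s in back.sites]
            assert back.total_assigned == orig.total_assigned
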