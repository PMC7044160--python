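"""Permutation, hypergeometric, binomial and chromHMM enrichment statistics."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from helpers import random_interval_set
from silencerscan.enrich import (
    PermutationResult,
    Segmentation,
    binomial_overlap_enrichment,
    chromhmm_distribution,
    expand_ld,
    hypergeom_trait_enrichment,
    permutation_overlap_test,
    read_segmentation,
    snps_to_intervals,
)
from silencerscan.intervals import GenomicInterval, IntervalSet


def iv(s, e, chrom="chr1", **kw):
    return GenomicInterval(chrom, s, e, **kw)


class TestPermutationTest:
    def test_p_floor_and_ceiling(self):
        res = PermutationResult(observed_overlap=5, null_overlaps=np.zeros(10_000, int), N=10_000)
        assert res.sum_n == 0
        assert res.p == pytest.approx(1 / 10_001)
        res = PermutationResult(observed_overlap=0, null_overlaps=np.ones(10_000, int), N=10_000)
        assert res.sum_n == 10_000 and res.p == 1.0

    def test_universe_smaller_than_target_rejected(self):
        t = IntervalSet([iv(0, 10), iv(20, 30)])
        with pytest.raises(ValueError):
            permutation_overlap_test(t, IntervalSet([iv(0, 10)]), t, N=10)

    def test_monotone_in_observed_overlap(self, rng):
        null = rng.integers(0, 10, size=500)
        ps = [
            PermutationResult(obs, null, 500).p for obs in range(0, 11)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_within_3se_of_exhaustive_enumeration(self):
        # universe of 6 records, 3 of which hit the feature; target draws 2
        universe = IntervalSet([iv(i * 100, i * 100 + 50, name=f"u{i}") for i in range(6)])
        features = IntervalSet([iv(i * 100, i * 100 + 10) for i in range(3)])
        target = IntervalSet([iv(0, 50), iv(100, 150)])  # observed = 2
        res = permutation_overlap_test(target, universe, features, N=4000, seed=5)
        # exact: P(null > 2) over all C(6,2)=15 subsets; max null count is 2
        exact_exceed = (
            sum(
                1
                for pair in combinations(range(6), 2)
                if sum(1 for j in pair if j < 3) > 2
            )
            / 15
        )
        se = np.sqrt(max(exact_exceed * (1 - exact_exceed), 1e-9) / 4000)
        assert abs(res.sum_n / res.N - exact_exceed) <= 3 * se + 1e-12
        assert res.observed_overlap == 2

    def test_seed_reproducibility(self, rng):
        universe = random_interval_set(rng, 40)
        features = random_interval_set(rng, 10, label="f")
        target = IntervalSet(universe[:5])
        r1 = permutation_overlap_test(target, universe, features, N=200, seed=9)
        r2 = permutation_overlap_test(target, universe, features, N=200, seed=9)
        np.testing.assert_array_equal(r1.null_overlaps, r2.null_overlaps)


class TestExpandLd:
    def leads(self):
        return pd.DataFrame(
            {"snp_id": ["L1"], "chrom": ["chr1"], "pos": [1000], "trait": ["t"]}
        )

    def test_threshold_filters_proxies(self):
        proxies = pd.DataFrame(
            {
                "lead_id": ["L1", "L1"],
                "proxy_id": ["P1", "P2"],
                "proxy_chrom": ["chr1", "chr1"],
                "proxy_pos": [1100, 1200],
                "r2": [0.9, 0.7],
            }
        )
        out = expand_ld(self.leads(), proxies)
        assert sorted(out["snp_id"]) == ["L1", "P1"]
        assert out.loc[out["snp_id"] == "P1", "trait"].item() == "t"

    def test_no_proxy_table_returns_leads(self):
        out = expand_ld(self.leads(), None)
        assert out["snp_id"].tolist() == ["L1"] and out["is_lead"].all()

    def test_unknown_lead_skipped_with_warning(self):
        proxies = pd.DataFrame(
            {
                "lead_id": ["LX"], "proxy_id": ["P1"], "proxy_chrom": ["chr1"],
                "proxy_pos": [1100], "r2": [0.95],
            }
        )
        with pytest.warns(UserWarning):
            out = expand_ld(self.leads(), proxies)
        assert out["snp_id"].tolist() == ["L1"]

    def test_shared_proxy_appears_once_per_trait(self):
        leads = pd.DataFrame(
            {
                "snp_id": ["L1", "L2"],
                "chrom": ["chr1"] * 2,
                "pos": [1000, 5000],
                "trait": ["t1", "t2"],
            }
        )
        proxies = pd.DataFrame(
            {
                "lead_id": ["L1", "L2"],
                "proxy_id": ["P", "P"],
                "proxy_chrom": ["chr1"] * 2,
                "proxy_pos": [3000, 3000],
                "r2": [0.9, 0.85],
            }
        )
        out = expand_ld(leads, proxies)
        p_rows = out[out["snp_id"] == "P"]
        assert sorted(p_rows["trait"]) == ["t1", "t2"]
        assert len(out) == 4


class TestHypergeomEnrichment:
    def test_exact_summation_example(self):
        # M=20, K=5, n=8, k=4: p = [C(5,4)C(15,4) + C(5,5)C(15,3)] / C(20,8)
        snps = []
        for i in range(20):
            trait = "t" if i < 5 else "other"
            snps.append((f"s{i}", "chr1", 10 + i * 100, trait))
        snps = pd.DataFrame(snps, columns=["snp_id", "chrom", "pos", "trait"])
        # silencers covering 4 trait SNPs and 4 others (n=8)
        cover = [0, 1, 2, 3, 5, 6, 7, 8]
        sil = IntervalSet([iv(10 + i * 100, 20 + i * 100) for i in cover])
        tab = hypergeom_trait_enrichment(snps, {"c": sil})
        p = tab.set_index("trait").loc["t", "p"]
        expected = (comb(5, 4) * comb(15, 4) + comb(5, 5) * comb(15, 3)) / comb(20, 8)
        assert p == pytest.approx(expected)
        row = tab.set_index("trait").loc["t"]
        assert (row["k"], row["n"], row["K"], row["M"]) == (4, 8, 5, 20)

    def test_zero_hits_gives_p_one(self):
        snps = pd.DataFrame(
            {"snp_id": ["a", "b"], "chrom": ["chr1"] * 2, "pos": [10, 20],
             "trait": ["t", "u"]}
        )
        sil = IntervalSet([iv(5000, 6000)])
        tab = hypergeom_trait_enrichment(snps, {"c": sil})
        assert (tab["p"] == 1.0).all()

    def test_degenerate_full_universe(self):
        snps = pd.DataFrame(
            {"snp_id": ["a", "b"], "chrom": ["chr1"] * 2, "pos": [10, 20],
             "trait": ["t", "t"]}
        )
        sil = IntervalSet([iv(0, 100)])
        tab = hypergeom_trait_enrichment(snps, {"c": sil})
        assert tab["p"].iloc[0] == pytest.approx(1.0)

    def test_per_cell_scope_bh(self):
        snps = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(10)], "chrom": ["chr1"] * 10,
             "pos": np.arange(10) * 100 + 10,
             "trait": ["t1"] * 5 + ["t2"] * 5}
        )
        sil = IntervalSet([iv(0, 250)])
        g = hypergeom_trait_enrichment(snps, {"a": sil, "b": sil}, scope="global")
        pc = hypergeom_trait_enrichment(snps, {"a": sil, "b": sil}, scope="per_cell")
        assert set(g.columns) == set(pc.columns)
        assert len(g) == 4


class TestBinomialEnrichment:
    def test_matches_exact_pmf_summation(self):
        from math import comb as C

        k, n, rate = 10, 100, 0.05
        exact = sum(C(n, j) * rate**j * (1 - rate) ** (n - j) for j in range(k, n + 1))
        assert binomial_overlap_enrichment(k, n, rate) == pytest.approx(exact)

    @pytest.mark.parametrize(
        "k,n,rate,expected",
        [(0, 50, 0.3, 1.0), (7, 10, 1.0, 1.0), (3, 10, 0.0, 0.0), (0, 10, 0.0, 1.0)],
    )
    def test_edge_cases(self, k, n, rate, expected):
        assert binomial_overlap_enrichment(k, n, rate) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_overlap_enrichment(11, 10, 0.5)


class TestChromhmmDistribution:
    def make_seg(self):
        return Segmentation(
            [
                iv(0, 1000, name="Quies"),
                iv(1000, 2000, name="TxWk"),
                iv(2000, 3000, name="Het"),
            ]
        )

    def test_single_state_block(self):
        seg = self.make_seg()
        els = IntervalSet([iv(10, 50, name="a"), iv(500, 900, name="b")])
        res = chromhmm_distribution(els, seg)
        assert res.fractions.to_dict() == {"Quies": 1.0}

    def test_majority_rule_and_canonical_tie_break(self):
        seg = self.make_seg()
        # 60/40 split between TxWk and Het -> TxWk
        res = chromhmm_distribution(IntervalSet([iv(1400, 2400, name="x")]), seg)
        assert res.assignments["x"] == "TxWk"
        # exact 50/50 tie: TxWk precedes Het in the canonical ordering
        res = chromhmm_distribution(IntervalSet([iv(1500, 2500, name="y")]), seg)
        assert res.assignments["y"] == "TxWk"

    def test_uncovered_element_is_na(self):
        res = chromhmm_distribution(IntervalSet([iv(5000, 5100, name="z")]), self.make_seg())
        assert res.n_na == 1 and len(res.fractions) == 0

    def test_fractions_sum_to_one_and_match_bruteforce(self, rng):
        states = ["Quies", "TxWk", "Het", "Enh", "TssA"]
        blocks = [
            iv(i * 500, (i + 1) * 500, name=states[i % 5]) for i in range(40)
        ]
        seg = Segmentation(blocks)
        els = random_interval_set(rng, 60, chrom_len=20_000)
        res = chromhmm_distribution(els, seg)
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        # brute-force per-element max-overlap scan
        for el, got in zip(els, res.assignments):
            best, best_bp = "NA", 0
            for b in blocks:
                ov = el.overlap_bp(b)
                rank = Segmentation([b]).state_rank(b.name)
                if ov > best_bp:
                    best, best_bp = b.name, ov
                elif ov == best_bp and ov > 0 and seg.state_rank(b.name) < seg.state_rank(best):
                    best = b.name
            assert got == best

    def test_baseline_mean_fractions(self, rng):
        seg = self.make_seg()
        universe = IntervalSet(
            [iv(i * 30, i * 30 + 20, name=f"u{i}") for i in range(90)]
        )
        els = IntervalSet(universe[:10])
        res = chromhmm_distribution(els, seg, baseline_universe=universe, B=50, seed=3)
        assert res.baseline_fractions is not None
        assert res.baseline_fractions.sum() == pytest.approx(1.0, abs=1e-6)

    def test_overlapping_segmentation_rejected(self):
        with pytest.raises(ValueError):
            Segmentation([iv(0, 100, name="Quies"), iv(50, 150, name="Het")])

    def test_empty_segmentation_rejected(self):
        with pytest.raises(ValueError):
            chromhmm_distribution(IntervalSet([iv(0, 10)]), Segmentation([]))


def test_segmentation_round_trip(tmp_path, small_bundle):
    from silencerscan.intervals import write_bed

    seg = small_bundle.segmentation_by_cell["cell_0"]
    path = tmp_path / "seg.bed"
    write_bed(seg, path)
    loaded = read_segmentation(path)
    assert list(loaded) == list(seg)


def test_snps_to_intervals_point_membership():
    snps = pd.DataFrame(
        {"snp_id": ["a", "b"], "chrom": ["chr1"] * 2, "pos": [99, 100], "trait": ["t"] * 2}
    )
    pts = snps_to_intervals(snps)
    # half-open membership: position 99 is inside [0,100), position 100 is not
    region = IntervalSet([iv(0, 100)])
    from silencerscan.intervals import overlapping_mask

    assert overlapping_mask(pts, region).tolist() == [True, False]
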