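"""Median-rank permutation machinery."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from neurovuln import enrichment, pls


def make_ranked(n, genes=None):
    genes = genes or [f"g{i}" for i in range(n)]
    table = pd.DataFrame(
        {
            "gene": genes,
            "weight": np.linspace(1, -1, n),
            "rank": np.arange(1, n + 1),
            "centered_rank": np.arange(1, n + 1) - (n + 1) / 2.0,
        }
    )
    return pls.RankedGeneList(table)


class TestMedianRank:
    def test_full_list_is_zero(self):
        ranked = make_ranked(11)
        assert enrichment.median_rank(ranked, ranked.genes) == 0.0

    def test_even_set_midpoint(self):
        ranked = make_ranked(10)
        # ranks 1, 2 -> centered -4.5, -3.5 -> median -4.0
        assert enrichment.median_rank(ranked, ["g0", "g1"]) == -4.0

    def test_matches_numpy_median(self, rng):
        ranked = make_ranked(50)
        members = list(rng.choice(ranked.genes, size=7, replace=False))
        expected = np.median(ranked.centered_ranks(members))
        assert enrichment.median_rank(ranked, members) == expected

    def test_empty_intersection_lists_missing(self):
        ranked = make_ranked(10)
        with pytest.raises(ValueError, match="absent|missing"):
            enrichment.median_rank(ranked, ["nope1", "nope2"])


class TestPRandTrans:
    def test_exhaustive_minimum_median(self):
        """N=6, k=2: the minimum possible median has exact p = 1/15."""
        ranked = make_ranked(6)
        observed = enrichment.median_rank(ranked, ["g0", "g1"])
        res = enrichment.p_rand_trans(
            ranked, 2, observed, direction="low", exhaustive=True
        )
        assert res.p == pytest.approx(1 / 15)
        assert res.n_perm == 15

    def test_exhaustive_matches_enumeration(self, rng):
        ranked = make_ranked(9)
        members = ["g2", "g5", "g8"]
        observed = enrichment.median_rank(ranked, members)
        res = enrichment.p_rand_trans(
            ranked, 3, observed, direction="high", exhaustive=True
        )
        pool = ranked.centered_ranks()
        null = [np.median(c) for c in combinations(pool, 3)]
        expected = sum(v >= observed for v in null) / len(null)
        assert res.p == expected

    def test_extreme_observed_attains_floor(self):
        ranked = make_ranked(100)
        res = enrichment.p_rand_trans(
            ranked, 5, observed=47.0, direction="high", n_perm=500, seed=1
        )
        assert res.p == res.floor

    def test_direction_required(self):
        ranked = make_ranked(20)
        with pytest.raises(ValueError, match="direction"):
            enrichment.p_rand_trans(ranked, 3, 0.0, direction=None)

    def test_null_p_approximately_uniform(self, rng):
        """Under random sets the p distribution is ~uniform on its support."""
        ranked = make_ranked(300)
        ps = []
        for i in range(300):
            members = list(rng.choice(ranked.genes, size=10, replace=False))
            obs = enrichment.median_rank(ranked, members)
            ps.append(
                enrichment.p_rand_trans(
                    ranked, 10, obs, "high", n_perm=200, seed=1000 + i
                ).p
            )
        ps = np.asarray(ps)
        assert 0.40 < np.mean(ps < 0.5) < 0.60
        assert 0.05 < np.mean(ps < 0.1) < 0.16


class TestPRandCis:
    def test_whole_genome_chromosome_reduces_to_trans(self):
        ranked = make_ranked(50)
        a = enrichment.p_rand_trans(ranked, 5, -10.0, "low", n_perm=200, seed=3)
        b = enrichment.p_rand_cis(ranked, ranked.genes, 5, -10.0, "low", n_perm=200, seed=3)
        np.testing.assert_allclose(a.null_sample, b.null_sample)

    def test_full_chromosome_set_degenerate(self):
        ranked = make_ranked(50)
        chrom = ranked.genes[:10]
        with pytest.raises(ValueError, match="smaller"):
            enrichment.p_rand_cis(ranked, chrom, 10, 0.0, "low")

    def test_cis_null_harder_on_gradient_chromosome(self):
        """When the whole chromosome is shifted, cis resampling absorbs the
        shift and yields a larger p than genome-wide resampling."""
        ranked = make_ranked(200)
        chrom = ranked.genes[:40]  # chromosome occupying the extreme low ranks
        cnv = chrom[5:15]  # extreme genome-wide, mid-pack within chromosome
        obs = enrichment.median_rank(ranked, cnv)
        p_trans = enrichment.p_rand_trans(ranked, 10, obs, "low", 2000, seed=5).p
        p_cis = enrichment.p_rand_cis(ranked, chrom, 10, obs, "low", 2000, seed=5).p
        assert p_cis > p_trans


class TestChromosomeProfile:
    def _annotations(self, ranked, n_chrom=5):
        return pd.DataFrame(
            {
                "gene": ranked.genes,
                "chromosome": [str(i % n_chrom + 1) for i in range(ranked.n)],
            }
        )

    def test_single_chromosome_median_zero(self):
        ranked = make_ranked(21)
        ann = pd.DataFrame({"gene": ranked.genes, "chromosome": "1"})
        out = enrichment.chromosome_rank_profile(ranked, ann, seed=0)
        assert len(out) == 1
        assert out.loc[0, "median_centered_rank"] == 0.0

    def test_bootstrap_se_nonnegative(self):
        ranked = make_ranked(60)
        out = enrichment.chromosome_rank_profile(
            ranked, self._annotations(ranked), seed=0
        )
        assert (out["se"] >= 0).all()

    def test_planted_extreme_chromosome_has_max_median(self):
        ranked = make_ranked(100)
        ann = self._annotations(ranked)
        ann.loc[ann.index[-20:], "chromosome"] = "99"  # bottom ranks
        ranked2 = make_ranked(100)
        out = enrichment.chromosome_rank_profile(ranked2, ann, seed=0)
        best = out.loc[out["median_centered_rank"].idxmax(), "chromosome"]
        assert best == "99"


class TestMostExtremeChromosome:
    def test_two_chromosomes_symmetric_null(self, rng):
        ps = []
        for i in range(20):
            genes = [f"g{j}" for j in range(40)]
            order = rng.permutation(40)
            ranked = make_ranked(40, genes=[genes[j] for j in order])
            ann = pd.DataFrame({"gene": genes, "chromosome": ["1", "2"] * 20})
            ps.append(
                enrichment.p_most_extreme_chromosome(
                    ranked, ann, "1", "high", n_perm=300, seed=i
                ).p
            )
        assert 0.2 < np.mean(ps) < 0.55

    def test_planted_gain_small_p(self):
        ranked = make_ranked(200)
        ann = pd.DataFrame(
            {
                "gene": ranked.genes,
                "chromosome": ["T" if i >= 180 else str(i % 10) for i in range(200)],
            }
        )
        res = enrichment.p_most_extreme_chromosome(
            ranked, ann, "T", "high", n_perm=500, seed=2
        )
        assert res.p <= 0.01
        assert res.meta["observed_extreme"]

    def test_floor_respected(self):
        ranked = make_ranked(50)
        ann = pd.DataFrame(
            {"gene": ranked.genes, "chromosome": [str(i % 5) for i in range(50)]}
        )
        res = enrichment.p_most_extreme_chromosome(
            ranked, ann, "0", "high", n_perm=100, seed=0
        )
        assert res.p >= 1 / 101

    def test_missing_target_raises(self):
        ranked = make_ranked(20)
        ann = pd.DataFrame({"gene": ranked.genes, "chromosome": "1"})
        with pytest.raises(ValueError):
            enrichment.p_most_extreme_chromosome(ranked, ann, "Z", "high")


class TestOmnibus:
    def _result(self, observed, null, direction="high"):
        from neurovuln._stats import permutation_result

        return permutation_result("median_centered_rank", observed, null, direction)

    def test_all_p_one_gives_one(self, rng):
        null = np.abs(rng.standard_normal(200)) + 10
        res = [self._result(0.0, null), self._result(0.0, null)]
        assert enrichment.omnibus_p(res) == 1.0

    def test_floor_when_all_at_floor(self, rng):
        null = -np.abs(rng.standard_normal(200))
        res = [self._result(10.0, null), self._result(10.0, null)]
        assert enrichment.omnibus_p(res) == pytest.approx(1 / 201)

    def test_independent_uniform_product(self, rng):
        """For independent null columns the omnibus is ~ the product."""
        vals = []
        for i in range(50):
            r1 = self._result(1.0, rng.standard_normal(400))
            r2 = self._result(1.0, rng.standard_normal(400))
            vals.append(enrichment.omnibus_p([r1, r2]))
        expected = (1 - 0.8413) ** 2  # P(Z>=1)^2
        assert np.mean(vals) == pytest.approx(expected, rel=0.35)


class TestDsNds:
    def test_exchangeable_difference_centered(self, rng):
        ranked = make_ranked(100)
        obs = []
        for i in range(50):
            members = rng.choice(ranked.genes, size=20, replace=False)
            res = enrichment.ds_nds_median_test(
                ranked, list(members[:10]), list(members[10:]), n_perm=50, seed=i
            )
            obs.append(res.observed)
        assert abs(np.mean(obs)) < 8  # null-centered on a +/-49.5 scale

    def test_top_block_maximal_difference(self):
        ranked = make_ranked(40)
        ds = ranked.genes[:5]
        nds = ranked.genes[5:]
        res = enrichment.ds_nds_median_test(ranked, ds, nds, n_perm=200, seed=0)
        pool = ranked.centered_ranks(ds + nds)
        max_diff = np.median(np.sort(pool)[:5]) - np.median(np.sort(pool)[5:])
        assert res.observed == max_diff

    def test_matches_exhaustive_enumeration(self, rng):
        ranked = make_ranked(9)
        ds, nds = ranked.genes[:3], ranked.genes[3:7]
        res = enrichment.ds_nds_median_test(ranked, ds, nds, n_perm=4000, seed=7)
        pool = ranked.centered_ranks(ds + nds)
        diffs = []
        for idx in combinations(range(7), 3):
            a = pool[list(idx)]
            b = pool[[i for i in range(7) if i not in idx]]
            diffs.append(np.median(a) - np.median(b))
        exact = np.mean(np.abs(diffs) >= abs(res.observed))
        assert res.p == pytest.approx(exact, abs=3 * np.sqrt(exact / 4000) + 1e-3)

    def test_overlap_raises(self):
        ranked = make_ranked(10)
        with pytest.raises(ValueError, match="overlap"):
            enrichment.ds_nds_median_test(ranked, ["g1"], ["g1", "g2"])


class TestDecileEnrichment:
    def test_identical_composition_zero_difference(self):
        ranked = make_ranked(40)
        ds = ["g0", "g10", "g20", "g30"]
        nds = ["g1", "g11", "g21", "g31"]  # same decile occupancy
        out = enrichment.decile_enrichment(ranked, ds, nds, n_perm=50, seed=0)
        np.testing.assert_allclose(out.table["difference"], 0.0, atol=1e-12)

    def test_proportions_sum_to_one(self, rng):
        ranked = make_ranked(80)
        members = rng.choice(ranked.genes, size=24, replace=False)
        out = enrichment.decile_enrichment(
            ranked, list(members[:12]), list(members[12:]), n_perm=50, seed=0
        )
        assert out.table["proportion_ds"].sum() == pytest.approx(1.0, abs=1e-12)
        assert out.table["proportion_nds"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_planted_extreme_subset_flags_only_its_decile(self):
        ranked = make_ranked(200)
        ds = ranked.genes[:6] + ranked.genes[90:96]  # 6 extreme + 6 mid
        nds = ranked.genes[100:130]
        out = enrichment.decile_enrichment(ranked, ds, nds, n_perm=2000, seed=3)
        assert 1 in out.significant_deciles()
        assert 10 not in out.significant_deciles()


class TestExtractDsss:
    def test_members_from_significant_deciles(self):
        ranked = make_ranked(100)
        table = pd.DataFrame(
            {
                "decile": np.arange(1, 11),
                "proportion_ds": 0.1,
                "proportion_nds": 0.1,
                "difference": 0.0,
                "p": [0.01] + [0.8] * 9,
            }
        )
        ds = ["g0", "g5", "g9", "g50"]  # first three in decile 1
        out = enrichment.extract_dsss(enrichment.DecileTable(table), ds, ranked)
        assert out == ["g0", "g5", "g9"]

    def test_subset_of_ds(self, rng):
        ranked = make_ranked(60)
        ds = list(rng.choice(ranked.genes, size=12, replace=False))
        nds = [g for g in ranked.genes if g not in ds][:12]
        table = enrichment.decile_enrichment(ranked, ds, nds, n_perm=100, seed=0)
        out = enrichment.extract_dsss(table, ds, ranked)
        assert set(out) <= set(ds)

    def test_no_significant_decile_warns_empty(self):
        ranked = make_ranked(50)
        table = pd.DataFrame(
            {
                "decile": np.arange(1, 11),
                "proportion_ds": 0.1,
                "proportion_nds": 0.1,
                "difference": 0.0,
                "p": 0.9,
            }
        )
        with pytest.warns(UserWarning, match="DS\\^SS"):
            out = enrichment.extract_dsss(
                enrichment.DecileTable(table), ["g1"], ranked
            )
        assert out == []


class TestSetSizeSensitivity:
    def test_full_size_reduces_to_single_set(self):
        ranked = make_ranked(100)
        donor = ranked.genes[:10]
        out = enrichment.set_size_sensitivity(
            ranked, donor, sizes=[10], direction="low", n_draws=300, seed=1
        )
        assert out.loc[0, "observed_median_of_medians"] == enrichment.median_rank(
            ranked, donor
        )

    def test_p_nonincreasing_on_planted_monotone_fixture(self):
        ranked = make_ranked(400)
        donor = ranked.genes[:40]  # uniformly extreme
        out = enrichment.set_size_sensitivity(
            ranked, donor, sizes=[3, 10, 25, 40], direction="low",
            n_draws=1500, seed=4,
        )
        ps = out["p"].to_numpy()
        assert np.all(np.diff(ps) <= 1e-12)

    def test_floor_and_size_bounds(self):
        ranked = make_ranked(50)
        donor = ranked.genes[:8]
        out = enrichment.set_size_sensitivity(
            ranked, donor, sizes=[2, 8], direction="low", n_draws=100, seed=0
        )
        assert (out["p"] >= 1 / 101).all()
        with pytest.raises(ValueError):
            enrichment.set_size_sensitivity(
                ranked, donor, sizes=[0], direction="low"
            )


def test_permutation_floor_invariant(rng):
    ranked = make_ranked(200)
    res = enrichment.p_rand_trans(ranked, 10, 99.0, "high", n_perm=250, seed=0)
    assert res.p >= 1 / 251
    assert res.p == (1 + np.sum(res.null_sample >= 99.0)) / 251
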