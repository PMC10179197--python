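import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from complexshare import (
    PermutationConfig,
    RankedSamples,
    enrichment_score,
    exhaustive_null,
    fdr_over_tissues,
    nes_and_pvalue,
    permutation_null,
    rank_samples,
    run_enrichment,
)
from complexshare.enrichment import EnrichmentWarning, running_sum


def ranking_from(stats):
    ids = tuple(f"s{i}" for i in range(len(stats)))
    return RankedSamples(samples=ids, statistics=np.array(stats, dtype=float))


class TestRankSamples:
    def test_descending_order(self):
        shares = pd.DataFrame({"s1": [0.5], "s2": [0.2], "s3": [0.9]}, index=["g"])
        ranked = rank_samples(shares, "g")
        assert ranked.samples == ("s3", "s1", "s2")

    def test_ties_broken_by_ascending_id(self):
        shares = pd.DataFrame({"b": [0.5], "a": [0.5], "c": [0.5]}, index=["g"])
        assert rank_samples(shares, "g").samples == ("a", "b", "c")

    def test_single_sample(self):
        shares = pd.DataFrame({"s1": [0.5]}, index=["g"])
        assert rank_samples(shares, "g").samples == ("s1",)

    def test_absent_gene_rejected(self):
        with pytest.raises(KeyError):
            rank_samples(pd.DataFrame({"s1": [0.5]}, index=["g"]), "nope")


class TestEnrichmentScore:
    def test_worked_instance_running_sum(self, worked_ranking):
        es, profile = enrichment_score(worked_ranking, {"s1", "s2"})
        np.testing.assert_allclose(profile, [4 / 7, 1.0, 0.5, 0.0])
        assert es == 1.0

    def test_worked_instance_mirror(self, worked_ranking):
        es, _ = enrichment_score(worked_ranking, {"s3", "s4"})
        assert es == -1.0

    def test_unweighted_top_half_is_one(self):
        # exponent 0 with equal statistics: classic KS; the top half scores 1
        ranked = ranking_from([1.0] * 6)
        es, _ = enrichment_score(ranked, {"s0", "s1", "s2"}, weight_exponent=0.0)
        assert es == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "bad_set", [set(), {"s0", "s1", "s2", "s3"}, {"s0", "zz"}]
    )
    def test_invalid_sets_rejected(self, bad_set):
        ranked = ranking_from([4.0, 3.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            enrichment_score(ranked, bad_set)

    def test_all_zero_statistics_fall_back_to_unweighted(self):
        ranked = ranking_from([0.0, 0.0, 0.0, 0.0])
        es, _ = enrichment_score(ranked, {"s0", "s1"})
        unweighted, _ = enrichment_score(ranked, {"s0", "s1"}, weight_exponent=0.0)
        assert es == unweighted == pytest.approx(1.0)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    stats=st.lists(st.floats(0, 1e3), min_size=3, max_size=12),
    data=st.data(),
    exponent=st.sampled_from([0.0, 1.0, 1.5]),
)
def test_walk_bounds_and_conservation(stats, data, exponent):
    """ES is always in [-1, 1] and the weighted KS walk ends exactly at 0."""
    n = len(stats)
    k = data.draw(st.integers(1, n - 1))
    positions = data.draw(
        st.lists(st.integers(0, n - 1), min_size=k, max_size=k, unique=True)
    )
    ranked = ranking_from(sorted(stats, reverse=True))
    member_set = {ranked.samples[i] for i in positions}
    es, profile = enrichment_score(ranked, member_set, exponent)
    assert -1.0 <= es <= 1.0
    assert abs(profile[-1]) < 1e-9
    oracle_es, oracle_walk = oracles.walk_es(
        list(ranked.statistics), positions, exponent
    )
    np.testing.assert_allclose(profile, oracle_walk, atol=1e-12)
    assert es == pytest.approx(oracle_es, abs=1e-12)


class TestExhaustiveNull:
    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        stats = sorted(rng.integers(0, 10, size=n).astype(float), reverse=True)
        ranked = ranking_from(stats)
        for k in range(1, n):
            null = exhaustive_null(ranked, k)
            oracle = oracles.enumerate_null(stats, k)
            np.testing.assert_allclose(null, oracle, atol=1e-12)

    def test_worked_instance_null_set(self, worked_ranking):
        null = sorted(exhaustive_null(worked_ranking, 2))
        np.testing.assert_allclose(null, [-1.0, -0.5, 0.5, 2 / 3, 0.8, 1.0], atol=1e-12)


class TestPermutationNull:
    def test_auto_exhaustive_gives_all_subset_scores(self, worked_ranking):
        config = PermutationConfig(n_permutations=100, seed=1)
        null = permutation_null(worked_ranking, 2, config)
        assert len(null) == math.comb(4, 2)
        np.testing.assert_allclose(sorted(null), sorted(exhaustive_null(worked_ranking, 2)))

    def test_seeded_sampling_is_reproducible(self):
        ranked = ranking_from(np.linspace(10, 1, 12))
        config = PermutationConfig(n_permutations=500, seed=42, exhaustive=False)
        a = permutation_null(ranked, 4, config)
        b = permutation_null(ranked, 4, config)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 500

    def test_set_size_n_minus_one_valid(self):
        ranked = ranking_from([5.0, 4.0, 3.0, 2.0])
        null = permutation_null(ranked, 3, PermutationConfig(n_permutations=100))
        assert np.isfinite(null).all()

    @pytest.mark.parametrize("k", [0, 4])
    def test_out_of_range_set_size_rejected(self, worked_ranking, k):
        with pytest.raises(ValueError):
            permutation_null(worked_ranking, k, PermutationConfig())

    def test_sampled_null_converges_to_exhaustive_distribution(self):
        # N=7, k=3: sampled tail fraction within 3 MC SE of the enumerated one
        stats = [9.0, 7.0, 5.0, 4.0, 2.0, 1.0, 1.0]
        ranked = ranking_from(stats)
        exh = np.array(oracles.enumerate_null(stats, 3))
        config = PermutationConfig(n_permutations=10_000, seed=7, exhaustive=False)
        sampled = permutation_null(ranked, 3, config)
        es = float(exh.max())
        m = int((sampled > 0).sum())
        p_sampled_tail = float((np.abs(sampled[sampled > 0]) >= es).sum()) / m
        p_exh_tail = float((np.abs(exh[exh > 0]) >= es).sum()) / (exh > 0).sum()
        se = math.sqrt(p_exh_tail * (1 - p_exh_tail) / m) or 1 / m
        assert abs(p_sampled_tail - p_exh_tail) <= 3 * se + 1e-12


class TestNesAndPvalue:
    def test_worked_instance_pvalue(self, worked_ranking):
        # frozen from the enumeration oracle: positive null {1.0, 0.8, 2/3, 0.5}
        es, _ = enrichment_score(worked_ranking, {"s1", "s2"})
        null = exhaustive_null(worked_ranking, 2)
        nes, pvalue = nes_and_pvalue(es, null)
        oracle_p = oracles.pvalue_same_sign(es, list(null))
        assert pvalue == oracle_p == pytest.approx(0.4)

    def test_symmetric_null_gives_unit_nes(self):
        nes, _ = nes_and_pvalue(0.5, np.array([0.5, -0.5, 0.5, -0.5]))
        assert nes == pytest.approx(1.0)

    def test_zero_es_maps_to_zero_and_one(self):
        assert nes_and_pvalue(0.0, np.array([0.1, -0.2])) == (0.0, 1.0)

    def test_no_same_sign_null(self):
        nes, pvalue = nes_and_pvalue(0.5, np.array([-0.1, -0.2, -0.3]))
        assert math.isnan(nes)
        assert pvalue == pytest.approx(1 / 4)

    def test_pvalue_floor_is_one_over_n_plus_one(self):
        null = np.full(999, 0.1)
        _, pvalue = nes_and_pvalue(0.9, null)
        assert pvalue == pytest.approx(1 / 1000)


class TestFdr:
    def test_hand_bh_example(self):
        p = pd.Series([0.01, 0.02, 0.03], index=["t1", "t2", "t3"])
        q = fdr_over_tissues(p)
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])
        np.testing.assert_allclose(q, oracles.bh_adjust(list(p)))

    def test_single_tissue_q_equals_p(self):
        q = fdr_over_tissues(pd.Series([0.2], index=["t"]))
        assert q.iloc[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        q = fdr_over_tissues(pd.Series([1.0, 1.0, 1.0]))
        assert (q == 1.0).all()

    @pytest.mark.parametrize("seed", [0, 1])
    def test_q_ge_p_and_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = pd.Series(rng.uniform(size=12))
        q = fdr_over_tissues(p)
        assert (q.to_numpy() >= p.to_numpy() - 1e-15).all()
        np.testing.assert_allclose(q, oracles.bh_adjust(list(p)), atol=1e-12)


def synthetic_shares(seed=0, n_per_tissue=12, effect_gene="gA", effect_tissue="T1", fold=6.0):
    rng = np.random.default_rng(seed)
    tissues = ["T1", "T2", "T3"]
    samples, labels = [], {}
    for t in tissues:
        for i in range(n_per_tissue):
            s = f"{t}-{i:02d}"
            samples.append(s)
            labels[s] = t
    ann = pd.Series(labels)
    values = pd.DataFrame(
        np.exp(rng.normal(np.log(50), 0.4, size=(3, len(samples)))),
        index=["gA", "gB", "gC"],
        columns=samples,
    )
    if effect_gene:
        cols = [s for s in samples if labels[s] == effect_tissue]
        values.loc[effect_gene, cols] *= fold
    shares = values / values.sum(axis=0)
    return shares, ann


class TestRunEnrichment:
    def test_planted_effect_flagged_positive(self):
        shares, ann = synthetic_shares(seed=3)
        records = run_enrichment(
            shares, ann, PermutationConfig(n_permutations=2000, seed=0), group="G"
        )
        hit = records[(records.gene == "gA") & (records.tissue == "T1")].iloc[0]
        assert hit.significant and hit.nes > 0
        assert set(records.columns) >= {
            "group", "gene", "tissue", "set_size", "es", "nes",
            "pvalue", "qvalue", "significant",
        }

    def test_qvalues_dominate_pvalues_within_gene(self):
        shares, ann = synthetic_shares(seed=4, effect_gene=None)
        records = run_enrichment(shares, ann, PermutationConfig(n_permutations=500, seed=1))
        assert (records.qvalue >= records.pvalue - 1e-15).all()

    def test_results_invariant_to_gene_iteration_order(self):
        shares, ann = synthetic_shares(seed=5)
        config = PermutationConfig(n_permutations=500, seed=9, exhaustive=False)
        a = run_enrichment(shares, ann, config)
        b = run_enrichment(shares.iloc[::-1], ann, config)
        key = ["gene", "tissue"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True)[a.columns],
            b.sort_values(key).reset_index(drop=True)[a.columns],
        )

    def test_single_tissue_annotation_yields_empty_with_warning(self):
        shares, _ = synthetic_shares(seed=6, effect_gene=None)
        ann = pd.Series("T", index=shares.columns)
        with pytest.warns(EnrichmentWarning, match="spans all"):
            records = run_enrichment(shares, ann, PermutationConfig(n_permutations=200))
        assert records.empty

    def test_small_tissue_skipped_with_warning(self):
        shares, ann = synthetic_shares(seed=7, effect_gene=None)
        ann = ann.copy()
        ann.iloc[0] = "tiny"
        with pytest.warns(EnrichmentWarning, match="tiny"):
            records = run_enrichment(shares, ann, PermutationConfig(n_permutations=200))
        assert "tiny" not in set(records.tissue)


def test_reversal_and_complement_preserve_top_tissue():
    """On a fixed two-tissue fixture, reversing the ranking and swapping the
    tissue roles cannot change which tissue attains the larger |es|."""
    ranked = ranking_from([1.0] * 8)  # equal stats: order fixed by sample id
    t1 = {"s0", "s1", "s2"}
    t2 = set(ranked.samples) - t1
    es1, _ = enrichment_score(ranked, t1, weight_exponent=0.0)
    es2, _ = enrichment_score(ranked, t2, weight_exponent=0.0)
    top = "t1" if abs(es1) >= abs(es2) else "t2"
    reversed_ranked = RankedSamples(
        samples=ranked.samples[::-1], statistics=ranked.statistics[::-1]
    )
    r1, _ = enrichment_score(reversed_ranked, t2, weight_exponent=0.0)
    r2, _ = enrichment_score(reversed_ranked, t1, weight_exponent=0.0)
    rtop = "t1" if abs(r1) >= abs(r2) else "t2"
    assert top == rtop
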