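"""Normalization, dispersion, exact NB test, BH, and the enrichment model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from liga.enrichment import (
    ContrastSpec,
    DifferentialEnrichment,
    bh_adjust,
    estimate_dispersion,
    group_tests,
    nb_exact_test,
    normalize,
    run_enrichment,
)
from liga.synth import simulate_counts


class TestNormalize:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame({"A": [10, 20, 30], "B": [10, 20, 30]},
                          index=["i1", "i2", "g1"])
        res = normalize(df, "invariant_set", ["i1", "i2"])
        assert np.allclose(res.size_factors, [1.0, 1.0])

    def test_doubled_sample_equalized_on_invariants(self):
        df = pd.DataFrame({"A": [10, 40, 7], "B": [20, 80, 100]},
                          index=["i1", "i2", "g1"])
        res = normalize(df, "invariant_set", ["i1", "i2"])
        normed = df[["A", "B"]].div(res.size_factors)
        assert np.allclose(normed.loc["i1", "A"], normed.loc["i1", "B"])
        assert np.allclose(normed.loc["i2", "A"], normed.loc["i2", "B"])

    def test_factors_have_unit_geometric_mean(self, liga6x5):
        cm, _ = simulate_counts(liga6x5, seed=5)
        inv = [e.entry_id for e in liga6x5.invariant_entries]
        for method, ids in [("invariant_set", inv), ("tmm", None),
                            ("naive_composition", None)]:
            f = normalize(cm, method, ids).size_factors.to_numpy()
            assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)
            assert (f > 0).all()

    def test_tmm_recovers_global_threefold_scale(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(5, 1, 200).round() + 1
        df = pd.DataFrame({"A": base, "B": 3 * base})
        res = normalize(df, "tmm")
        ratio = res.size_factors["B"] / res.size_factors["A"]
        assert ratio == pytest.approx(3.0, abs=1e-6)

    def test_zero_count_invariant_raises_with_entry_name(self):
        df = pd.DataFrame({"A": [0, 5], "B": [3, 5]}, index=["i1", "i2"])
        with pytest.raises(ValueError, match="i1"):
            normalize(df, "invariant_set", ["i1", "i2"])


class TestDispersion:
    def _design(self, cm):
        return {"test": ["T1", "T2", "T3"], "control": ["C1", "C2", "C3"]}

    def test_poisson_counts_give_near_zero_dispersion(self, liga6x5):
        rng = np.random.default_rng(42)
        mu = rng.lognormal(5, 0.8, 50)
        df = pd.DataFrame(
            rng.poisson(mu[:, None], (50, 6)),
            columns=["T1", "T2", "T3", "C1", "C2", "C3"],
        )
        f = pd.Series(1.0, index=df.columns)
        est = estimate_dispersion(df, f, self._design(df))
        assert est.common <= 0.02

    def test_nb_dispersion_recovered_within_tolerance(self):
        rng = np.random.default_rng(7)
        true_disp = 0.1
        r = 1 / true_disp
        mu = rng.lognormal(5.5, 0.8, 60)
        y = rng.negative_binomial(r, r / (r + mu[:, None]), (60, 6))
        df = pd.DataFrame(y, columns=["T1", "T2", "T3", "C1", "C2", "C3"])
        f = pd.Series(1.0, index=df.columns)
        est = estimate_dispersion(df, f, self._design(df))
        assert est.common == pytest.approx(true_disp, abs=0.05)

    def test_constant_counts_give_zero_dispersion(self):
        df = pd.DataFrame(100, index=range(10),
                          columns=["T1", "T2", "T3", "C1", "C2", "C3"])
        f = pd.Series(1.0, index=df.columns)
        est = estimate_dispersion(df, f, self._design(df))
        assert est.common == 0.0

    def test_single_replicate_design_returns_floor_with_warning(self):
        df = pd.DataFrame({"T1": [5, 6], "C1": [7, 8]})
        f = pd.Series(1.0, index=df.columns)
        est = estimate_dispersion(df, f, {"test": ["T1"], "control": ["C1"]})
        assert est.single_replicate_warning
        assert est.common > 0

    def test_partial_shrinkage_interpolates_toward_common(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(5, 0.5, 20)
        y = rng.poisson(mu[:, None], (20, 6))
        df = pd.DataFrame(y, columns=["T1", "T2", "T3", "C1", "C2", "C3"])
        f = pd.Series(1.0, index=df.columns)
        full = estimate_dispersion(df, f, self._design(df), shrinkage_weight=1.0)
        half = estimate_dispersion(df, f, self._design(df), shrinkage_weight=0.5)
        assert np.allclose(full.per_entry, full.common)
        assert np.all(half.per_entry >= 0)


class TestExactTest:
    def test_balanced_counts_are_modal(self):
        assert nb_exact_test([10, 10], ([0], [1]), 0.0) == 1.0

    def test_extreme_split_matches_enumeration(self):
        p = nb_exact_test([0, 20], ([0], [1]), 0.0)
        assert p == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_dispersion_zero_matches_binomial_oracle_exhaustively(self):
        """Conditional binomial oracle agreement for every split, totals <= 50."""
        for s in range(1, 51):
            for z1 in range(s + 1):
                ours = nb_exact_test([z1, s - z1], ([0], [1]), 0.0)
                oracle = stats.binomtest(z1, s, 0.5).pvalue
                assert ours == pytest.approx(oracle, rel=1e-9), (s, z1)

    def test_unbalanced_group_sizes_use_group_proportion(self):
        # 2 test vs 1 control replicate: null proportion 2/3
        p = nb_exact_test([5, 5, 5], ([0, 1], [2]), 0.0)
        oracle = stats.binomtest(10, 15, 2 / 3).pvalue
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_dispersion_widens_the_null(self):
        p0 = nb_exact_test([40, 10], ([0], [1]), 0.0)
        p1 = nb_exact_test([40, 10], ([0], [1]), 0.5)
        assert p1 > p0

    def test_conditional_law_matches_monte_carlo_at_positive_dispersion(self):
        """The negative-hypergeometric conditional distribution underlying
        the exact test matches brute-force simulation: draw independent NB
        pairs with common dispersion, condition on their sum."""
        from liga.enrichment import _nb_cond_pmf

        rng = np.random.default_rng(123)
        disp, mu = 0.4, 8.0
        r = 1 / disp
        z1 = rng.negative_binomial(r, r / (r + mu), 400_000)
        z2 = rng.negative_binomial(r, r / (r + mu), 400_000)
        s = 12
        sel = z1[z1 + z2 == s]
        emp = np.bincount(sel, minlength=s + 1) / sel.size
        pmf = _nb_cond_pmf(s, r, r)
        assert np.max(np.abs(emp - pmf)) < 4 / np.sqrt(sel.size)

    def test_negative_dispersion_raises(self):
        with pytest.raises(ValueError):
            nb_exact_test([1, 2], ([0], [1]), -0.1)

    def test_zero_total_gives_p_one(self):
        assert nb_exact_test([0, 0], ([0], [1]), 0.1) == 1.0


class TestBH:
    def test_degenerate_all_ones(self):
        assert np.allclose(bh_adjust([1, 1, 1]), [1, 1, 1])

    def test_hand_enumerated_stepup_values(self):
        out = bh_adjust([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(out, [0.04, 0.04, 0.05, 0.05])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        assert np.all(bh_adjust(p) >= p - 1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrichmentModel:
    def test_true_enrichment_detected_invariants_clean(self, liga6x5):
        enriched = [e.entry_id for e in liga6x5.glycan_entries[:6]]
        cm, _ = simulate_counts(
            liga6x5, seed=3, fc_map={e: 8.0 for e in enriched}, dispersion=0.1
        )
        res = run_enrichment(
            cm, liga6x5, ContrastSpec(("T1", "T2", "T3"), ("C1", "C2", "C3"))
        )
        sig = set(res.significant_entries)
        assert set(enriched) <= sig
        inv_ids = {e.entry_id for e in liga6x5.invariant_entries}
        assert not (sig & inv_ids)
        assert (res.table.loc[enriched, "log2FC"] > 2).all()

    def test_identical_count_groups_give_zero_fc_nothing_significant(
        self, liga6x5
    ):
        cm, _ = simulate_counts(liga6x5, n_test=3, n_control=0, seed=8)
        df = cm.counts[["T1", "T2", "T3"]]
        dup = pd.concat(
            [df, df.rename(columns={"T1": "C1", "T2": "C2", "T3": "C3"})], axis=1
        )
        res = run_enrichment(
            dup, liga6x5, ContrastSpec(("T1", "T2", "T3"), ("C1", "C2", "C3"))
        )
        assert np.allclose(res.table["log2FC"], 0.0)
        assert not res.significant_entries

    def test_global_count_doubling_leaves_log2fc_unchanged(self, liga6x5):
        """Scale invariance via normalization, up to the O(prior/mean) effect
        of the fixed 0.5 prior count on the count scale."""
        cm, _ = simulate_counts(
            liga6x5, seed=13,
            fc_map={liga6x5.glycan_entries[0].entry_id: 4.0},
        )
        contrast = ContrastSpec(("T1", "T2", "T3"), ("C1", "C2", "C3"))
        a = run_enrichment(cm.counts, liga6x5, contrast)
        b = run_enrichment(cm.counts * 2, liga6x5, contrast)
        assert np.allclose(a.table["log2FC"], b.table["log2FC"], atol=0.01)
        assert a.significant_entries == b.significant_entries

    def test_missing_contrast_sample_raises(self, liga6x5):
        cm, _ = simulate_counts(liga6x5, seed=1)
        with pytest.raises(KeyError, match="absent"):
            run_enrichment(
                cm, liga6x5, ContrastSpec(("T1", "T9"), ("C1", "C2"))
            )

    def test_entry_absent_from_dictionary_raises(self, liga6x5):
        cm, _ = simulate_counts(liga6x5, seed=1)
        counts = cm.counts.rename(index={cm.counts.index[0]: "alien"})
        with pytest.raises(KeyError, match="alien"):
            run_enrichment(
                counts, liga6x5, ContrastSpec(("T1", "T2", "T3"),
                                              ("C1", "C2", "C3"))
            )

    def test_contrast_overlap_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ContrastSpec(("A", "B"), ("B", "C"))

    def test_heatmap_is_structure_by_density_with_flags(self, liga6x5):
        enriched = [e.entry_id for e in liga6x5.glycan_entries[:5]]
        cm, _ = simulate_counts(
            liga6x5, seed=3, fc_map={e: 8.0 for e in enriched}
        )
        res = run_enrichment(
            cm, liga6x5, ContrastSpec(("T1", "T2", "T3"), ("C1", "C2", "C3"))
        )
        heat = res.heatmap_frame()
        assert heat.shape == (6, 5)
        assert list(heat.columns) == [50, 150, 500, 750, 1000]
        starred = heat.loc["Man3"].str.endswith("*")
        assert starred.all()

    def test_summary_mentions_contrast_and_alpha(self, liga6x5):
        cm, _ = simulate_counts(liga6x5, seed=3)
        res = run_enrichment(
            cm, liga6x5,
            ContrastSpec(("T1", "T2", "T3"), ("C1", "C2", "C3"), label="SNA vs BSA"),
        )
        text = res.summary()
        assert "SNA vs BSA" in text
        assert "invariant" in text


class TestGroupTests:
    def test_exact_u_test_enumeration(self):
        # 2 of C(6,3)=20 orderings are as extreme -> p = 0.1
        p = group_tests({"a": [1, 2, 3], "b": [4, 5, 6]},
                        "mann_whitney_two_sided")
        assert p == pytest.approx(0.1, rel=1e-9)

    def test_identical_groups_give_p_one(self):
        p = group_tests({"a": [1, 2, 3], "b": [1, 2, 3]},
                        "mann_whitney_two_sided")
        assert p == 1.0

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        p = group_tests({"a": a, "b": b}, "mann_whitney_two_sided")
        oracle = stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert p == pytest.approx(oracle)

    def test_anova_matches_f_oneway(self):
        groups = {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 3.5, 4.0],
                  "g3": [5.0, 6.0, 5.5]}
        p = group_tests(groups, "one_way_anova")
        assert p == pytest.approx(stats.f_oneway(*groups.values()).pvalue)

    def test_degenerate_anova_flagged_as_nan(self):
        p = group_tests({"a": [2.0, 2.0], "b": [2.0, 2.0]}, "one_way_anova")
        assert np.isnan(p)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            group_tests({"a": [], "b": [1.0]}, "mann_whitney_two_sided")


class TestFdrCalibration:
    def test_empirical_fdr_controlled_and_power_high(self, liga6x5):
        """Null+signal simulations: FDP <= alpha on average, power near 1."""
        glyc = [e.entry_id for e in liga6x5.glycan_entries]
        fdps, powers = [], []
        for i in range(1, 61):
            rng = np.random.default_rng(90000 + i)
            enriched = list(rng.choice(glyc, size=6, replace=False))
            cm, _ = simulate_counts(
                liga6x5, seed=i, fc_map={e: 8.0 for e in enriched},
                dispersion=0.1,
            )
            res = run_enrichment(
                cm, liga6x5,
                ContrastSpec(("T1", "T2", "T3"), ("C1", "C2", "C3")),
            )
            sig = set(res.significant_entries)
            fdps.append(len(sig - set(enriched)) / max(len(sig), 1))
            powers.append(len(sig & set(enriched)) / 6)
        assert np.mean(fdps) <= 0.05 + 0.02  # alpha within Monte-Carlo error
        assert np.mean(powers) > 0.9
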