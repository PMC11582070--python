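"""Unit and property tests for the five-stage rank-sum statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sortscreen import (
    CountMatrix,
    GuideLibrary,
    LibraryEntry,
    Sample,
    ScreenDesign,
    ValidationError,
    aggregate_targets,
    analyze_screen,
    build_null,
    compute_feature_stats,
    empirical_pvalues,
    enrichment_ratios,
    normalize_counts,
    rank_features,
)
from sortscreen.stats import NullDistribution

from conftest import random_count_matrix


def one_rep_design(**kw):
    kw.setdefault("pseudocount", 0.5)
    return ScreenDesign(mode="reporter_sort", pairs=[(1, "s_num", "s_den")], **kw)


def frame(values, columns):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    idx = pd.Index([f"f{i}" for i in range(values.shape[0])], name="feature_id")
    return pd.DataFrame(values, index=idx, columns=columns)


class TestNormalize:
    def test_reads_per_million(self):
        cm = CountMatrix(["a", "b", "c"], [Sample("s", 1, "stable")],
                         [[2], [3], [5]])
        out = normalize_counts(cm, scale=1e6)
        assert out["s"].tolist() == [200000.0, 300000.0, 500000.0]

    def test_single_feature_identity(self):
        cm = CountMatrix(["a"], [Sample("s", 1, "stable")], [[7]])
        assert normalize_counts(cm)["s"].tolist() == [1e6]

    def test_columns_sum_to_scale(self):
        cm, _ = random_count_matrix(n_features=50, n_replicates=2, seed=1, low=1)
        out = normalize_counts(cm)
        np.testing.assert_allclose(out.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_total_sample_named(self):
        cm = CountMatrix(["a", "b"], [Sample("ok", 1, "stable"),
                                      Sample("empty", 1, "unstable")],
                         [[1, 0], [2, 0]])
        with pytest.raises(ValidationError, match="empty"):
            normalize_counts(cm)


class TestRatios:
    def test_examples(self):
        norm = frame([[200.0, 100.0], [100.0, 100.0]], ["s_num", "s_den"])
        out = enrichment_ratios(norm, one_rep_design(pseudocount=0.0))
        assert out[1].tolist() == [2.0, 1.0]

    def test_pseudocount_on_zero_numerator(self):
        norm = frame([[0.0, 100.0]], ["s_num", "s_den"])
        out = enrichment_ratios(norm, one_rep_design(pseudocount=0.5))
        assert out[1].iloc[0] == pytest.approx(0.5 / 100.5)

    def test_zero_denominator_without_pseudocount_raises(self):
        norm = frame([[5.0, 0.0]], ["s_num", "s_den"])
        with pytest.raises(ValidationError, match="f0"):
            enrichment_ratios(norm, one_rep_design(pseudocount=0.0))


class TestRanks:
    def test_enriched_first(self):
        ratios = frame([[3.0], [1.0], [0.5], [2.0]], [1])
        assert rank_features(ratios, "enriched_first")[1].tolist() == [1, 3, 4, 2]

    def test_tie_average(self):
        ratios = frame([[2.0], [2.0], [1.0]], [1])
        assert rank_features(ratios, "enriched_first")[1].tolist() == [1.5, 1.5, 3]

    def test_depleted_first_reverses(self):
        ratios = frame([[3.0], [1.0], [0.5], [2.0]], [1])
        assert rank_features(ratios, "depleted_first")[1].tolist() == [4, 2, 1, 3]

    @given(st.integers(2, 40), st.integers(1, 4), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_rank_sums_conserved(self, n, reps, seed):
        """Per-replicate ranks always sum to N(N+1)/2, ties included."""
        rng = np.random.default_rng(seed)
        ratios = frame(rng.choice([0.5, 1.0, 2.0, 3.0], size=(n, reps)),
                       list(range(1, reps + 1)))
        ranks = rank_features(ratios, "enriched_first")
        np.testing.assert_allclose(ranks.sum(axis=0), n * (n + 1) / 2)


class TestAggregate:
    def make_stats(self, med, rank):
        idx = pd.Index([f"g_{i}" for i in range(len(med))], name="feature_id")
        return pd.DataFrame({"median_ratio": med, "rank_sum": rank}, index=idx)

    def library_one_target(self, n):
        return GuideLibrary([LibraryEntry(f"g_{i}", "tgt") for i in range(n)])

    def test_even_count_midpoint_median(self):
        stats = self.make_stats([1, 2, 3, 4], [5, 9, 11, 20])
        out = aggregate_targets(stats, self.library_one_target(4))
        assert out.loc[0, "fold_change"] == 2.5
        assert out.loc[0, "rank_stat"] == 10.0
        assert out.loc[0, "n_features"] == 4

    def test_single_feature_identity(self):
        stats = self.make_stats([1.7], [42.0])
        out = aggregate_targets(stats, self.library_one_target(1))
        assert out.loc[0, "fold_change"] == 1.7
        assert out.loc[0, "rank_stat"] == 42.0

    def test_target_without_features_rejected(self):
        stats = self.make_stats([1.0], [3.0])
        lib = GuideLibrary([LibraryEntry("g_0", "tgt"), LibraryEntry("g_x", "ghost")])
        with pytest.raises(ValidationError, match="ghost"):
            aggregate_targets(stats, lib)


class TestNull:
    def test_whole_library_one_target_is_degenerate(self):
        null = build_null(4, 1, 4, n_iterations=50, seed=0)
        assert np.all(null.stats == 2.5)  # median of any permutation of 1..4

    def test_mean_matches_closed_form(self):
        # E[rank] = (N+1)/2 per replicate, so E[rank sum] = R(N+1)/2 = 151.5
        null = build_null(100, 3, 4, n_iterations=400, seed=1)
        assert null.stats.mean() == pytest.approx(151.5, rel=0.01)

    def test_seed_reproducibility(self):
        a = build_null(50, 2, 4, 20, seed=9)
        b = build_null(50, 2, 4, 20, seed=9)
        np.testing.assert_array_equal(a.stats, b.stats)

    def test_pooling_size(self):
        null = build_null(10, 1, 4, n_iterations=7, seed=0)
        assert null.size == 7 * (10 // 4)

    def test_bad_arguments(self):
        with pytest.raises(ValidationError):
            build_null(4, 1, 8, 10, seed=0)
        with pytest.raises(ValidationError):
            build_null(4, 1, 2, 0, seed=0)


class TestEmpiricalP:
    def test_floor_when_below_all_draws(self):
        null = NullDistribution(np.arange(1.0, 101.0), 100, 1, 0)
        p = empirical_pvalues([0.0], null)
        assert p[0] == pytest.approx(2 / 101)

    def test_capped_at_one_at_the_median(self):
        null = NullDistribution(np.arange(1.0, 102.0), 101, 1, 0)  # odd size
        assert empirical_pvalues([51.0], null)[0] == 1.0

    def test_bounds_hold_for_random_observations(self):
        rng = np.random.default_rng(0)
        null = NullDistribution(rng.normal(size=500), 500, 1, 0)
        p = empirical_pvalues(rng.normal(size=200), null)
        assert np.all(p >= 2 / 501) and np.all(p <= 1.0)


class TestPipeline:
    def test_swapping_roles_inverts_fold_change(self):
        # odd replicate and guide counts: medians are order statistics, so
        # the reciprocal map commutes with both aggregation medians
        lib = GuideLibrary([LibraryEntry(f"t{t}_g{i}", f"t{t}")
                            for t in range(3) for i in range(3)])
        cm, design = random_count_matrix(n_features=9, n_replicates=3,
                                         seed=3, low=10, high=400)
        cm = CountMatrix(lib.feature_ids, cm.samples, cm.counts)
        small_library = lib
        design.pseudocount = 0.0
        res = analyze_screen(cm, small_library, design)
        swapped_pairs = [(r, den, num) for r, num, den in design.pairs]
        swapped_samples = [Sample(s.sample_id, s.replicate,
                                  {"stable": "unstable", "unstable": "stable"}[s.role])
                           for s in cm.samples]
        cm2 = CountMatrix(cm.features, swapped_samples, cm.counts)
        design2 = ScreenDesign(mode="reporter_sort", pairs=swapped_pairs,
                               pseudocount=0.0, seed=design.seed)
        res2 = analyze_screen(cm2, small_library, design2)
        a = res.set_index("target_id")["fold_change"]
        b = res2.set_index("target_id")["fold_change"]
        np.testing.assert_allclose(a * b.loc[a.index], 1.0, rtol=1e-9)
        # rank order reverses
        r1 = res.set_index("target_id")["rank_stat"]
        r2 = res2.set_index("target_id")["rank_stat"].loc[r1.index]
        assert np.all(np.argsort(r1.to_numpy()) == np.argsort(-r2.to_numpy()))

    def test_monotone_in_numerator_count(self, small_library, small_samples,
                                         small_design):
        rng = np.random.default_rng(2)
        base = rng.integers(50, 500, size=(8, 4))
        cm = CountMatrix(small_library.feature_ids, small_samples, base)
        res = analyze_screen(cm, small_library, small_design)
        bumped = base.copy()
        bumped[0, 0] += 200  # feature geneA_sg1 in rep1_stable
        cm2 = CountMatrix(small_library.feature_ids, small_samples, bumped)
        res2 = analyze_screen(cm2, small_library, small_design)
        fc1 = res.set_index("target_id").loc["geneA", "fold_change"]
        fc2 = res2.set_index("target_id").loc["geneA", "fold_change"]
        assert fc2 >= fc1

    def test_exclude_controls_drops_control_targets(self, small_samples,
                                                    small_design):
        lib = GuideLibrary(
            [LibraryEntry(f"geneA_sg{i}", "geneA") for i in range(1, 5)]
            + [LibraryEntry(f"ctrl_sg{i}", "CTRL", None, True) for i in range(1, 5)]
        )
        rng = np.random.default_rng(4)
        cm = CountMatrix(lib.feature_ids, small_samples,
                         rng.integers(10, 300, size=(8, 4)))
        res = analyze_screen(cm, lib, small_design, exclude_controls=True)
        assert res["target_id"].tolist() == ["geneA"]

    def test_mismatched_library_rejected(self, small_library, small_counts,
                                         small_design):
        other = GuideLibrary([LibraryEntry("x1", "x")])
        with pytest.raises(ValidationError, match="feature sets differ"):
            analyze_screen(small_counts, other, small_design)
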