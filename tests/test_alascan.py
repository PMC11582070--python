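"""Sub-library concatenation and single-feature-target statistics."""

import numpy as np
import pandas as pd
import pytest

from sortscreen import (
    CountMatrix,
    GuideLibrary,
    LibraryEntry,
    Sample,
    ScreenDesign,
    ValidationError,
    aggregate_targets,
    analyze_alascan,
    concat_sublibraries,
    parse_variant_id,
    simulate_alascan,
    split_sublibraries,
)


def two_sample_set():
    return [Sample("rep1_stable", 1, "stable"), Sample("rep1_unstable", 1, "unstable")]


class TestConcat:
    def test_disjoint_blocks_stack(self):
        samples = two_sample_set()
        a = CountMatrix([f"a{i}" for i in range(57)], samples,
                        np.ones((57, 2), dtype=int))
        b = CountMatrix([f"b{i}" for i in range(56)], samples,
                        np.full((56, 2), 2))
        merged = concat_sublibraries([a, b])
        assert len(merged.features) == 113
        assert merged.counts[:57].sum() == 57 * 2
        assert merged.counts[57:].sum() == 56 * 4

    def test_shared_feature_named(self):
        samples = two_sample_set()
        a = CountMatrix(["V380A", "x1"], samples, np.ones((2, 2), dtype=int))
        b = CountMatrix(["V380A"], samples, np.ones((1, 2), dtype=int))
        with pytest.raises(ValidationError, match="V380A"):
            concat_sublibraries([a, b])

    def test_replicate_structure_mismatch(self):
        a = CountMatrix(["x"], two_sample_set(), [[1, 2]])
        b = CountMatrix(["y"], [Sample("rep1_stable", 1, "stable"),
                               Sample("rep2_unstable", 2, "unstable")], [[1, 2]])
        with pytest.raises(ValidationError, match="structure"):
            concat_sublibraries([a, b])

    def test_column_order_aligned_to_first(self):
        a = CountMatrix(["x"], two_sample_set(), [[1, 2]])
        b = CountMatrix(["y"], list(reversed(two_sample_set())), [[3, 4]])
        merged = concat_sublibraries([a, b])
        assert merged.sample_ids == ["rep1_stable", "rep1_unstable"]
        assert merged.counts.tolist() == [[1, 2], [4, 3]]


class TestVariantIds:
    @pytest.mark.parametrize("vid,expected", [
        ("H437A", (437, "Ala")),
        ("A412R", (412, "Arg")),
        ("W349A", (349, "Ala")),
    ])
    def test_parse(self, vid, expected):
        assert parse_variant_id(vid) == expected

    def test_malformed_rejected(self):
        with pytest.raises(ValidationError, match="437"):
            parse_variant_id("437A")


class TestAnalyze:
    def test_single_feature_aggregation_is_identity(self):
        lib = GuideLibrary([LibraryEntry(f"v{i}", f"v{i}") for i in range(5)])
        rng = np.random.default_rng(1)
        stats = pd.DataFrame(
            {"median_ratio": rng.lognormal(size=5), "rank_sum": rng.uniform(1, 10, 5)},
            index=pd.Index([f"v{i}" for i in range(5)], name="feature_id"))
        out = aggregate_targets(stats, lib).set_index("target_id")
        np.testing.assert_array_equal(out["fold_change"], stats["median_ratio"])
        np.testing.assert_array_equal(out["rank_stat"], stats["rank_sum"])
        assert (out["n_features"] == 1).all()

    def test_fold_change_is_median_across_replicates(self):
        # 3 variants, 2 replicates, counts crafted so variant v0's
        # normalized ratios are exactly 2 and 4
        samples = [Sample("rep1_stable", 1, "stable"),
                   Sample("rep1_unstable", 1, "unstable"),
                   Sample("rep2_stable", 2, "stable"),
                   Sample("rep2_unstable", 2, "unstable")]
        counts = CountMatrix(["N1A", "N2A", "N3A"], samples,
                             [[200, 100, 400, 100],
                              [400, 400, 300, 400],
                              [400, 500, 300, 500]])
        lib = GuideLibrary([LibraryEntry(v, v) for v in counts.features])
        design = ScreenDesign("reporter_sort",
                              [(1, "rep1_stable", "rep1_unstable"),
                               (2, "rep2_stable", "rep2_unstable")],
                              pseudocount=0.0, n_null_iterations=50, seed=0)
        res = analyze_alascan(counts, lib, design).set_index("variant_id")
        assert res.loc["N1A", "fold_change"] == pytest.approx(3.0)
        assert res.loc["N1A", "position"] == 1
        assert res.loc["N1A", "substitution"] == "Ala"

    def test_multi_feature_targets_rejected(self):
        lib = GuideLibrary([LibraryEntry("v1", "t"), LibraryEntry("v2", "t")])
        counts = CountMatrix(["v1", "v2"], two_sample_set(), [[1, 2], [3, 4]])
        design = ScreenDesign("reporter_sort",
                              [(1, "rep1_stable", "rep1_unstable")])
        with pytest.raises(ValidationError, match="exactly one feature"):
            analyze_alascan(counts, lib, design)

    def test_sublibrary_order_invariance(self):
        counts, lib, design = simulate_alascan(range(349, 462), depth=10 ** 5,
                                               seed=11, effects={400: 1.0})
        parts = split_sublibraries(counts, lib)
        res_fwd = analyze_alascan(parts, lib, design)
        res_rev = analyze_alascan(list(reversed(parts)), lib, design)
        pd.testing.assert_frame_equal(res_fwd, res_rev)

    def test_per_sublibrary_normalization_mode_runs(self):
        counts, lib, design = simulate_alascan(range(349, 404), depth=10 ** 4,
                                               seed=2)
        parts = split_sublibraries(counts, lib)
        res = analyze_alascan(parts, lib, design,
                              per_sublibrary_normalization=True)
        assert len(res) == len(lib)

    def test_concat_equivalent_to_premerged_truth(self):
        """Analyzing concatenated equal-depth sub-libraries matches a
        single-pool simulation of the same effects on fold changes."""
        effects = {360: 1.2}
        merged, lib1, design = simulate_alascan(range(349, 462), n_sublibraries=2,
                                                effects=effects, depth=10 ** 6,
                                                seed=21)
        single, lib2, _ = simulate_alascan(range(349, 462), n_sublibraries=1,
                                           effects=effects, depth=2 * 10 ** 6,
                                           seed=22)
        res_a = analyze_alascan(merged, lib1, design).set_index("position")
        res_b = analyze_alascan(single, lib2, design).set_index("position")
        assert res_a.loc[360, "fold_change"] == pytest.approx(
            res_b.loc[360, "fold_change"], rel=0.1)
        assert res_a.loc[360, "fold_change"] == pytest.approx(np.exp(2 * 1.2),
                                                              rel=0.1)
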