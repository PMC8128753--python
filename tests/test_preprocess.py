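import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from exonarh import (
    gc_baseline_correct,
    presence_call,
    quantile_normalize,
    summarize_probes,
)
from conftest import make_annotation, make_matrix

CMAP2 = {"A_1": "A", "B_1": "B"}


def bg_row(pid, gc):
    return (pid, "", "", "", 0, 0, gc, True)


def fg_row(pid, gene, exon, gc, start=100, end=200):
    return (pid, gene, exon, "chr1", start, end, gc, False)


class TestGCBaselineCorrect:
    def test_zero_medians_identity(self):
        rows = [fg_row("p1", "g1", "e1", 10)] + [
            bg_row(f"b{i}", 10) for i in range(3)
        ]
        ann = make_annotation(rows)
        m = make_matrix([[5.0, 5.0], [0, 0], [0, 0], [0, 0]],
                        ["p1", "b0", "b1", "b2"], ["A_1", "B_1"], CMAP2)
        out = gc_baseline_correct(m, ann, min_bin_size=3)
        assert (out.values.to_numpy() == m.values.to_numpy()).all()

    def test_bin_median_subtracted(self):
        # background bin {1,2,3} has median 2; probe value 5 -> 3
        rows = [fg_row("p1", "g1", "e1", 10)] + [
            bg_row(f"b{i}", 10) for i in range(3)
        ]
        ann = make_annotation(rows)
        m = make_matrix([[5, 5], [1, 1], [2, 2], [3, 3]],
                        ["p1", "b0", "b1", "b2"], ["A_1", "B_1"], CMAP2)
        out = gc_baseline_correct(m, ann, min_bin_size=3)
        assert out.values.loc["p1", "A_1"] == pytest.approx(3.0)
        # background probes are corrected too
        assert out.values.loc["b2", "A_1"] == pytest.approx(1.0)

    def test_small_bin_falls_back_to_global_median(self):
        # probe in GC bin 15 with no background; global background median 1
        rows = [fg_row("p1", "g1", "e1", 15)] + [
            bg_row(f"b{i}", 10) for i in range(3)
        ]
        ann = make_annotation(rows)
        m = make_matrix([[4, 4], [0, 0], [1, 1], [2, 2]],
                        ["p1", "b0", "b1", "b2"], ["A_1", "B_1"], CMAP2)
        out = gc_baseline_correct(m, ann, min_bin_size=3)
        assert out.values.loc["p1", "A_1"] == pytest.approx(3.0)

    def test_no_background_probes_is_an_error(self):
        ann = make_annotation([fg_row("p1", "g1", "e1", 10)])
        m = make_matrix([[1, 1]], ["p1"], ["A_1", "B_1"], CMAP2)
        with pytest.raises(ValueError, match="background"):
            gc_baseline_correct(m, ann)

    def test_per_array_constant_shift_absorbed(self, small_sim):
        """Adding a constant per GC bin to one array does not change the result."""
        matrix, ann, _ = small_sim
        out1 = gc_baseline_correct(matrix, ann)
        shifted = matrix.values.copy()
        gc = ann.table.set_index("probe_id").loc[matrix.probe_ids, "gc_count"]
        shifted.iloc[:, 0] = shifted.iloc[:, 0] + 0.37 * gc.to_numpy()
        out2 = gc_baseline_correct(matrix.with_values(shifted), ann)
        np.testing.assert_allclose(
            out1.values.to_numpy(), out2.values.to_numpy(), atol=1e-10
        )


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = make_matrix([[1, 1], [3, 3]], ["p1", "p2"], ["A_1", "B_1"], CMAP2)
        out = quantile_normalize(m)
        assert (out.values.to_numpy() == m.values.to_numpy()).all()

    def test_hand_computed_rank_means(self):
        m = make_matrix([[1, 4], [3, 2]], ["p1", "p2"], ["A_1", "B_1"], CMAP2)
        out = quantile_normalize(m)
        np.testing.assert_allclose(
            out.values.to_numpy(), [[1.5, 3.5], [3.5, 1.5]]
        )

    def test_ties_get_mean_of_reference_values(self):
        m = make_matrix([[2, 1], [2, 3]], ["p1", "p2"], ["A_1", "B_1"], CMAP2)
        out = quantile_normalize(m)
        # reference is [1.5, 2.5]; the tied column gets the mean 2.0 twice
        np.testing.assert_allclose(
            out.values.to_numpy(), [[2.0, 1.5], [2.0, 2.5]]
        )

    def test_single_sample_warns_and_returns_unchanged(self):
        m = make_matrix([[1.0], [2.0]], ["p1", "p2"], ["A_1"],
                        {"A_1": "A", "unmeasured": "B"})
        with pytest.warns(UserWarning, match="single-sample"):
            out = quantile_normalize(m)
        assert (out.values.to_numpy() == m.values.to_numpy()).all()

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(
            float, (17, 4),
            elements=st.floats(-30, 30, allow_nan=False),
        )
    )
    def test_sorted_columns_pairwise_identical(self, X):
        samples = ["A_1", "A_2", "B_1", "B_2"]
        m = make_matrix(
            X, [f"p{i}" for i in range(X.shape[0])], samples,
            {"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"},
        )
        out = quantile_normalize(m).values.to_numpy()
        cols = np.sort(out, axis=0)
        for j in range(1, cols.shape[1]):
            # ties may perturb a column's multiset; on tie-free input exact
            if len(np.unique(X[:, j])) == len(X) and len(np.unique(X[:, 0])) == len(X):
                np.testing.assert_allclose(cols[:, j], cols[:, 0], atol=1e-12)


class TestSummarizeProbes:
    def test_odd_and_even_medians(self):
        rows = [
            fg_row("p1", "g1", "e1", 10),
            fg_row("p2", "g1", "e1", 10),
            fg_row("p3", "g1", "e2", 10, 300, 400),
            bg_row("b1", 10),
        ]
        ann = make_annotation(rows)
        m = make_matrix([[1, 1], [2, 3], [9, 9], [0, 0]],
                        ["p1", "p2", "p3", "b1"], ["A_1", "B_1"], CMAP2)
        gene = summarize_probes(m, ann, "gene")
        assert gene.loc["g1", "A_1"] == 2.0  # median of {1,2,9}
        exon = summarize_probes(m, ann, "exon")
        assert exon.loc["e1", "B_1"] == 2.0  # midpoint of {1,3}
        assert exon.loc["e2", "A_1"] == 9.0

    def test_gene_median_equals_pooled_exon_probes(self, small_sim):
        matrix, ann, _ = small_sim
        gene = summarize_probes(matrix, ann, "gene")
        t = ann.foreground.set_index("probe_id")
        rng = np.random.default_rng(0)
        for g in rng.choice(gene.index, 10, replace=False):
            probes = t.index[t["gene_id"] == g]
            expected = matrix.values.loc[probes].median(axis=0)
            np.testing.assert_allclose(gene.loc[g], expected)

    def test_random_gene_matches_sort_and_pick_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(size=(6, 2))
        rows = [fg_row(f"p{i}", "g1", "e1", 10) for i in range(6)] + [bg_row("b", 10)]
        ann = make_annotation(rows)
        m = make_matrix(
            np.vstack([vals, [[0, 0]]]),
            [f"p{i}" for i in range(6)] + ["b"], ["A_1", "B_1"], CMAP2,
        )
        out = summarize_probes(m, ann, "gene")
        for j, s in enumerate(["A_1", "B_1"]):
            srt = np.sort(vals[:, j])
            assert out.loc["g1", s] == pytest.approx((srt[2] + srt[3]) / 2)


class TestPresenceCall:
    def build(self, probe_vals):
        rows = [fg_row(f"p{i}", "g1", "e1", 10) for i in range(len(probe_vals))]
        rows += [bg_row(f"b{i}", 10) for i in range(4)]
        ids = [r[0] for r in rows]
        vals = [[v, v] for v in probe_vals] + [[b, b] for b in (0, 1, 2, 3)]
        ann = make_annotation(rows)
        m = make_matrix(vals, ids, ["A_1", "B_1"], CMAP2)
        return m, ann

    def test_interpolated_threshold_2_25(self):
        # background {0,1,2,3} -> 75% quantile 2.25; a probe at 2.5 is above
        m, ann = self.build([2.5, 2.5, 2.5])
        pres = presence_call(m, ann, min_bin_size=4)
        assert bool(pres.loc["g1", "present_A"])
        assert pres.loc["g1", "frac_above_A"] == 1.0

    def test_exact_half_above_is_absent(self):
        m, ann = self.build([2.5, 2.5, 2.0, 2.0])
        pres = presence_call(m, ann, min_bin_size=4)
        assert not bool(pres.loc["g1", "present_A"])
        assert pres.loc["g1", "frac_above_A"] == 0.5

    def test_strict_majority_is_present(self):
        m, ann = self.build([2.5, 2.5, 2.5, 2.0])
        pres = presence_call(m, ann, min_bin_size=4)
        assert bool(pres.loc["g1", "present_B"])
        assert pres.loc["g1", "frac_above_B"] == 0.75

    def test_value_at_threshold_not_above(self):
        m, ann = self.build([2.25, 2.25, 2.25])
        pres = presence_call(m, ann, min_bin_size=4)
        assert not bool(pres.loc["g1", "present_A"])
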