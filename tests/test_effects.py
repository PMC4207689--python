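"""Weighted fold changes, subcategorization, concordance, rank enrichment,
direction bias, and cross-tissue comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cistrans.effects import (
    compare_tissues,
    direction_bias_by_foldchange,
    effect_table,
    fisher_exact_two_tailed,
    fpkm_matrix,
    known_fraction,
    rank_enrichment,
    replicate_concordance,
    subcategorize,
    summarize_subcategories,
    weighted_log2_fold_change,
    weighted_mean,
)
from conftest import make_gene_df

LN2 = math.log(2.0)


class TestWeightedMean:
    def test_equal_variances_reduce_to_arithmetic_mean(self):
        assert weighted_mean([1, 2, 3], [0.4] * 3) == pytest.approx(2.0,
                                                                    abs=1e-12)

    def test_hand_computed_example(self):
        # (1/1 + 2/0.5) / (1/1 + 1/0.5) = 5/3
        assert weighted_mean([1.0, 2.0], [1.0, 0.5]) == pytest.approx(5 / 3)

    def test_single_replicate_passthrough(self):
        assert weighted_mean([2.7], [0.3]) == pytest.approx(2.7, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            weighted_mean([], [])
        with pytest.raises(ValueError):
            weighted_mean([1.0], [0.0])
        with pytest.raises(ValueError):
            weighted_mean([np.nan], [1.0])


class TestWeightedFoldChange:
    def test_identical_groups_give_zero(self):
        m, v = [1.0, 2.0], [0.2, 0.4]
        assert weighted_log2_fold_change(m, v, m, v) == 0.0

    def test_ln2_difference_is_one_log2_unit(self):
        assert weighted_log2_fold_change([LN2], [1.0], [0.0], [1.0]) == \
            pytest.approx(1.0)

    def test_worked_example_against_zero_group(self):
        got = weighted_log2_fold_change([1.0, 2.0], [1.0, 0.5],
                                        [0.0], [1.0])
        assert got == pytest.approx((5 / 3) / LN2, abs=1e-9)

    def test_effect_table_recovers_true_deltas(self):
        df = make_gene_df(delta0=0.7, delta1=0.3, sd=0.05, noise_sd=1e-9)
        tab = effect_table(df)
        assert tab.iloc[0]["y"] == pytest.approx(0.7 / LN2, abs=1e-6)
        assert tab.iloc[0]["x"] == pytest.approx(0.3 / LN2, abs=1e-6)


class TestSubcategorize:
    @pytest.mark.parametrize("x,y,label", [
        (0.8, 0.4, "CIS_minus_trans"),
        (0.5, -0.3, "TRANS_minus_cis"),
        (0.3, 0.9, "TRANS_plus_cis"),
        (0.5, 0.7, "CIS_plus_trans"),
        (-0.8, -0.4, "CIS_minus_trans"),
        (-0.3, -0.9, "TRANS_plus_cis"),
        # x*y < 0 carries no magnitude condition, so |x| = |y| is not a
        # boundary in the opposite-direction half-plane
        (0.4, -0.4, "TRANS_minus_cis"),
    ])
    def test_printed_inequalities(self, x, y, label):
        assert subcategorize(x, y) == label

    @pytest.mark.parametrize("x,y", [
        (0.0, 0.5), (0.5, 0.0), (0.4, 0.4), (0.3, 0.6),
    ])
    def test_boundaries_get_explicit_label(self, x, y):
        assert subcategorize(x, y) == "boundary"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            subcategorize(float("nan"), 1.0)

    @given(st.floats(-10, 10, allow_nan=False),
           st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=300, deadline=None)
    def test_partitions_the_non_boundary_plane(self, x, y):
        """Every point off the boundary sets receives exactly one of the
        four labels, and the label is consistent with the implied trans
        component t = y - x."""
        ax, ay = abs(x), abs(y)
        if (min(ax, ay) < 1e-6 or abs(ax - ay) < 1e-9
                or abs(ay - 2 * ax) < 1e-9):
            return  # stay clear of boundary sets and float degeneracy
        label = subcategorize(x, y)
        assert label in ("CIS_minus_trans", "TRANS_minus_cis",
                         "CIS_plus_trans", "TRANS_plus_cis")
        t = y - x
        if label == "CIS_minus_trans" and x * y > 0:
            assert np.sign(t) == -np.sign(x) and abs(x) > abs(t)
        if label == "TRANS_plus_cis":
            assert np.sign(t) == np.sign(x) and abs(t) > abs(x)


class TestSummarize:
    def test_retina_subcategory_arithmetic(self):
        """Counts 195/327/60/135 of 717 give the 73% stabilizing split."""
        labels = (["CIS_minus_trans"] * 195 + ["TRANS_minus_cis"] * 327
                  + ["CIS_plus_trans"] * 60 + ["TRANS_plus_cis"] * 135)
        s = summarize_subcategories(labels)
        assert s.n_assignable == 717
        assert s.stabilizing_fraction == pytest.approx(522 / 717)
        assert s.stabilizing_fraction == pytest.approx(0.728, abs=0.001)
        assert s.destabilizing_fraction == pytest.approx(195 / 717)

    def test_counts_sum_to_assignable_total(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["CIS_minus_trans", "TRANS_minus_cis",
                             "CIS_plus_trans", "TRANS_plus_cis",
                             "boundary"], size=200)
        s = summarize_subcategories(labels)
        assert sum(s.counts.values()) == s.n_assignable
        assert s.n_assignable + s.n_boundary == 200

    def test_all_one_category(self):
        s = summarize_subcategories(["CIS_minus_trans"] * 5)
        assert s.stabilizing_fraction == 1.0

    def test_empty_input_reports_absent_fractions(self):
        s = summarize_subcategories([])
        assert s.stabilizing_fraction is None
        assert s.destabilizing_fraction is None


class TestConcordance:
    def test_duplicated_sample_perfectly_correlated(self):
        rng = np.random.default_rng(1)
        col = rng.lognormal(size=50)
        mat = pd.DataFrame({"a": col, "b": col,
                            "c": rng.lognormal(size=50)})
        r = replicate_concordance(mat)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert (np.diag(r) == 1.0).all()
        pd.testing.assert_frame_equal(r, r.T)

    def test_anticorrelated_vectors(self):
        mat = pd.DataFrame({"a": [1, 2, 3], "b": [3, 2, 1]})
        assert replicate_concordance(mat).loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_samples_uncorrelated(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        assert abs(replicate_concordance(mat).loc["a", "b"]) < 0.05

    def test_zero_variance_sample_reported_as_nan(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3]})
        assert np.isnan(replicate_concordance(mat).loc["a", "b"])

    def test_fpkm_matrix_exponentiates(self):
        df = make_gene_df()
        mat = fpkm_matrix(df, ["F0_B6", "F0_CAST"])
        assert mat.shape == (1, 6)
        assert (mat > 0).all().all()


class TestRankEnrichment:
    def test_all_known_gives_identity_curve(self):
        ids = [f"g{i}" for i in range(10)]
        curve = rank_enrichment(ids, {g: 4 for g in ids})
        assert list(curve["cumulative_known"]) == list(range(1, 11))

    def test_disjoint_known_set_gives_flat_zero(self):
        curve = rank_enrichment(["a", "b"], {"z": 3})
        assert list(curve["cumulative_known"]) == [0, 0]

    def test_curve_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(50)]
        known = {g: int(rng.integers(0, 5)) for g in ids}
        curve = rank_enrichment(ids, known)
        assert curve["cumulative_known"].is_monotonic_increasing

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            rank_enrichment(["a", "a"], {})

    def test_top_tier_fraction(self):
        """29 known genes among a 39-gene top tier is a 74% fraction."""
        ids = [f"k{i}" for i in range(29)] + [f"u{i}" for i in range(10)]
        known = {f"k{i}": 2 for i in range(29)}
        k, frac = known_fraction(ids, known, top_n=39)
        assert (k, round(frac, 3)) == (29, round(29 / 39, 3))


class TestFisherAndDirectionBias:
    def test_balanced_table_p_is_one(self):
        assert fisher_exact_two_tailed([[10, 10], [10, 10]]) == \
            pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        # only 2 of the C(10,5) tables are as extreme: p = 2/252
        assert fisher_exact_two_tailed([[5, 0], [0, 5]]) == \
            pytest.approx(2 / 252, abs=1e-12)

    def test_degenerate_margin_reported_absent(self):
        assert fisher_exact_two_tailed([[3, 2], [0, 0]]) is None

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
                continue
            ours = fisher_exact_two_tailed(t.tolist())
            ref = stats.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_direction_bias_binning(self):
        fc = pd.Series([2.0, -2.0, 0.5, 1.5, -1.5, 3.0])
        assoc = pd.Series([True, True, True, False, False, False])
        out = direction_bias_by_foldchange(fc, assoc, [1.0, 2.5])
        assert list(out["n"]) == [5, 1]
        assert pd.isna(out.iloc[1]["p"])  # degenerate margin in top bin

    def test_identical_proportions_give_p_one(self):
        fc = pd.Series([1.0] * 10 + [-1.0] * 10 + [1.0] * 10 + [-1.0] * 10)
        assoc = pd.Series([True] * 20 + [False] * 20)
        out = direction_bias_by_foldchange(fc, assoc, [0.5])
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            direction_bias_by_foldchange(pd.Series([1.0]),
                                         pd.Series([True]), [2.0, 1.0])


class TestCompareTissues:
    def test_identical_cis_sets_fully_shared(self):
        classes = {f"g{i}": "cis" for i in range(4)}
        eff = pd.DataFrame({"gene_id": list(classes),
                            "x": [0.1, 0.5, -0.3, 0.8],
                            "y": [0.2, 0.6, -0.4, 0.9]})
        comp = compare_tissues(classes, classes, eff, eff)
        assert comp.cis_tissue_specific_fraction == 0.0
        assert comp.pearson_r_f0 == pytest.approx(1.0)
        assert comp.pearson_r_f1 == pytest.approx(1.0)

    def test_disjoint_classifiable_sets_absent_fractions(self):
        comp = compare_tissues({"a": "cis"}, {"b": "cis"})
        assert comp.cis_tissue_specific_fraction is None
        assert comp.pearson_r_f0 is None

    def test_cis_in_one_trans_in_other_excluded_from_both(self):
        comp = compare_tissues({"g": "cis"}, {"g": "trans"})
        assert comp.cis_tissue_specific_fraction is None
        assert comp.trans_tissue_specific_fraction is None

    def test_comparability_rule(self):
        ca = {"g1": "cis", "g2": "cis", "g3": "trans", "g4": "conserved"}
        cb = {"g1": "cis", "g2": "conserved", "g3": "trans", "g4": "trans"}
        comp = compare_tissues(ca, cb)
        assert comp.shared_cis == ["g1"]
        assert comp.cis_only_a == ["g2"]
        assert comp.shared_trans == ["g3"]
        assert comp.trans_only_b == ["g4"]
        assert comp.cis_tissue_specific_fraction == pytest.approx(0.5)
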