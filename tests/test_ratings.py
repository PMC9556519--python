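"""Expert aggregation and inter-rater reliability against
from-definition oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridqc import ratings as rt

# ---------------------------------------------------------------------------
# Brute-force oracles, straight from the defining formulas.
# ---------------------------------------------------------------------------


def kappa_quadratic_oracle(r1, r2, levels=(-2, -1, 0, 1, 2)):
    """Weighted kappa by explicit contingency-table evaluation."""
    levels = list(levels)
    k = len(levels)
    n = len(r1)
    observed = np.zeros((k, k))
    for a, b in zip(r1, r2):
        observed[levels.index(a), levels.index(b)] += 1
    observed /= n
    p1 = observed.sum(axis=1)
    p2 = observed.sum(axis=0)
    expected = np.outer(p1, p2)
    weights = np.array(
        [[(i - j) ** 2 / (k - 1) ** 2 for j in range(k)] for i in range(k)]
    )
    return 1.0 - (weights * observed).sum() / (weights * expected).sum()


def icc_oracle(values, variant):
    """ICC3/ICC3k from an explicit two-way ANOVA decomposition."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = values.mean()
    ss_rows = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ms_rows = ss_rows / (n - 1)
    ms_error = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if variant == "ICC3":
        return (ms_rows - ms_error) / (ms_rows + (k - 1) * ms_error)
    return (ms_rows - ms_error) / ms_rows


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


class TestAggregation:
    def test_unanimous_top_rating(self):
        ratings = pd.DataFrame([[2] * 6], index=["sub-1"])
        out = rt.aggregate_expert(ratings)
        assert out.loc["sub-1", "scaled"] == 1.0
        assert out.loc["sub-1", "category"] == "definitely pass"
        assert out.loc["sub-1", "binary"] == 1

    def test_mixed_ratings_arithmetic(self):
        ratings = pd.DataFrame([[1, 1, 0, 1, 2, 1]], index=["sub-1"])
        out = rt.aggregate_expert(ratings).loc["sub-1"]
        assert out["mean_raw"] == 1.0
        assert out["scaled"] == 0.75
        assert out["category"] == "probably pass"
        assert out["binary"] == 1

    def test_low_score_category(self):
        # scaled 0.15 <=> mean_raw -1.4; ratings (-2,-2,-1,-1,-1)
        ratings = pd.DataFrame([[-2, -2, -1, -1, -1]], index=["sub-1"])
        out = rt.aggregate_expert(ratings).loc["sub-1"]
        assert out["scaled"] == pytest.approx(0.15)
        assert out["category"] == "definitely fail"
        assert out["binary"] == 0

    @pytest.mark.parametrize(
        "scaled,category",
        [
            (0.1, "definitely fail"),
            (0.25, "probably fail"),
            (0.5, "not sure"),
            (0.75, "probably pass"),
            (0.95, "definitely pass"),
            (1.0, "definitely pass"),
        ],
    )
    def test_category_bands(self, scaled, category):
        assert rt.score_category(scaled) == category

    def test_missing_raters_ignored_and_empty_row_kept(self):
        ratings = pd.DataFrame(
            {"a": [2, np.nan], "b": [np.nan, np.nan]}, index=["sub-1", "sub-2"]
        )
        out = rt.aggregate_expert(ratings)
        assert out.loc["sub-1", "scaled"] == 1.0
        assert np.isnan(out.loc["sub-2", "scaled"])
        assert len(out) == 2

    def test_off_scale_rating_rejected(self):
        with pytest.raises(ValueError):
            rt.aggregate_expert(pd.DataFrame([[3]]))


# ---------------------------------------------------------------------------
# Quadratic-weighted kappa
# ---------------------------------------------------------------------------


class TestKappa:
    def test_perfect_agreement(self):
        r = [-2, -1, 0, 1, 2, 1, 0]
        assert rt.cohen_kappa_quadratic(r, r) == pytest.approx(1.0)

    def test_reversed_ratings_match_hand_formula(self):
        r1 = [-2, -1, 0, 1, 2]
        r2 = [2, 1, 0, -1, -2]
        expected = kappa_quadratic_oracle(r1, r2)
        assert rt.cohen_kappa_quadratic(r1, r2) == pytest.approx(expected)

    def test_constant_identical_coders_undefined(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            value = rt.cohen_kappa_quadratic([1, 1, 1], [1, 1, 1])
        assert np.isnan(value)

    def test_symmetry_and_participant_relabel_invariance(self, rng):
        r1 = rng.integers(-2, 3, size=50)
        r2 = rng.integers(-2, 3, size=50)
        assert rt.cohen_kappa_quadratic(r1, r2) == pytest.approx(
            rt.cohen_kappa_quadratic(r2, r1)
        )
        perm = rng.permutation(50)
        assert rt.cohen_kappa_quadratic(r1[perm], r2[perm]) == pytest.approx(
            rt.cohen_kappa_quadratic(r1, r2)
        )

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        r1 = rng.integers(-2, 3, size=n)
        r2 = np.where(rng.random(n) < 0.6, r1, rng.integers(-2, 3, size=n))
        if np.unique(np.concatenate([r1, r2])).size == 1:
            return
        assert rt.cohen_kappa_quadratic(r1, r2) == pytest.approx(
            kappa_quadratic_oracle(r1, r2), abs=1e-12
        )

    def test_pairwise_complete_filtering(self):
        r1 = [1, 2, np.nan, 0, -1]
        r2 = [1, np.nan, 2, 0, -1]
        expected = kappa_quadratic_oracle([1, 0, -1], [1, 0, -1])
        assert rt.cohen_kappa_quadratic(r1, r2) == pytest.approx(expected)


class TestKappaMatrix:
    def test_symmetric_unit_diagonal(self, small_experts):
        matrix = rt.pairwise_kappa_matrix(small_experts)
        np.testing.assert_allclose(matrix, matrix.T)
        np.testing.assert_allclose(np.diag(matrix), 1.0)

    def test_coders_permutation_equivariance(self, small_experts):
        matrix = rt.pairwise_kappa_matrix(small_experts)
        shuffled = small_experts[list(small_experts.columns[::-1])]
        matrix2 = rt.pairwise_kappa_matrix(shuffled)
        reordered = matrix2.loc[matrix.index, matrix.columns]
        np.testing.assert_allclose(matrix, reordered)

    def test_duplicate_coder_row_matches_original(self, small_experts):
        dup = small_experts.copy()
        dup["copy"] = dup.iloc[:, 0]
        matrix = rt.pairwise_kappa_matrix(dup)
        original = matrix.loc[small_experts.columns[0], small_experts.columns[1:]]
        copied = matrix.loc["copy", small_experts.columns[1:]]
        np.testing.assert_allclose(original, copied)

    def test_model_added_as_extra_coder(self, small_experts, rng):
        scores = rng.random(len(small_experts))
        matrix = rt.pairwise_kappa_matrix(small_experts, {"model": scores})
        assert "model" in matrix.index
        assert matrix.shape == (7, 7)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


class TestICC:
    def test_identical_coders_give_unity(self):
        column = np.arange(10, dtype=float)
        table = pd.DataFrame({f"r{i}": column for i in range(4)})
        assert rt.icc(table, "ICC3")["estimate"] == pytest.approx(1.0)
        assert rt.icc(table, "ICC3k")["estimate"] == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_anova_oracle_and_spearman_brown(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(4, 20)), int(rng.integers(2, 6))
        signal = rng.normal(size=(n, 1))
        values = signal + 0.5 * rng.normal(size=(n, k))
        table = pd.DataFrame(values)
        icc3 = rt.icc(table, "ICC3")["estimate"]
        icc3k = rt.icc(table, "ICC3k")["estimate"]
        assert icc3 == pytest.approx(icc_oracle(values, "ICC3"), abs=1e-10)
        assert icc3k == pytest.approx(icc_oracle(values, "ICC3k"), abs=1e-10)
        # Spearman-Brown identity linking the two variants
        assert icc3k == pytest.approx(
            k * icc3 / (1 + (k - 1) * icc3), abs=1e-10
        )

    def test_matches_pingouin(self, small_experts):
        import pingouin as pg

        long = small_experts.reset_index(names="target").melt(
            id_vars="target", var_name="rater", value_name="score"
        )
        table = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        # two-way mixed consistency: single measure and k-rater mean
        for variant, label in (("ICC3", "ICC(C,1)"), ("ICC3k", "ICC(C,k)")):
            ours = rt.icc(small_experts, variant)
            assert ours["estimate"] == pytest.approx(
                float(table.loc[label, "ICC"]), abs=1e-8
            )
            np.testing.assert_allclose(
                ours["ci"], table.loc[label, ci_col], atol=5e-3
            )

    def test_zero_between_participant_variance(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        with pytest.warns(RuntimeWarning, match="between-participant"):
            out = rt.icc(table, "ICC3")
        assert out["estimate"] == 0.0

    def test_more_rater_noise_lowers_reliability(self):
        rng = np.random.default_rng(0)
        signal = rng.normal(size=(60, 1))
        estimates = []
        for noise in (0.2, 0.8, 2.0):
            values = signal + noise * rng.normal(size=(60, 5))
            estimates.append(rt.icc(pd.DataFrame(values), "ICC3k")["estimate"])
        assert estimates[0] > estimates[1] > estimates[2]

    def test_incomplete_rows_dropped_listwise(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(20, 3))
        table = pd.DataFrame(values)
        table.iloc[0, 0] = np.nan
        out = rt.icc(table, "ICC3")
        assert out["n_participants"] == 19


class TestModelAsCoder:
    def test_consensus_model_does_not_reduce_consistency(self, small_experts):
        scaled = (small_experts + 2.0) / 4.0
        consensus = scaled.mean(axis=1)
        base = rt.icc(scaled, "ICC3")["estimate"]
        augmented = rt.icc(
            rt.model_as_coder(consensus, small_experts), "ICC3"
        )["estimate"]
        assert augmented >= base - 1e-9

    def test_constant_model_reduces_consistency(self, small_experts):
        scaled = (small_experts + 2.0) / 4.0
        constant = pd.Series(0.5, index=small_experts.index)
        base = rt.icc(scaled, "ICC3")["estimate"]
        augmented = rt.icc(
            rt.model_as_coder(constant, small_experts), "ICC3"
        )["estimate"]
        assert augmented < base

    def test_misaligned_participants_rejected(self, small_experts):
        wrong = pd.Series(0.5, index=[f"x{i}" for i in range(len(small_experts))])
        with pytest.raises(ValueError, match="misaligned"):
            rt.model_as_coder(wrong, small_experts)
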