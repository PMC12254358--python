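"""Scoring rules, inclusion filters, alpha/skew estimators, preparation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twinlink.scales import (
    apply_inclusion_filters,
    cronbach_alpha,
    descriptives_table,
    pairs_to_individuals,
    prepare_phenotype,
    score_dataset,
    score_scale,
    score_synaesthesia_screen,
    skewness,
)
from twinlink.syntwin import DK_CODE, default_config, generate_twin_dataset

from conftest import ten_pair_filter_fixture


class TestScreenScoring:
    @pytest.mark.parametrize(
        "responses, expected",
        [
            (["no"] * 8, 0.0),
            (["yes", "some_extent"] + ["no"] * 6, 1.5),
            (["yes"] * 8, 8.0),
            (["DK"] + ["yes"] * 7, 7.0),  # one unanswered item contributes 0
            ([np.nan] + ["some_extent"] * 7, 3.5),
        ],
    )
    def test_screen_scores(self, responses, expected):
        score, excluded = score_synaesthesia_screen(responses)
        assert not excluded
        assert score == pytest.approx(expected)

    def test_more_than_one_unanswered_excludes(self):
        score, excluded = score_synaesthesia_screen(["DK", "DK"] + ["no"] * 6)
        assert excluded and np.isnan(score)
        score, excluded = score_synaesthesia_screen([np.nan, "DK"] + ["no"] * 6)
        assert excluded

    def test_wrong_item_count_raises(self):
        with pytest.raises(ValueError, match="8 items"):
            score_synaesthesia_screen(["no"] * 7)

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="unknown response label"):
            score_synaesthesia_screen(["maybe"] + ["no"] * 7)


class TestScaleScoring:
    def test_complete_zero_scale(self):
        assert score_scale([0] * 12) == 0.0

    def test_below_80pct_is_missing(self):
        # 30/38 answered = 78.9% < 80%
        responses = [1] * 30 + [np.nan] * 8
        assert np.isnan(score_scale(responses))

    def test_exactly_80pct_is_included(self):
        # strict "<80%": exactly 80% answered stays in
        responses = [2] * 8 + [np.nan] * 2
        assert score_scale(responses) == pytest.approx(10 * 2.0)

    def test_prorating_hand_value(self):
        responses = [1] * 9 + [np.nan]
        assert score_scale(responses) == pytest.approx(10.0)

    def test_dk_counts_as_unanswered(self):
        responses = [1] * 7 + [DK_CODE] * 3
        assert np.isnan(score_scale(responses))

    @given(st.integers(min_value=0, max_value=3))
    @settings(derandomize=True, max_examples=20)
    def test_prorated_score_bounded_by_item_range(self, level):
        k = 10
        responses = [level] * 8 + [np.nan] * 2
        score = score_scale(responses)
        assert 0.0 <= score <= k * 3


class TestCronbachAlpha:
    def test_parallel_items_give_exactly_one(self):
        x = np.random.default_rng(0).standard_normal(50)
        X = np.column_stack([x, x, x])
        alpha, lo, hi = cronbach_alpha(X)
        assert alpha == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_give_near_zero(self):
        X = np.random.default_rng(1).standard_normal((5000, 12))
        alpha, _, _ = cronbach_alpha(X)
        assert abs(alpha) < 0.05

    def test_hand_computed_value(self):
        # exact sample covariance with unit item variances, total variance 6
        # -> alpha = (3/2) * (1 - 3/6) = 0.75
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((200, 3))
        Z -= Z.mean(axis=0)
        # whiten to exact identity sample covariance, then color
        L = np.linalg.cholesky(np.cov(Z, rowvar=False, ddof=1))
        W = Z @ np.linalg.inv(L).T
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        X = W @ np.linalg.cholesky(C).T
        alpha, _, _ = cronbach_alpha(X)
        assert alpha == pytest.approx(0.75, abs=1e-10)

    def test_alpha_never_exceeds_one_and_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X = rng.standard_normal((30, 5)) + rng.standard_normal((30, 1))
            alpha, lo, hi = cronbach_alpha(X)
            assert alpha <= 1.0
            assert lo <= alpha <= hi
            assert hi <= 1.0

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="2 items"):
            cronbach_alpha(np.zeros((10, 1)))
        with pytest.raises(ValueError, match="zero total-score variance"):
            cronbach_alpha(np.ones((10, 3)))


class TestSkewness:
    def test_symmetric_is_zero(self):
        assert skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_exponential_skew_is_two(self):
        x = np.random.default_rng(4).exponential(1.0, 100_000)
        assert skewness(x) == pytest.approx(2.0, abs=0.1)

    def test_matches_pandas_adjusted_estimator(self):
        x = np.random.default_rng(5).gamma(2.0, 1.0, 500)
        assert skewness(x) == pytest.approx(pd.Series(x).skew(), abs=1e-12)

    def test_transform_decision_threshold(self):
        # skew 2.38 -> transform; skew 0.66 -> no transform
        rng = np.random.default_rng(6)
        skewed = rng.lognormal(0, 0.9, 4000)
        assert skewness(skewed) > 1
        prep = prepare_phenotype(skewed, rng.integers(0, 2, 4000), np.full(4000, 2000.0))
        assert prep.transform_applied
        mild = rng.gamma(9.0, 1.0, 4000)
        assert skewness(mild) < 1
        prep2 = prepare_phenotype(mild, rng.integers(0, 2, 4000), np.full(4000, 2000.0))
        assert not prep2.transform_applied


class TestPreparePhenotype:
    def test_standardized_residuals(self):
        rng = np.random.default_rng(7)
        sex = rng.integers(0, 2, 2000)
        by = rng.integers(1999, 2005, 2000).astype(float)
        scores = 2.0 * sex + 0.1 * by + rng.standard_normal(2000)
        prep = prepare_phenotype(scores, sex, by)
        v = prep.values.to_numpy()
        assert np.nanmean(v) == pytest.approx(0.0, abs=1e-8)
        assert np.nanvar(v, ddof=1) == pytest.approx(1.0, abs=1e-8)
        # OLS orthogonality
        assert abs(np.corrcoef(v, sex)[0, 1]) < 1e-8
        assert abs(np.corrcoef(v, by)[0, 1]) < 1e-8

    def test_transform_reduces_skew_monotonically(self):
        x = np.random.default_rng(8).lognormal(0, 1.0, 5000)
        prep = prepare_phenotype(x, np.zeros(5000, dtype=int) + (x > 1), np.full(5000, 2000.0))
        assert prep.transform_applied
        assert prep.skew_after_transform < prep.skew_raw

    def test_decision_is_not_reapplied_to_prepared_output(self):
        # standardized residuals contain negatives, so log(1+x) cannot be
        # (and must not be) applied again
        x = np.random.default_rng(9).lognormal(0, 1.2, 3000)
        sex = np.random.default_rng(10).integers(0, 2, 3000)
        by = np.full(3000, 2001.0)
        first = prepare_phenotype(x, sex, by)
        assert first.transform_applied
        second = prepare_phenotype(first.values, sex, by)
        assert not second.transform_applied

    def test_missing_propagates(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 2.5, 3.0])
        prep = prepare_phenotype(x, np.zeros(6, dtype=int), np.full(6, 2000.0))
        assert np.isnan(prep.values.iloc[2])
        assert np.isfinite(prep.values.drop(index=2)).all()

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            prepare_phenotype(np.ones(10), np.zeros(10, dtype=int), np.full(10, 2000.0))


class TestInclusionFilters:
    def test_hand_counted_fixture(self):
        scored = ten_pair_filter_fixture()
        out, tally = apply_inclusion_filters(scored)
        assert out["pair_id"].nunique() == 6
        assert len(out) == 12
        assert tally == {
            "screen_missingness": 2,
            "incomplete_pair": 3,
            "undetermined_zygosity": 2,
            "included": 12,
        }

    def test_tally_partitions_participants(self):
        scored = ten_pair_filter_fixture()
        n_participants = int((~scored["absent"]).sum())
        _, tally = apply_inclusion_filters(scored)
        assert sum(tally.values()) == n_participants

    def test_whole_pair_removed_when_one_twin_fails_screen(self):
        scored = ten_pair_filter_fixture()
        out, _ = apply_inclusion_filters(scored)
        assert not set(out["pair_id"]) & {1, 2}

    def test_undetermined_pair_removed_despite_complete_data(self):
        scored = ten_pair_filter_fixture()
        out, _ = apply_inclusion_filters(scored)
        assert 4 not in set(out["pair_id"])

    def test_duplicate_pair_ids_raise(self):
        scored = ten_pair_filter_fixture()
        dup = pd.concat([scored, scored.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            apply_inclusion_filters(dup)


@pytest.fixture(scope="module")
def cohort():
    cfg = default_config(n_mz=400, n_dz_ss=400, n_dz_os=400, seed=21)
    pairs = generate_twin_dataset(cfg)
    ind = pairs_to_individuals(pairs, cfg.traits)
    scored = score_dataset(ind, cfg.traits)
    included, _ = apply_inclusion_filters(scored)
    key = included.set_index(["pair_id", "twin"]).index
    ind_inc = ind.set_index(["pair_id", "twin"]).loc[key].reset_index()
    return cfg, ind_inc, included


class TestDescriptives:
    def test_one_row_per_trait_with_zygosity_split(self, cohort):
        cfg, ind_inc, included = cohort
        table = descriptives_table(ind_inc, included, cfg.traits)
        assert list(table["trait"]) == [s.name for s in cfg.traits]
        # MZ and DZ subsamples are drawn from the same marginal model
        gap = (table["mean_mz"] - table["mean_dz"]).abs()
        assert (gap < 0.5 * table["sd_all"]).all()

    def test_skew_after_transform_only_for_skewed_traits(self, cohort):
        cfg, ind_inc, included = cohort
        table = descriptives_table(ind_inc, included, cfg.traits).set_index("trait")
        assert np.isfinite(table.loc["synaesthesia", "skew_after_transform"])
        assert table.loc["synaesthesia", "skew_raw"] > 1
        assert pd.isna(table.loc["adhd", "skew_after_transform"])

    def test_empty_dataset_raises(self, cohort):
        cfg, ind_inc, included = cohort
        with pytest.raises(ValueError, match="empty"):
            descriptives_table(ind_inc, included.iloc[0:0], cfg.traits)
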