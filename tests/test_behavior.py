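"""Behavioral battery scoring and dissociation GLMs."""

import math

import numpy as np
import pandas as pd
import pytest

import flowcpm as fc
from flowcpm import CollinearityError, DegenerateDataError
from flowcpm.synthetic import CohortSpec, make_cohort


def ratings_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "item_id", "response_index", "rater",
            "novelty", "appropriateness",
        ],
    )


class TestAggregateAut:
    def test_two_participant_hand_zscore(self):
        rows = [
            ("p1", "brick", 1, 1, 2, 3),
            ("p2", "brick", 1, 1, 4, 3.5),
        ]
        out = fc.aggregate_aut(ratings_frame(rows))
        # novelty means {2, 4}: z = +/-0.7071 with the sample SD
        assert out.loc["p1", "novelty_z"] == pytest.approx(-0.70710678, abs=1e-6)
        assert out.loc["p2", "novelty_z"] == pytest.approx(0.70710678, abs=1e-6)

    def test_rater_permutation_invariance(self):
        rows = []
        for i, pid in enumerate(("p1", "p2", "p3")):
            for j, item in enumerate(("brick", "can")):
                for rater in (1, 2, 3):
                    # deterministic, participant-varying 1-5 ratings
                    nov = 1 + (i + j + rater) % 5
                    app = 1 + (2 * i + rater) % 5
                    rows.append((pid, item, 1, rater, nov, app))
        frame = ratings_frame(rows)
        permuted = frame.copy()
        permuted["rater"] = permuted["rater"].map({1: 3, 2: 1, 3: 2})
        assert np.allclose(
            fc.aggregate_aut(frame).to_numpy(),
            fc.aggregate_aut(permuted).to_numpy(),
        )

    def test_clone_cohort_is_degenerate(self):
        rows = [(p, "brick", 1, 1, 3, 3) for p in ("p1", "p2", "p3")]
        with pytest.raises(DegenerateDataError):
            fc.aggregate_aut(ratings_frame(rows))

    def test_missing_item_excluded(self):
        rows = [
            ("p1", "brick", 1, 1, 2, 3), ("p1", "can", 1, 1, 3, 2),
            ("p2", "brick", 1, 1, 4, 4), ("p2", "can", 1, 1, 2, 5),
            ("p3", "brick", 1, 1, 5, 1),  # never rated on "can"
        ]
        out = fc.aggregate_aut(ratings_frame(rows))
        assert list(out.index) == ["p1", "p2"]

    def test_out_of_scale_rating_rejected(self):
        rows = [("p1", "brick", 1, 1, 6, 3), ("p2", "brick", 1, 1, 2, 3)]
        with pytest.raises(ValueError):
            fc.aggregate_aut(ratings_frame(rows))


class TestCronbachAlpha:
    def test_identical_raters_give_one(self):
        col = np.array([1.0, 2.5, 4.0, 3.0])
        assert fc.cronbach_alpha(np.column_stack([col, col, col])) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self, rng):
        x = rng.standard_normal((4000, 3))
        assert abs(fc.cronbach_alpha(x)) < 0.1

    def test_worked_table_matches_direct_formula(self):
        x = np.array(
            [[2, 3, 3], [4, 4, 5], [1, 2, 1], [3, 5, 4]], dtype=float
        )
        k = 3
        expected = k / (k - 1) * (
            1 - x.var(axis=0, ddof=1).sum() / x.sum(axis=1).var(ddof=1)
        )
        assert fc.cronbach_alpha(x) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            fc.cronbach_alpha(np.ones((5, 3)))
        with pytest.raises(ValueError):
            fc.cronbach_alpha(np.ones((2, 3)))


class TestScoreNback:
    def test_all_correct(self):
        t = pd.DataFrame({"rt": [500.0] * 6, "correct": True, "responded": True})
        assert fc.score_nback(t) == (500.0, 1.0)

    def test_half_incorrect(self):
        t = pd.DataFrame(
            {
                "rt": [400.0, 400.0, 700.0, 700.0],
                "correct": [True, True, False, False],
                "responded": True,
            }
        )
        assert fc.score_nback(t) == (400.0, 0.5)

    def test_no_response_excluded_from_acc(self):
        t = pd.DataFrame(
            {
                "rt": [300.0, 500.0, np.nan, 400.0],
                "correct": [True, False, False, True],
                "responded": [True, True, False, True],
            }
        )
        rt, acc = fc.score_nback(t)
        assert rt == pytest.approx((300 + 400) / 2)
        assert acc == pytest.approx(2 / 3)

    def test_unusable_table_gives_missing_marker(self):
        t = pd.DataFrame({"rt": [1.0], "correct": [False], "responded": [False]})
        rt, acc = fc.score_nback(t)
        assert math.isnan(rt) and math.isnan(acc)


def sorted_quantile_oracle(go_rts, p):
    """Nearest-rank quantile by explicit sorted-list indexing."""
    s = sorted(go_rts)
    k = math.ceil(p * len(s))
    return s[max(k, 1) - 1]


class TestSsrtIntegration:
    def test_flat_distribution(self):
        assert fc.ssrt_integration([500.0] * 10, {200.0: (10, 5)}) == pytest.approx(300.0)

    def test_single_ssd_quantile(self):
        go = [400, 450, 500, 550, 600]
        expected = sorted_quantile_oracle(go, 0.4) - 180
        assert fc.ssrt_integration(go, {180.0: (10, 4)}) == pytest.approx(expected)

    def test_two_ssd_average(self):
        go = [400, 450, 500, 550, 600]
        v1 = sorted_quantile_oracle(go, 0.4) - 180
        v2 = sorted_quantile_oracle(go, 0.8) - 260
        est = fc.ssrt_integration(go, {180.0: (10, 4), 260.0: (10, 8)})
        assert est == pytest.approx((v1 + v2) / 2)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            go = rng.normal(500, 80, size=int(rng.integers(20, 200)))
            ssds = rng.choice([140, 180, 220, 260, 320], size=2, replace=False)
            stop = {}
            per_ssd = []
            for ssd in ssds:
                n_stop = int(rng.integers(4, 30))
                n_resp = int(rng.integers(1, n_stop + 1))
                stop[float(ssd)] = (n_stop, n_resp)
                per_ssd.append(
                    sorted_quantile_oracle(go, n_resp / n_stop) - float(ssd)
                )
            assert fc.ssrt_integration(go, stop) == pytest.approx(
                np.mean(per_ssd), abs=1e-9
            )

    def test_zero_respond_ssd_skipped(self):
        go = [400.0, 500.0, 600.0]
        with_skip = fc.ssrt_integration(go, {140.0: (8, 0), 220.0: (8, 4)})
        only_valid = fc.ssrt_integration(go, {220.0: (8, 4)})
        assert with_skip == pytest.approx(only_valid)
        assert math.isnan(fc.ssrt_integration(go, {140.0: (8, 0)}))


class TestScoreSwitch:
    def _table(self):
        return pd.DataFrame(
            {
                "trial_type": ["switch"] * 4 + ["repeat"] * 4,
                "rt": [900, 900, 950, 850, 800, 820, 780, 800],
                "correct": [True, True, False, True, True, True, True, False],
                "responded": True,
            }
        )

    def test_cost_and_acc(self):
        cost, acc = fc.score_switch(self._table())
        # correct-only RTs: switch (900+900+850)/3, repeat (800+820+780)/3
        assert cost == pytest.approx(883.3333 - 800.0, abs=1e-3)
        assert acc == pytest.approx((0.75 + 0.75) / 2)

    def test_simple_means(self):
        t = pd.DataFrame(
            {
                "trial_type": ["switch", "repeat"],
                "rt": [900.0, 800.0],
                "correct": True,
                "responded": True,
            }
        )
        cost, acc = fc.score_switch(t)
        assert cost == pytest.approx(100.0)
        assert acc == pytest.approx(1.0)

    def test_missing_type_marker(self):
        t = pd.DataFrame(
            {"trial_type": ["switch"], "rt": [900.0], "correct": [True],
             "responded": [True]}
        )
        cost, acc = fc.score_switch(t)
        assert math.isnan(cost) and math.isnan(acc)


class TestExecutiveComposites:
    def _scores(self):
        return pd.DataFrame(
            {
                "nback_rt": [500.0, 520.0, 540.0],
                "ssrt": [240.0, 250.0, 290.0],
                "switch_cost_rt": [90.0, 120.0, 100.0],
                "nback_acc": [0.9, 0.85, 0.95],
                "stop_acc": [0.8, 0.9, 0.85],
                "switch_acc": [0.88, 0.92, 0.8],
            },
            index=["p1", "p2", "p3"],
        )

    def test_matches_hand_z_then_mean(self):
        scores = self._scores()
        out = fc.executive_composites(scores)

        def z(col):
            return (col - col.mean()) / col.std(ddof=1)

        hand_rt = (
            z(scores["nback_rt"]) + z(scores["ssrt"]) + z(scores["switch_cost_rt"])
        ) / 3
        assert np.allclose(out["ef_rt_z"], hand_rt)

    def test_composite_mean_zero(self):
        out = fc.executive_composites(self._scores())
        assert abs(out["ef_rt_z"].mean()) < 1e-10
        assert abs(out["ef_acc_z"].mean()) < 1e-10

    def test_column_order_invariance(self):
        scores = self._scores()
        shuffled = scores[list(scores.columns[::-1])]
        assert np.allclose(
            fc.executive_composites(scores).to_numpy(),
            fc.executive_composites(shuffled).to_numpy(),
        )

    def test_listwise_exclusion_of_missing(self):
        scores = self._scores()
        scores.loc["p4"] = [510.0, np.nan, 95.0, 0.9, 0.9, 0.9]
        out = fc.executive_composites(scores)
        assert "p4" not in out.index

    def test_zero_variance_column_raises(self):
        scores = self._scores()
        scores["ssrt"] = 250.0
        with pytest.raises(DegenerateDataError):
            fc.executive_composites(scores)


class TestExcludeOutliers:
    def test_identity_when_all_within_limit(self):
        table = make_cohort(CohortSpec(n_participants=50, seed=3))
        clipped = table.copy()
        for col in ("novelty_z", "appropriateness_z", "assoc_z", "ef_rt_z", "ef_acc_z"):
            clipped[col] = np.clip(clipped[col], -2.9, 2.9)
        kept, log = fc.exclude_outliers(clipped)
        assert len(kept) == 50 and len(log) == 0

    def test_planted_outlier_removed(self):
        table = make_cohort(CohortSpec(n_participants=50, seed=3))
        table.iloc[7, table.columns.get_loc("assoc_z")] = 5.0
        kept, log = fc.exclude_outliers(table)
        assert table.index[7] not in kept.index
        assert set(log["participant"]) == {table.index[7]}

    def test_seven_planted_outliers_leave_93(self, rng):
        table = make_cohort(CohortSpec(n_participants=100, seed=4))
        for col in ("novelty_z", "appropriateness_z", "assoc_z", "ef_rt_z", "ef_acc_z"):
            table[col] = np.clip(table[col], -2.9, 2.9)
        hit = rng.choice(100, size=7, replace=False)
        for i in hit:
            table.iloc[i, table.columns.get_loc("novelty_z")] = 4.0 + i / 100
        kept, log = fc.exclude_outliers(table)
        assert len(kept) == 93
        assert len(set(log["participant"])) == 7


class TestDissociationGlm:
    def test_pure_noise_outcome_is_null(self):
        table = make_cohort(
            CohortSpec(
                n_participants=2000, beta_assoc_nov=0.0, beta_ef_app=0.0,
                beta_assoc_app=0.0, seed=21,
            )
        )
        res = fc.dissociation_glm(table, "novelty", model="1")
        assert (res.table["p_bonferroni"] > 0.05).all()

    def test_recovers_planted_effect(self):
        table = make_cohort(CohortSpec(n_participants=2000, seed=22))
        res = fc.dissociation_glm(table, "novelty", model="1")
        beta = res["assoc_z"]["beta"]
        assert beta == pytest.approx(0.12, abs=0.06)
        assert res["assoc_z"]["p_bonferroni"] < 0.001

    def test_duplicated_predictor_raises_collinearity(self):
        table = make_cohort(CohortSpec(n_participants=100, seed=5))
        table["ef_acc_z"] = table["ef_rt_z"]
        with pytest.raises(CollinearityError):
            fc.dissociation_glm(table, "novelty", model="1")

    def test_standardized_fit_invariant_to_raw_rescaling(self):
        # z-scoring upstream removes any affine transformation of raw scores
        table = make_cohort(CohortSpec(n_participants=300, seed=6))
        rescaled = table.copy()
        raw = 3.7 * table["assoc_z"] + 11.0
        rescaled["assoc_z"] = (raw - raw.mean()) / raw.std(ddof=1)
        a = fc.dissociation_glm(table, "appropriateness", model="1")
        b = fc.dissociation_glm(rescaled, "appropriateness", model="1")
        assert np.allclose(a.table["beta"], b.table["beta"], atol=1e-10)

    def test_interaction_and_covariate_models(self):
        table = make_cohort(CohortSpec(n_participants=300, seed=7))
        res_x = fc.dissociation_glm(table, "novelty", model="1x")
        assert "assoc_z:ef_rt_z" in res_x.table.index
        res_2 = fc.dissociation_glm(table, "novelty", model="2")
        assert {"gender", "age", "handedness"} <= set(res_2.table.index)
        n, p = 300, len(res_2.table)
        assert res_2.table["df"].iloc[0] == pytest.approx(n - p - 1)

    def test_bonferroni_is_clipped_product(self):
        table = make_cohort(CohortSpec(n_participants=200, seed=8))
        res = fc.dissociation_glm(table, "novelty", model="1", family_size=4)
        expected = np.minimum(1.0, res.table["p_raw"] * 4)
        assert np.allclose(res.table["p_bonferroni"], expected)
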