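"""Reduction arithmetic, subgroup analyses, importances, dossiers, report."""

import numpy as np
import pandas as pd
import pytest

import bprx
from bprx.cohort import modeling_table
from bprx.evaluation import (
    aggregate_importance,
    deprescribing_analysis,
    evaluate_split,
    export_dossiers,
    naive_initiation_analysis,
    neighborhood_profiles,
    percent_improvement,
    repeated_splits,
)
from bprx.neighbors import CounterfactualPanel
from bprx.policy import Recommendation
from bprx.regression import FittedRegressor
from bprx.synthetic import CURRENT_OPTION


class TestPercentImprovement:
    def test_identity_is_zero(self):
        assert percent_improvement(-9.3, -9.3) == 0.0

    def test_direction(self):
        assert percent_improvement(-10.0, -8.0) == pytest.approx(25.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            percent_improvement(-10.0, 0.0)


def _mini_setting():
    """Two hand-built visits with panels and recommendations."""
    visits = pd.DataFrame(
        [
            {"visit_id": 1, "patient_id": 1, "period_index": 0, "period_start": 0,
             "regimen": "ACEi", "current_sbp": 150.0, "future_sbp": 147.0,
             "prior_exposure": True, "age": 60.0, "diabetes": 0,
             "systolic_hf": 0, "athero_hd": 0, "pvd": 0},
            {"visit_id": 2, "patient_id": 2, "period_index": 0, "period_start": 0,
             "regimen": "CCB+Thiazide", "current_sbp": 160.0, "future_sbp": 150.0,
             "prior_exposure": True, "age": 70.0, "diabetes": 1,
             "systolic_hf": 0, "athero_hd": 0, "pvd": 0},
        ]
    )
    p1 = CounterfactualPanel(
        visit_id=1, regimen="ACEi",
        predictions={"ACEi": 144.0, "CCB": 136.0, CURRENT_OPTION: 144.0},
        current_alias="ACEi",
    )
    p2 = CounterfactualPanel(
        visit_id=2, regimen="CCB+Thiazide",
        predictions={"CCB": 149.0, "Thiazide": 151.0, CURRENT_OPTION: 152.0},
    )
    r1 = Recommendation(visit_id=1, probabilities={"CCB": 1.0}, chosen="CCB",
                        excluded={}, kept_current=False)
    r2 = Recommendation(visit_id=2, probabilities={CURRENT_OPTION: 1.0},
                        chosen=CURRENT_OPTION, excluded={}, kept_current=True)
    return visits, [p1, p2], [r1, r2]


class TestEvaluateSplit:
    def test_reduction_arithmetic(self):
        visits, panels, recs = _mini_setting()
        red = evaluate_split(visits, panels, recs).set_index("visit_id")
        assert red.loc[1, "model_reduction"] == pytest.approx(-14.0)  # 136 - 150
        assert red.loc[1, "soc_reduction"] == pytest.approx(-3.0)
        assert red.loc[1, "current_reduction"] == pytest.approx(-6.0)

    def test_keeping_current_equates_model_and_current(self):
        visits, panels, recs = _mini_setting()
        red = evaluate_split(visits, panels, recs).set_index("visit_id")
        assert red.loc[2, "model_reduction"] == red.loc[2, "current_reduction"]

    def test_missing_panel_names_visit(self):
        visits, panels, recs = _mini_setting()
        with pytest.raises(KeyError, match="2"):
            evaluate_split(visits, panels[:1], recs)

    def test_truth_based_reductions_join(self, small_cohort, small_split, drlr_split_result):
        red = drlr_split_result["reductions"]
        assert red["truth_model_reduction"].notna().mean() > 0.9
        # keeping current means the truth columns coincide too
        kept = red[red["kept_current"]]
        sub = kept.dropna(subset=["truth_model_reduction", "truth_current_reduction"])
        assert np.allclose(sub["truth_model_reduction"], sub["truth_current_reduction"])


class TestDeprescribing:
    def test_toy_three_of_four_better(self):
        visits = pd.DataFrame(
            [
                {"visit_id": i, "patient_id": i, "period_index": 0, "period_start": 0,
                 "regimen": "ACEi+CCB", "current_sbp": 150.0, "future_sbp": 150.0,
                 "prior_exposure": True, "age": 60 + i, "diabetes": i % 2,
                 "systolic_hf": 0, "athero_hd": 0, "pvd": 0}
                for i in range(4)
            ]
        )
        red = pd.DataFrame(
            {
                "visit_id": [0, 1, 2, 3],
                "model_reduction": [-10.0, -10.0, -10.0, -2.0],
                "soc_reduction": [-5.0, -5.0, -5.0, -5.0],
                "current_reduction": [-4.0] * 4,
            }
        )
        out = deprescribing_analysis(visits, red)
        assert out["n_combo_visits"] == 4
        assert out["n_better"] == 3
        assert out["fraction_better_pct"] == pytest.approx(75.0)

    def test_empty_subgroup(self):
        visits, panels, recs = _mini_setting()
        mono = visits[visits.regimen == "ACEi"]
        red = evaluate_split(mono, panels[:1], recs[:1])
        out = deprescribing_analysis(mono, red)
        assert out["n_combo_visits"] == 0 and out["n_better"] == 0

    def test_fraction_definition_on_pipeline_output(self, small_split, drlr_split_result):
        _, _, test = small_split
        out = deprescribing_analysis(modeling_table(test), drlr_split_result["reductions"])
        if out["n_combo_visits"]:
            assert out["fraction_better_pct"] == pytest.approx(
                100.0 * out["n_better"] / out["n_combo_visits"]
            )
            assert set(out["profile"]["group"]) == {"all_test_visits", "effective_deprescribing"}


class TestProfiles:
    def test_pooled_percentage_definition(self):
        train = pd.DataFrame(
            {
                "visit_id": range(10),
                "patient_id": range(10),
                "age": 60.0,
                "current_sbp": 150.0,
                "female": [1] * 10,
                "race_black": [0] * 10,
                "race_white": [0] * 10,
                "diabetes": [1] * 7 + [0] * 3,
                "future_sbp": 140.0,
            }
        )
        panel = CounterfactualPanel(
            visit_id=99, regimen="", predictions={"ARB": 135.0},
            neighbor_ids={"ARB": np.arange(10)},
        )
        rec = Recommendation(visit_id=99, probabilities={"ARB": 1.0}, chosen="ARB",
                             excluded={}, kept_current=False)
        baseline = train.assign(prior_exposure=False)
        prof = neighborhood_profiles([rec], [panel], train, baseline)
        arb = prof[prof["class"] == "ARB"].iloc[0]
        assert arb["diabetes_pct"] == pytest.approx(70.0)
        assert arb["female_pct"] == pytest.approx(100.0)
        assert arb["n_pooled"] == 10

    def test_pipeline_profiles_have_baseline_row(self, small_split, drlr_split_result):
        train, _, test = small_split
        prof = neighborhood_profiles(
            drlr_split_result["recs"], drlr_split_result["panels"],
            modeling_table(train), test,
        )
        assert "test_set_baseline" in set(prof["class"])
        pcts = prof.filter(like="_pct").to_numpy(dtype=float)
        finite = pcts[np.isfinite(pcts)]
        assert ((finite >= 0) & (finite <= 100)).all()


class TestImportance:
    def _model(self, coefs, names):
        return FittedRegressor(drug_class="x", algorithm="DRLR",
                               coef_=np.array(coefs, dtype=float), intercept_=0.0,
                               feature_names=names)

    def test_two_orthogonal_models_average_to_half(self):
        names = ["a", "b"]
        out = aggregate_importance([self._model([1, 0], names), self._model([0, 1], names)])
        assert dict(zip(out["feature"], out["score"])) == {"a": 0.5, "b": 0.5}

    def test_everywhere_zero_feature_ranked_last(self):
        names = ["a", "b", "c"]
        out = aggregate_importance(
            [self._model([2, 1, 0], names), self._model([1, 3, 0], names)]
        )
        assert out.iloc[-1]["feature"] == "c" and out.iloc[-1]["score"] == 0.0

    def test_scores_sum_to_one(self):
        rng = np.random.default_rng(0)
        names = list("abcde")
        models = [self._model(rng.normal(size=5), names) for _ in range(4)]
        assert aggregate_importance(models)["score"].sum() == pytest.approx(1.0)

    def test_schema_mismatch_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            aggregate_importance(
                [self._model([1, 0], ["a", "b"]), self._model([1, 0], ["a", "c"])]
            )


class TestNaiveInitiation:
    def test_shares_sum_to_hundred(self, small_split, drlr_split_result):
        _, _, test = small_split
        out = naive_initiation_analysis(
            modeling_table(test), drlr_split_result["recs"], drlr_split_result["reductions"]
        )
        if out["n_naive_visits"]:
            assert sum(out["class_shares_pct"].values()) == pytest.approx(100.0)

    def test_prior_exposure_excluded(self):
        visits = pd.DataFrame(
            [
                {"visit_id": 0, "patient_id": 0, "period_index": 1, "period_start": 90,
                 "regimen": "", "current_sbp": 150.0, "future_sbp": 145.0,
                 "prior_exposure": True, "diabetes": 0},
                {"visit_id": 1, "patient_id": 1, "period_index": 0, "period_start": 0,
                 "regimen": "", "current_sbp": 150.0, "future_sbp": 145.0,
                 "prior_exposure": False, "diabetes": 0},
            ]
        )
        recs = [
            Recommendation(visit_id=i, probabilities={"CCB": 1.0}, chosen="CCB",
                           excluded={}, kept_current=False)
            for i in (0, 1)
        ]
        out = naive_initiation_analysis(visits, recs)
        assert out["n_naive_visits"] == 1

    def test_toy_share(self):
        visits = pd.DataFrame(
            [
                {"visit_id": i, "patient_id": i, "period_index": 0, "period_start": 0,
                 "regimen": "", "current_sbp": 150.0, "future_sbp": 145.0,
                 "prior_exposure": False, "diabetes": 0}
                for i in range(10)
            ]
        )
        recs = [
            Recommendation(visit_id=i, probabilities={}, chosen="Thiazide" if i < 6 else "CCB",
                           excluded={}, kept_current=False)
            for i in range(10)
        ]
        out = naive_initiation_analysis(visits, recs)
        assert out["class_shares_pct"]["Thiazide"] == pytest.approx(60.0)


class TestDossiers:
    def test_sample_size_and_determinism(self, small_split, drlr_split_result):
        _, _, test = small_split
        recs, panels = drlr_split_result["recs"], drlr_split_result["panels"]
        n = min(25, len(recs))
        a = export_dossiers(recs, panels, modeling_table(test), None, n=n, seed=3)
        b = export_dossiers(recs, panels, modeling_table(test), None, n=n, seed=3)
        assert len(a) == n
        assert [d["visit_id"] for d in a] == [d["visit_id"] for d in b]

    def test_chosen_never_in_exclusions(self, small_split, drlr_split_result):
        _, _, test = small_split
        recs, panels = drlr_split_result["recs"], drlr_split_result["panels"]
        docs = export_dossiers(recs, panels, modeling_table(test), None,
                               n=min(50, len(recs)), seed=1)
        for d in docs:
            assert d["chosen"] not in d["exclusions"]

    def test_oversized_request_rejected(self, small_split, drlr_split_result):
        _, _, test = small_split
        recs, panels = drlr_split_result["recs"], drlr_split_result["panels"]
        with pytest.raises(ValueError, match="only"):
            export_dossiers(recs, panels, modeling_table(test), None,
                            n=len(recs) + 1, seed=0)


_ALGO_PARAMS = {"DRLR": {"epsilon": 0.01}, "LASSO": {"lam": 0.01}, "CART": {"max_depth": 4}}


@pytest.fixture(scope="module")
def tiny_report(small_visits, small_cohort):
    return repeated_splits(
        small_visits, algorithms=("LASSO", "CART", "OLS", "DRLR"),
        modes=("deterministic", "randomized"), n_splits=2, seed=0, k=15,
        truth=small_cohort.truth, algo_params=_ALGO_PARAMS,
    )


class TestRepeatedSplits:
    def test_report_rows_cover_algorithm_grid(self, tiny_report):
        rows = set(zip(tiny_report.table["algorithm"], tiny_report.table["mode"]))
        for algo in ("LASSO", "CART", "OLS+KNN", "DRLR+KNN"):
            for mode in ("deterministic", "randomized"):
                assert (algo, mode) in rows
        assert ("Current regimen", "-") in rows and ("Standard of care", "-") in rows

    def test_every_mean_has_visit_count(self, tiny_report):
        assert (tiny_report.table["n_visits"] > 0).all()

    def test_determinism(self, small_visits, small_cohort, tiny_report):
        again = repeated_splits(
            small_visits, algorithms=("LASSO", "CART", "OLS", "DRLR"),
            modes=("deterministic", "randomized"), n_splits=2, seed=0, k=15,
            truth=small_cohort.truth, algo_params=_ALGO_PARAMS,
        )
        pd.testing.assert_frame_equal(tiny_report.table, again.table)

    def test_rejects_single_split(self, small_visits):
        with pytest.raises(ValueError, match="2 splits"):
            repeated_splits(small_visits, n_splits=1)
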