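"""Classifier fitting, prediction, consistency rules, model objects."""

import numpy as np
import pytest

import somnoscore as sc
from somnoscore.features import FeatureMatrix
from somnoscore.model import (
    ConsistencyRules,
    StageModel,
    apply_consistency_rules,
    fit_stage_model,
    load_model,
    predict_hypnogram,
    save_model,
)
from somnoscore.training import TrainingSet


def _separable_fixture(n_per=40, seed=0):
    """Two well-separated Gaussian clusters labelled W / NREM."""
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(-3.0, 0.3, size=(n_per, 4)),
        rng.normal(+3.0, 0.3, size=(n_per, 4)),
    ])
    fm = FeatureMatrix(values=X, names=[f"f{i}" for i in range(4)])
    ts = TrainingSet(
        epochs={
            "W": [("r", i) for i in range(n_per)],
            "NREM": [("r", n_per + i) for i in range(n_per)],
            "REM": [],
        },
        seed=0,
    )
    return fm, ts


class TestFitPredict:
    def test_separable_training_epochs_perfectly_recovered(self):
        fm, ts = _separable_fixture()
        model = fit_stage_model(fm, ts, "r", sc.ANIMAL_VOCABULARY, seed=1)
        grid = sc.EpochGrid(4.0, fm.n_epochs)
        hyp, scores = predict_hypnogram(model, fm, grid)
        assert list(hyp.labels[:40]) == ["W"] * 40
        assert list(hyp.labels[40:]) == ["NREM"] * 40
        np.testing.assert_allclose(scores.sum(axis=1), 1.0)

    def test_fit_is_deterministic_given_seed(self):
        fm, ts = _separable_fixture()
        grid = sc.EpochGrid(4.0, fm.n_epochs)
        runs = [
            predict_hypnogram(fit_stage_model(fm, ts, "r", sc.ANIMAL_VOCABULARY, seed=9),
                              fm, grid)[1]
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_single_class_training_rejected(self):
        fm, ts = _separable_fixture()
        ts_single = TrainingSet(epochs={"W": ts.epochs["W"]}, seed=0)
        with pytest.raises(ValueError, match="two stages"):
            fit_stage_model(fm, ts_single, "r", sc.ANIMAL_VOCABULARY)

    def test_out_of_range_training_index_rejected(self):
        fm, ts = _separable_fixture()
        bad = TrainingSet(epochs={"W": [("r", 0)], "NREM": [("r", 10_000)]}, seed=0)
        with pytest.raises(ValueError, match="outside"):
            fit_stage_model(fm, bad, "r", sc.ANIMAL_VOCABULARY)

    def test_feature_name_mismatch_rejected_at_prediction(self):
        fm, ts = _separable_fixture()
        model = fit_stage_model(fm, ts, "r", sc.ANIMAL_VOCABULARY)
        other = FeatureMatrix(values=fm.values, names=[f"g{i}" for i in range(4)])
        with pytest.raises(ValueError, match="feature names"):
            model.predict_scores(other)

    def test_score_ties_break_to_earlier_vocabulary_label(self):
        class _Stub:
            classes_ = np.array(["NREM", "W"])

            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        fm = FeatureMatrix(values=np.zeros((3, 2)), names=["a", "b"])
        model = StageModel(_Stub(), ["a", "b"], sc.ANIMAL_VOCABULARY, seed=0)
        hyp, _ = predict_hypnogram(model, fm, sc.EpochGrid(4.0, 3))
        assert list(hyp.labels) == ["W", "W", "W"]  # W precedes NREM

    def test_model_serialization_round_trip(self, tmp_path):
        fm, ts = _separable_fixture()
        model = fit_stage_model(fm, ts, "r", sc.ANIMAL_VOCABULARY, seed=3)
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        np.testing.assert_array_equal(back.predict_scores(fm), model.predict_scores(fm))


def _uniform_scores(n, k):
    return np.full((n, k), 1.0 / k)


class TestConsistencyRules:
    def test_seconds_convert_to_epochs_by_ceiling(self):
        rules = ConsistencyRules({"W": 4.0, "NREM": 8.0, "REM": 8.0})
        assert rules.min_epochs(4.0) == {"W": 1, "NREM": 2, "REM": 2}
        assert ConsistencyRules({"REM": 12.0}).min_epochs(4.0) == {"REM": 3}
        assert ConsistencyRules({"REM": 9.0}).min_epochs(4.0) == {"REM": 3}

    def test_single_violating_bout_merges_into_neighbour(self, animal_hypnogram):
        hyp = animal_hypnogram(["NREM", "NREM", "REM", "NREM", "NREM"])
        scores = np.array([
            [0.1, 0.8, 0.1], [0.1, 0.8, 0.1], [0.1, 0.5, 0.4],
            [0.1, 0.8, 0.1], [0.1, 0.8, 0.1],
        ])
        out = apply_consistency_rules(hyp, ConsistencyRules({"REM": 8.0}), scores)
        assert list(out.labels) == ["NREM"] * 5

    def test_twelve_second_threshold_removes_short_bouts(self, animal_hypnogram):
        labels = ["W"] * 6 + ["NREM"] * 2 + ["W"] * 6 + ["REM"] * 4
        hyp = animal_hypnogram(labels)
        out = apply_consistency_rules(
            hyp, ConsistencyRules.mouse(), _uniform_scores(len(labels), 3)
        )
        from somnoscore.bouts import segment_bouts

        assert all(b.length >= 3 for b in segment_bouts(out))
        assert list(out.labels[6:8]) == ["W", "W"]  # 8 s NREM bout absorbed

    def test_unit_minima_are_identity(self, animal_hypnogram):
        hyp = animal_hypnogram(["W", "REM", "NREM", "REM"])
        out = apply_consistency_rules(
            hyp, ConsistencyRules({"W": 4.0, "NREM": 4.0, "REM": 4.0}),
            _uniform_scores(4, 3),
        )
        assert list(out.labels) == list(hyp.labels)

    def test_relabelling_follows_higher_scoring_neighbour(self, animal_hypnogram):
        hyp = animal_hypnogram(["W", "W", "REM", "NREM", "NREM"])
        scores = np.zeros((5, 3))
        scores[2] = [0.1, 0.45, 0.45]  # NREM outranks W on the violating epoch
        out = apply_consistency_rules(hyp, ConsistencyRules({"REM": 8.0}), scores)
        assert list(out.labels) == ["W", "W", "NREM", "NREM", "NREM"]

    @pytest.mark.parametrize("seed", range(6))
    def test_no_subminimum_bouts_and_no_new_stages(self, seed, animal_hypnogram):
        rng = np.random.default_rng(seed)
        labels = rng.choice(["W", "NREM", "REM"], size=200).tolist()
        hyp = animal_hypnogram(labels)
        scores = rng.dirichlet(np.ones(3), size=200)
        rules = ConsistencyRules({"W": 4.0, "NREM": 8.0, "REM": 8.0})
        out = apply_consistency_rules(hyp, rules, scores)
        from somnoscore.bouts import segment_bouts

        minima = rules.min_epochs(4.0)
        assert all(b.length >= minima.get(b.stage, 1) for b in segment_bouts(out))
        assert set(out.labels) <= set(hyp.labels)


class TestSleepStager:
    def test_end_to_end_recovery_on_separated_synthetic_data(self, rodent_pair):
        rec, hyp = rodent_pair
        stager = sc.SleepStager(rec, hyp, rules=ConsistencyRules.rodent())
        res = stager.fit(size_per_stage=30, seed=3)
        report = res.evaluate()
        for stage in ("W", "NREM", "REM"):
            assert report.stage_f(stage) >= 0.9

    def test_training_epochs_excluded_from_evaluation_by_default(self, rodent_pair):
        rec, hyp = rodent_pair
        res = sc.SleepStager(rec, hyp).fit(size_per_stage=30, seed=3)
        rep_excl = res.evaluate()
        rep_incl = res.evaluate(include_training=True)
        assert rep_incl.n_evaluated - rep_excl.n_evaluated == 90

    def test_results_summary_mentions_configuration(self, rodent_pair):
        rec, hyp = rodent_pair
        res = sc.SleepStager(rec, hyp).fit(size_per_stage=20, seed=0)
        text = res.summary()
        assert rec.id in text and "overall" in text

    def test_epoch_length_disagreement_rejected(self, rodent_pair):
        rec, hyp = rodent_pair
        with pytest.raises(ValueError):
            sc.SleepStager(rec, hyp, epoch_length=30.0)
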