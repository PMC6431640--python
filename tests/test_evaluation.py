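"""Agreement scoring: F-measure, ratings, effect sizes, reclassification,
transition exclusion, group comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import somnoscore as sc
from somnoscore.evaluation import (
    GroupSummary,
    ReclassScheme,
    compare_groups,
    confusion_counts,
    evaluate,
    f_measure,
    hedges_g,
    macro_f,
    overall_f,
    rate_f,
    reclassify,
)


class TestConfusionCounts:
    def test_identity_prediction(self, animal_hypnogram):
        hyp = animal_hypnogram(["W", "NREM", "REM", "W", "NREM"] * 2)
        counts = confusion_counts(hyp, hyp)
        assert all(fp == 0 and fn == 0 for _, fp, fn in counts.counts.values())
        assert sum(tp for tp, _, _ in counts.counts.values()) == 10

    def test_hand_counted_three_epoch_example(self, animal_hypnogram):
        ref = animal_hypnogram(["W", "W", "REM"])
        pred = animal_hypnogram(["W", "REM", "REM"])
        counts = confusion_counts(pred, ref)
        assert counts.counts["W"] == (1, 0, 1)
        assert counts.counts["REM"] == (1, 1, 0)

    def test_exclusion_removes_the_disputed_epoch(self, animal_hypnogram):
        ref = animal_hypnogram(["W", "W", "REM"])
        pred = animal_hypnogram(["W", "REM", "REM"])
        counts = confusion_counts(pred, ref, {1})
        assert counts.counts["W"] == (1, 0, 0)
        assert counts.counts["REM"] == (1, 0, 0)
        assert counts.n_evaluated == 2

    def test_reference_artifacts_always_excluded(self, animal_hypnogram):
        ref = animal_hypnogram(["W", sc.ARTIFACT, "REM"])
        pred = animal_hypnogram(["W", "W", "W"])
        counts = confusion_counts(pred, ref)
        assert counts.n_evaluated == 2
        assert counts.counts["W"] == (1, 1, 0)

    def test_grid_mismatch_rejected(self, animal_hypnogram):
        a = animal_hypnogram(["W", "NREM"])
        b = animal_hypnogram(["W", "NREM", "REM"])
        with pytest.raises(ValueError, match="grid"):
            confusion_counts(a, b)

    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 120))
        stages = ("W", "NREM", "REM")
        pool = stages + (sc.ARTIFACT,)
        grid = sc.EpochGrid(4.0, n)
        ref = sc.Hypnogram(grid, sc.ANIMAL_VOCABULARY,
                           rng.choice(pool, size=n, p=[0.3, 0.3, 0.3, 0.1]))
        pred = sc.Hypnogram(grid, sc.ANIMAL_VOCABULARY, rng.choice(stages, size=n))
        excl = set(rng.choice(n, size=n // 5, replace=False).tolist())

        counts = confusion_counts(pred, ref, excl)
        for stage in stages:
            tp = fp = fn = 0
            for i in range(n):
                if i in excl or ref.labels[i] == sc.ARTIFACT:
                    continue
                if pred.labels[i] == stage and ref.labels[i] == stage:
                    tp += 1
                elif pred.labels[i] == stage:
                    fp += 1
                elif ref.labels[i] == stage:
                    fn += 1
            assert counts.counts[stage] == (tp, fp, fn)


class TestFMeasure:
    def test_hand_evaluated_formulas(self):
        assert f_measure(8, 2, 2) == (0.8, 0.8, pytest.approx(0.8))

    def test_zero_hit_guard(self):
        assert f_measure(0, 3, 5) == (0.0, 0.0, 0.0)
        assert f_measure(0, 0, 0) == (0.0, 0.0, 0.0)

    @given(st.floats(0.01, 1.0))
    def test_equal_sensitivity_precision_give_f_equal_to_both(self, x):
        tp = 1000
        fp = fn = int(tp * (1 - x) / x)
        s, p, f = f_measure(tp, fp, fn)
        assert f == pytest.approx(s) == pytest.approx(p)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_f_between_min_and_max_of_components(self, tp, fp, fn):
        s, p, f = f_measure(tp, fp, fn)
        assert 0.0 <= f <= 1.0
        if s + p > 0:
            assert min(s, p) - 1e-12 <= f <= max(s, p) + 1e-12

    def test_micro_overall_from_pooled_counts(self, animal_hypnogram):
        ref = animal_hypnogram(["W", "W", "REM"])
        pred = animal_hypnogram(["W", "REM", "REM"])
        assert overall_f(confusion_counts(pred, ref)) == pytest.approx(2 / 3)

    def test_micro_overall_equals_epoch_accuracy(self, animal_hypnogram):
        rng = np.random.default_rng(0)
        stages = ["W", "NREM", "REM"]
        ref = animal_hypnogram(rng.choice(stages, 300).tolist())
        pred = animal_hypnogram(rng.choice(stages, 300).tolist())
        acc = np.mean(np.asarray(ref.labels) == np.asarray(pred.labels))
        assert overall_f(confusion_counts(pred, ref)) == pytest.approx(acc)

    def test_macro_is_unweighted_stage_mean(self, animal_hypnogram):
        ref = animal_hypnogram(["W", "W", "REM"])
        pred = animal_hypnogram(["W", "REM", "REM"])
        counts = confusion_counts(pred, ref)
        per_stage = [f_measure(*counts.counts[s])[2] for s in ("W", "NREM", "REM")]
        assert macro_f(counts) == pytest.approx(np.mean(per_stage))


class TestRatings:
    @pytest.mark.parametrize("f,label", [
        (0.92, "intra-scorer"), (0.90, "intra-scorer"),
        (0.85, "excellent"), (0.849, "strong"), (0.80, "strong"),
        (0.75, "average"), (0.70, "average"), (0.69, "inadequate"), (0.0, "inadequate"),
    ])
    def test_band_boundaries_inclusive_upward(self, f, label):
        assert rate_f(f) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rate_f(1.2)


class TestHedgesG:
    def test_equal_means_miniscule(self):
        a = GroupSummary(1.0, 0.5, 8)
        assert hedges_g(a, a) == (0.0, "miniscule")

    def test_hand_evaluated_pooled_sd(self):
        g, mag = hedges_g(GroupSummary(1.0, 0.5, 8), GroupSummary(0.0, 0.5, 8))
        assert g == pytest.approx(2.0)
        assert mag == "large"

    def test_antisymmetry(self):
        a, b = GroupSummary(0.9, 0.1, 6), GroupSummary(0.7, 0.2, 6)
        g1, m1 = hedges_g(a, b)
        g2, m2 = hedges_g(b, a)
        assert g1 == pytest.approx(-g2) and m1 == m2

    def test_zero_pooled_sd_with_unequal_means_flagged(self):
        g, mag = hedges_g(GroupSummary(1.0, 0.0, 5), GroupSummary(0.0, 0.0, 5))
        assert np.isnan(g) and mag == "undefined"

    @pytest.mark.parametrize("g,mag", [
        (0.1, "miniscule"), (0.2, "small"), (0.49, "small"),
        (0.5, "medium"), (0.79, "medium"), (0.8, "large"),
    ])
    def test_magnitude_classes(self, g, mag):
        out, label = hedges_g(GroupSummary(g, 1.0, 50), GroupSummary(0.0, 1.0, 50))
        assert label == mag


class TestCompareGroups:
    def test_identical_paired_groups_flagged_degenerate(self):
        r = compare_groups([0.9, 0.8, 0.7], [0.9, 0.8, 0.7], paired=True)
        assert r.degenerate and r.g == 0.0 and not r.significant

    def test_constant_shift_gives_closed_form_g(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 2000)
        b = a + 0.5
        r = compare_groups(a, b, paired=False)
        assert r.g == pytest.approx(-0.5, abs=0.05)

    def test_bonferroni_adjusts_alpha_to_half(self):
        r = compare_groups([1.0, 2.0, 3.0], [1.1, 2.1, 3.3], paired=True,
                           n_comparisons=2)
        assert r.alpha == 0.025

    def test_paired_lengths_must_match(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [1, 2], paired=True)


class TestReclassification:
    def test_n1_to_n2(self, human_hypnogram):
        hyp = human_hypnogram(["W", "N1", "N2", "N3", "REM"])
        out = reclassify(hyp, ReclassScheme.N1_TO_N2)
        assert list(out.labels) == ["W", "N2", "N2", "N3", "REM"]
        assert out.vocabulary.labels == ("W", "N2", "N3", "REM")

    def test_n1_to_wake(self, human_hypnogram):
        out = reclassify(human_hypnogram(["W", "N1", "REM"]), ReclassScheme.N1_TO_WAKE)
        assert list(out.labels) == ["W", "W", "REM"]

    def test_w1nrem23_matches_rodent_style_staging(self, human_hypnogram):
        out = reclassify(human_hypnogram(["W", "N1", "N2", "N3", "REM"]),
                         ReclassScheme.W1NREM23)
        assert list(out.labels) == ["W", "W", "NREM", "NREM", "REM"]
        assert out.vocabulary.labels == ("W", "NREM", "REM")

    def test_nrem123_collapses_all_nrem_depths(self, human_hypnogram):
        out = reclassify(human_hypnogram(["W", "N1", "N2", "N3", "REM"]),
                         ReclassScheme.NREM123)
        assert list(out.labels) == ["W", "NREM", "NREM", "NREM", "REM"]

    def test_none_is_identity(self, human_hypnogram):
        hyp = human_hypnogram(["W", "N1"])
        assert reclassify(hyp, ReclassScheme.NONE) is hyp

    def test_artifacts_pass_through(self, human_hypnogram):
        out = reclassify(human_hypnogram(["N1", sc.ARTIFACT]), ReclassScheme.NREM123)
        assert list(out.labels) == ["NREM", sc.ARTIFACT]

    def test_animal_vocabulary_rejected(self, animal_hypnogram):
        with pytest.raises(ValueError, match="undefined"):
            reclassify(animal_hypnogram(["W", "NREM"]), ReclassScheme.N1_TO_N2)

    def test_reclassify_commutes_with_evaluation(self, human_hypnogram):
        rng = np.random.default_rng(5)
        stages = ["W", "N1", "N2", "N3", "REM"]
        ref = human_hypnogram(rng.choice(stages, 200).tolist())
        pred = human_hypnogram(rng.choice(stages, 200).tolist())
        via_option = evaluate(pred, ref, scheme=ReclassScheme.NREM123)
        premapped = evaluate(reclassify(pred, ReclassScheme.NREM123),
                             reclassify(ref, ReclassScheme.NREM123))
        assert via_option.overall_f == pytest.approx(premapped.overall_f)
        for stage in premapped.per_stage:
            assert via_option.per_stage[stage]["f"] == pytest.approx(
                premapped.per_stage[stage]["f"]
            )


class TestEvaluate:
    def test_perfect_agreement_all_ones(self, animal_hypnogram):
        hyp = animal_hypnogram(["W", "W", "W", "NREM", "NREM", "NREM", "REM", "REM", "REM"])
        for kwargs in ({}, {"exclude_transitions": True}):
            rep = evaluate(hyp, hyp, **kwargs)
            assert rep.overall_f == 1.0
            assert all(d["f"] == 1.0 or d["tp"] == 0 for d in rep.per_stage.values())

    def test_transition_exclusion_keeps_predicted_bout_interiors(self, animal_hypnogram):
        pred = animal_hypnogram(["W", "W", "NREM", "NREM", "NREM", "W"])
        ref = animal_hypnogram(["W", "NREM", "NREM", "NREM", "NREM", "W"])
        rep = evaluate(pred, ref, exclude_transitions=True)
        assert rep.n_evaluated == 1  # only the interior of the NREM bout
        assert rep.overall_f == 1.0

    def test_same_pair_without_exclusion_scores_five_sixths(self, animal_hypnogram):
        pred = animal_hypnogram(["W", "W", "NREM", "NREM", "NREM", "W"])
        ref = animal_hypnogram(["W", "NREM", "NREM", "NREM", "NREM", "W"])
        rep = evaluate(pred, ref)
        assert rep.overall_f == pytest.approx(5 / 6)

    def test_excluded_fraction_reported(self, animal_hypnogram):
        pred = animal_hypnogram(["W"] * 10)
        ref = animal_hypnogram(["W"] * 9 + [sc.ARTIFACT])
        rep = evaluate(pred, ref, exclude={0, 1})
        assert rep.excluded_fraction == pytest.approx(0.3)

    def test_report_serializes_to_frame_and_json(self, animal_hypnogram):
        hyp = animal_hypnogram(["W", "NREM", "REM"])
        rep = evaluate(hyp, hyp, provenance={"recording": "demo"})
        frame = rep.to_frame()
        assert set(frame["stage"]) == {"W", "NREM", "REM", "overall"}
        assert '"recording": "demo"' in rep.to_json()
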