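"""Profile evaluation: confusion metrics, distances, threshold sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mockbench as mb
from mockbench.evaluation import (
    DEFAULT_TARGET_FDRS,
    _candidate_thresholds,
    evaluate_profile,
)


def profile(mapping, **kwargs):
    return mb.AbundanceProfile(mapping, **kwargs)


class TestFilterProfile:
    def test_zero_threshold_is_identity(self):
        p = profile({"A": 5.0, "B": 0.001})
        assert mb.filter_profile(p, 0.0).abundances == p.abundances

    def test_species_at_threshold_retained(self):
        p = profile({"A": 0.01})
        assert mb.filter_profile(p, 0.01).abundances == {"A": 0.01}

    def test_below_threshold_removed_without_renormalizing(self):
        p = profile({"A": 5.0, "B": 0.005})
        filtered = mb.filter_profile(p, 0.01)
        assert filtered.abundances == {"A": 5.0}  # A keeps its original value


class TestConfusion:
    def test_perfect_prediction(self):
        t = profile({"A": 60.0, "B": 40.0})
        c = mb.confusion(t, t)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_one_swap(self):
        truth = profile({chr(65 + i): 10.0 for i in range(10)})  # A..J
        pred_species = {chr(65 + i): 10.0 for i in range(9)}  # drop J
        pred_species["K"] = 10.0
        c = mb.confusion(truth, profile(pred_species))
        assert (c.tp, c.fp, c.fn) == (9, 1, 1)

    def test_disjoint_sets(self):
        c = mb.confusion(profile({"A": 100.0}), profile({"Z": 100.0}))
        assert c.tp == 0 and c.fp == 1 and c.fn == 1

    def test_duplicate_species_rejected_at_construction(self):
        with pytest.raises(mb.ValidationError, match="duplicate"):
            mb.AbundanceProfile.from_pairs([("A", 1.0), ("A", 2.0)])


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [
            (9, 1, 1, (0.9, 0.9, 0.9)),
            (1, 0, 3, (1.0, 0.25, 0.4)),
            (0, 0, 0, (1.0, 1.0, 1.0)),  # empty community convention
            (0, 5, 0, (0.0, 1.0, 0.0)),
            (0, 0, 4, (0.0, 0.0, 0.0)),  # empty prediction, species missed
        ],
    )
    def test_formulas_and_conventions(self, tp, fp, fn, expected):
        c = mb.ConfusionSummary(tp=tp, fp=fp, fn=fn, threshold=0.0)
        assert mb.precision_recall_f1(c) == pytest.approx(expected)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, fp, fn = rng.integers(0, 20, size=3)
            p, r, f1 = mb.precision_recall_f1(
                mb.ConfusionSummary(int(tp), int(fp), int(fn), 0.0)
            )
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12


class TestL1Distance:
    def test_identical_profiles_zero(self):
        p = profile({"A": 60.0, "B": 40.0})
        assert mb.l1_distance(p, p) == 0.0

    def test_disjoint_normalized_profiles_200(self):
        assert mb.l1_distance(
            profile({"A": 60.0, "B": 40.0}), profile({"C": 70.0, "D": 30.0})
        ) == pytest.approx(200.0)

    def test_worked_example(self):
        assert mb.l1_distance(
            profile({"A": 60.0, "B": 40.0}), profile({"A": 50.0, "B": 50.0})
        ) == pytest.approx(20.0)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        st.dictionaries(st.sampled_from("ABCDEF"), st.floats(0, 100), max_size=6),
        st.dictionaries(st.sampled_from("ABCDEF"), st.floats(0, 100), max_size=6),
        st.dictionaries(st.sampled_from("ABCDEF"), st.floats(0, 100), max_size=6),
    )
    def test_metric_axioms(self, a, b, c):
        pa, pb, pc = profile(a), profile(b), profile(c)
        assert mb.l1_distance(pa, pb) == pytest.approx(mb.l1_distance(pb, pa))
        assert (
            mb.l1_distance(pa, pc)
            <= mb.l1_distance(pa, pb) + mb.l1_distance(pb, pc) + 1e-9
        )
        assert (mb.l1_distance(pa, pb) == 0) == (
            {s: v for s, v in a.items() if v != 0}
            == {s: v for s, v in b.items() if v != 0}
        )


class TestRelativeErrors:
    def test_ten_percent_error(self):
        errors, mean = mb.relative_errors(profile({"A": 10.0}), profile({"A": 9.0}))
        assert errors["A"] == pytest.approx(10.0)
        assert mean == pytest.approx(10.0)

    def test_exact_prediction_zero_mean(self):
        p = profile({"A": 30.0, "B": 70.0})
        _, mean = mb.relative_errors(p, p)
        assert mean == 0.0

    def test_missing_truth_species_contributes_100(self):
        errors, _ = mb.relative_errors(
            profile({"A": 10.0, "B": 5.0}), profile({"A": 10.0})
        )
        assert errors["B"] == pytest.approx(100.0)

    def test_false_positives_excluded_from_mean(self):
        _, mean = mb.relative_errors(
            profile({"A": 10.0}), profile({"A": 10.0, "FP": 50.0})
        )
        assert mean == 0.0

    def test_zero_truth_abundance_rejected(self):
        with pytest.raises(mb.ValidationError):
            mb.relative_errors(profile({"A": 0.0}), profile({"A": 1.0}))


class TestFpFnAbundance:
    def test_perfect_prediction_zero_mass(self):
        p = profile({"A": 100.0})
        assert mb.fp_fn_abundance(p, p) == (0.0, 0.0)

    def test_fp_mass_is_predicted_abundance(self):
        fp, fn = mb.fp_fn_abundance(
            profile({"A": 98.0}), profile({"A": 98.0, "X": 2.0})
        )
        assert fp == pytest.approx(2.0) and fn == 0.0

    def test_fn_mass_is_truth_abundance(self):
        fp, fn = mb.fp_fn_abundance(
            profile({"A": 98.5, "B": 1.5}), profile({"A": 98.5})
        )
        assert fp == 0.0 and fn == pytest.approx(1.5)


class TestOptimizeF1Threshold:
    def test_low_abundance_fp_filtered_away(self):
        truth = profile({"A": 50.0, "B": 50.0})
        pred = profile({"A": 50.0, "B": 49.0, "C": 1.0})
        threshold, f1 = mb.optimize_f1_threshold(truth, pred)
        assert threshold == pytest.approx(49.0)
        assert f1 == pytest.approx(1.0)

    def test_perfect_profile_needs_no_filtering(self):
        p = profile({"A": 60.0, "B": 40.0})
        assert mb.optimize_f1_threshold(p, p) == (0.0, 1.0)

    def test_optimized_never_below_unfiltered(self, rng):
        for _ in range(30):
            truth = {f"t{i}": float(a) for i, a in
                     enumerate(rng.uniform(0.1, 50, size=8))}
            pred = mb.perturb_profile(truth, int(rng.integers(0, 4)),
                                      int(rng.integers(0, 4)), 0.3, rng)
            t_prof, p_prof = profile(truth), profile(pred)
            _, _, plain = mb.precision_recall_f1(mb.confusion(t_prof, p_prof))
            _, best = mb.optimize_f1_threshold(t_prof, p_prof)
            assert best >= plain - 1e-12


def _oracle_sweep_thresholds(pred):
    """Midpoints between consecutive abundances, plus 0 and beyond-max."""
    values = sorted(set(pred.abundances.values()))
    thresholds = [0.0]
    for lo, hi in zip(values, values[1:]):
        thresholds.append((lo + hi) / 2)
    if values:
        thresholds.extend([values[0] / 2, values[-1]])
    return sorted(set(thresholds))


def _random_profiles(rng, n_truth=10, n_pred=12):
    truth = {f"s{i}": float(a) for i, a in
             enumerate(rng.uniform(0.05, 40.0, size=n_truth))}
    pred = {}
    species = list(truth) + [f"fp{i}" for i in range(n_pred)]
    for sp in rng.choice(species, size=min(n_pred, len(species)), replace=False):
        pred[str(sp)] = float(rng.choice([0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 20.0]))
    return profile(truth), profile(pred)


class TestDetectionLimit:
    def test_no_false_positives_means_zero_limit(self):
        truth = profile({f"s{i}": 10.0 for i in range(10)})
        pred = profile({f"s{i}": 10.0 for i in range(7)})  # strict subset
        for fdr in DEFAULT_TARGET_FDRS:
            assert mb.detection_limit(truth, pred, fdr) == 0.0

    def test_worked_sweep_strict_target(self):
        truth = profile({"t1": 1.0, "t2": 0.5})
        pred = profile({"t1": 1.0, "t2": 0.5, "f1": 0.1, "f2": 0.05})
        assert mb.detection_limit(truth, pred, 0.0) == pytest.approx(0.5)

    def test_worked_sweep_lenient_target(self):
        truth = profile({"t1": 1.0, "t2": 0.5})
        pred = profile({"t1": 1.0, "t2": 0.5, "f1": 0.1, "f2": 0.05})
        assert mb.detection_limit(truth, pred, 0.40) == pytest.approx(0.1)

    def test_unachievable_target_returns_sentinel(self):
        truth = profile({"t1": 1.0})
        pred = profile({"t1": 1.0, "f1": 50.0})  # top prediction is an FP
        assert mb.detection_limit(truth, pred, 0.0) is None

    def test_monotone_in_target_fdr(self, rng):
        for _ in range(25):
            truth, pred = _random_profiles(rng)
            limits = [mb.detection_limit(truth, pred, fdr)
                      for fdr in (0.0, 0.001, 0.01, 0.05, 0.1, 0.5, 1.0)]
            achieved = [l for l in limits if l is not None]
            # achievability can only improve with a laxer target …
            nones = [l is None for l in limits]
            assert nones == sorted(nones, reverse=True)
            # … and the limit itself never increases
            assert all(a >= b - 1e-12 for a, b in zip(achieved, achieved[1:]))

    def test_matches_midpoint_sweep_oracle(self, rng):
        for _ in range(50):
            truth, pred = _random_profiles(rng)
            truth_set = truth.species()
            for target in (0.0, 0.01, 0.1, 0.25, 0.5):
                got = mb.detection_limit(truth, pred, target)
                expected = None
                for t in _oracle_sweep_thresholds(pred):
                    kept = {s for s, a in pred.items() if a >= t}
                    fdr = len(kept - truth_set) / len(kept) if kept else 0.0
                    if fdr <= target:
                        expected = min(
                            (a for a in pred.abundances.values() if a >= t),
                            default=0.0,
                        ) if t > 0 else 0.0
                        break
                assert got == expected


class TestEvaluateProfile:
    def test_truth_against_itself_is_perfect(self):
        truth = profile({"A": 60.0, "B": 39.99, "C": 0.01})
        report = evaluate_profile(truth, truth)
        assert report.precision == report.recall == report.f1 == 1.0
        assert report.l1_distance == 0.0
        assert report.mean_relative_error == 0.0
        assert all(v == 0.0 for v in report.detection_limits.values())

    def test_planted_fp_and_fn_counted(self, rng):
        truth = {f"s{i}": 100.0 / 12 for i in range(12)}
        pred = mb.perturb_profile(truth, n_fp=3, n_fn=2, noise_sd=0.0, rng=rng)
        report = evaluate_profile(profile(truth), profile(pred),
                                  min_abundance=0.0)
        assert (report.confusion.tp, report.confusion.fp,
                report.confusion.fn) == (10, 3, 2)

    def test_report_serializes(self):
        truth = profile({"A": 60.0, "B": 40.0})
        report = evaluate_profile(truth, profile({"A": 55.0, "X": 45.0}))
        d = report.to_dict()
        assert d["tp"] == 1 and d["fp"] == 1 and d["fn"] == 1
        assert "detection_limit_fdr_0.05" in d


class TestAggregate:
    def _report(self, **overrides):
        truth = profile({"A": 60.0, "B": 40.0})
        report = evaluate_profile(truth, truth)
        for key, value in overrides.items():
            setattr(report, key, value)
        return report

    def test_single_report_round_trips(self):
        table = mb.aggregate({"high": [self._report()]})
        assert table.loc["high", "f1_mean"] == pytest.approx(1.0)
        assert table.loc["high", "f1_sd"] == 0.0

    def test_mean_of_two(self):
        reports = [self._report(f1=0.0), self._report(f1=0.1)]
        table = mb.aggregate({"g": reports})
        assert table.loc["g", "f1_mean"] == pytest.approx(0.05)

    def test_median_robust_to_outlier(self):
        reports = [
            self._report(detection_limits={0.05: v}) for v in (0.0, 0.0, 9.0)
        ]
        table = mb.aggregate({"g": reports}, statistic="median")
        assert table.loc["g", "detection_limit_fdr_0.05_median"] == 0.0

    def test_unachievable_counted_separately(self):
        reports = [
            self._report(detection_limits={0.05: 0.1}),
            self._report(detection_limits={0.05: None}),
        ]
        table = mb.aggregate({"g": reports})
        assert table.loc["g", "detection_limit_fdr_0.05_mean"] == pytest.approx(0.1)
        assert table.loc["g", "detection_limit_fdr_0.05_unachievable"] == 1

    def test_empty_group_warns_and_is_omitted(self):
        with pytest.warns(UserWarning, match="no reports"):
            table = mb.aggregate({"empty": [], "ok": [self._report()]})
        assert list(table.index) == ["ok"]


class TestCandidateThresholds:
    def test_zero_always_included(self):
        assert _candidate_thresholds(profile({"A": 5.0})) == [0.0, 5.0]
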