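"""Evaluation protocol: labeling, confusion counts, figures of merit,
rate error, CCF, corpus summaries."""

import pytest

from ticpr import (
    ConfusionCounts,
    EpisodeAnnotation,
    ValidationError,
    WindowReference,
    WindowResult,
    ccf_metrics,
    confusion,
    evaluate_corpus,
    figures_of_merit,
    label_windows,
    per_episode_summary,
    rate_error,
)


def _result(i, rate=0.0):
    detected = rate != 0.0
    return WindowResult(
        window_index=i,
        detected=detected,
        rate_cpm=rate,
        peak_lag_s=60.0 / rate if detected else None,
        peak_score=0.9 if detected else None,
        start_s=2.0 * i,
    )


def _ref(i, label, rate=None):
    return WindowReference(window_index=i, label=label, reference_rate_cpm=rate)


class TestLabelWindows:
    def test_window_inside_series_with_rate(self):
        ann = EpisodeAnnotation(
            series=[(0.0, 4.0)], instances_s=[0.25, 0.75, 1.25, 1.75]
        )
        ref = label_windows(ann, [(0.0, 2.0)])[0]
        assert ref.label == "compressions"
        assert ref.reference_rate_cpm == pytest.approx(120.0)

    def test_window_outside_series(self):
        ann = EpisodeAnnotation(series=[(10.0, 20.0)], instances_s=[12.0, 13.0])
        ref = label_windows(ann, [(0.0, 2.0)])[0]
        assert ref.label == "no_compressions"
        assert ref.reference_rate_cpm is None

    @pytest.mark.parametrize(
        "series_end, expected",
        [(0.8, "no_compressions"), (1.0, "compressions"), (1.4, "compressions")],
    )
    def test_overlap_rule_at_half_window(self, series_end, expected):
        ann = EpisodeAnnotation(series=[(0.0, series_end)], instances_s=[0.3])
        assert label_windows(ann, [(0.0, 2.0)])[0].label == expected

    def test_single_instant_leaves_rate_undefined(self):
        ann = EpisodeAnnotation(series=[(0.0, 2.0)], instances_s=[0.9])
        ref = label_windows(ann, [(0.0, 2.0)])[0]
        assert ref.label == "compressions"
        assert ref.reference_rate_cpm is None


class TestConfusion:
    def test_counts_by_category(self):
        results = [_result(0, 110), _result(1, 120), _result(2, 100),
                   _result(3), _result(4)]
        refs = [_ref(0, "compressions", 110), _ref(1, "compressions", 118),
                _ref(2, "compressions", 99), _ref(3, "no_compressions"),
                _ref(4, "no_compressions")]
        c = confusion(results, refs)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 2, 0, 0)
        assert c.total == 5

    def test_false_positive_is_detection_without_compressions(self):
        c = confusion([_result(0, 140)], [_ref(0, "no_compressions")])
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 1, 0)

    def test_empty_sequences(self):
        c = confusion([], [])
        assert c.total == 0

    def test_misalignment_rejected(self):
        with pytest.raises(ValidationError):
            confusion([_result(0)], [_ref(1, "no_compressions")])
        with pytest.raises(ValidationError):
            confusion([_result(0)], [])


class TestFiguresOfMerit:
    def test_percentages(self):
        fom = figures_of_merit(ConfusionCounts(tp=9, fn=1, tn=0, fp=0))
        assert fom["Se"] == pytest.approx(90.0)

    def test_zero_denominator_is_undefined(self):
        fom = figures_of_merit(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert fom["PPV"] is None
        assert fom["NPV"] == pytest.approx(62.5)

    def test_global_structure_example(self):
        fom = figures_of_merit(ConfusionCounts(tp=987, fn=13, fp=13, tn=435))
        assert fom["Se"] == pytest.approx(98.7)
        assert fom["PPV"] == pytest.approx(98.7)


class TestPerEpisodeSummary:
    def test_hand_computed_ci(self):
        # sd of [98,100,96,100,98] is 1.673; CI = mean +/- 1.96*sd/sqrt(5)
        s = per_episode_summary([98.0, 100.0, 96.0, 100.0, 98.0])
        assert s.mean == pytest.approx(98.4)
        assert s.ci_low == pytest.approx(96.93, abs=0.01)
        assert s.ci_high == pytest.approx(99.87, abs=0.01)

    def test_identical_values_zero_width(self):
        s = per_episode_summary([97.0, 97.0, 97.0])
        assert s.ci_low == pytest.approx(s.ci_high) == pytest.approx(97.0)

    def test_single_value_mean_only(self):
        s = per_episode_summary([88.0])
        assert s.mean == 88.0
        assert s.ci_low is None and s.ci_high is None

    def test_none_values_excluded(self):
        s = per_episode_summary([None, 90.0, None, 92.0])
        assert s.n == 2
        assert s.mean == pytest.approx(91.0)


class TestRateError:
    def test_signed_error_is_reference_minus_estimate(self):
        stats = rate_error(
            [_result(0, 118.0)], [_ref(0, "compressions", 120.0)]
        )
        assert stats.signed_errors_cpm == [pytest.approx(2.0)]

    def test_fp_and_undefined_reference_contribute_nothing(self):
        results = [_result(0, 100.0), _result(1, 100.0), _result(2)]
        refs = [
            _ref(0, "no_compressions"),          # FP: excluded
            _ref(1, "compressions", None),       # TP without reference rate
            _ref(2, "compressions", 110.0),      # FN: excluded
        ]
        stats = rate_error(results, refs)
        assert stats.n == 0
        assert stats.median_unsigned_cpm is None

    def test_fraction_within_10(self):
        results = [_result(i, 100.0) for i in range(4)]
        refs = [_ref(i, "compressions", r) for i, r in enumerate([102, 95, 125, 100])]
        stats = rate_error(results, refs)
        assert stats.fraction_within_10_cpm == pytest.approx(0.75)


class TestCCF:
    def test_window_fractions(self):
        results = [_result(i, 110.0) for i in range(21)] + [
            _result(i) for i in range(21, 30)
        ]
        refs = [_ref(i, "compressions", 110.0) for i in range(20)] + [
            _ref(i, "no_compressions") for i in range(20, 30)
        ]
        m = ccf_metrics(results, refs)
        assert m.reference_pct == pytest.approx(100 * 20 / 30)
        assert m.estimated_pct == pytest.approx(70.0)
        assert m.unsigned_error_pct == pytest.approx(10 / 3, abs=0.01)

    def test_perfect_detector_zero_error(self):
        results = [_result(0, 100.0), _result(1)]
        refs = [_ref(0, "compressions", 100.0), _ref(1, "no_compressions")]
        assert ccf_metrics(results, refs).unsigned_error_pct == 0.0


class TestEvaluateCorpus:
    def _episode(self, n_tp, n_tn, n_fp=0, n_fn=0, start=0):
        results, refs = [], []
        i = start
        for _ in range(n_tp):
            results.append(_result(i, 110.0))
            refs.append(_ref(i, "compressions", 112.0))
            i += 1
        for _ in range(n_fn):
            results.append(_result(i))
            refs.append(_ref(i, "compressions", 112.0))
            i += 1
        for _ in range(n_fp):
            results.append(_result(i, 90.0))
            refs.append(_ref(i, "no_compressions"))
            i += 1
        for _ in range(n_tn):
            results.append(_result(i))
            refs.append(_ref(i, "no_compressions"))
            i += 1
        return results, refs

    def test_single_episode_global_equals_per_episode(self):
        rep = evaluate_corpus([self._episode(8, 4)])
        assert rep.global_metrics["Se"] == rep.per_episode_metrics["Se"][0]

    def test_confusion_additivity_and_reorder_invariance(self):
        e1 = self._episode(5, 3, n_fp=1)
        e2 = self._episode(7, 2, n_fn=2)
        rep_a = evaluate_corpus([e1, e2])
        rep_b = evaluate_corpus([e2, e1])
        assert rep_a.global_counts.tp == 12
        assert rep_a.global_counts == rep_b.global_counts
        assert rep_a.global_metrics == rep_b.global_metrics

    def test_complementarity(self):
        episodes = [self._episode(5, 3, n_fp=2, n_fn=1), self._episode(4, 6)]
        rep = evaluate_corpus(episodes)
        n_pos = sum(
            r.label == "compressions" for _, refs in episodes for r in refs
        )
        n_neg = sum(
            r.label == "no_compressions" for _, refs in episodes for r in refs
        )
        c = rep.global_counts
        assert c.tp + c.fn == n_pos
        assert c.fp + c.tn == n_neg

    def test_perfect_oracle_closure(self):
        refs = [_ref(i, "compressions", 100.0) for i in range(12)] + [
            _ref(i, "no_compressions") for i in range(12, 20)
        ]
        results = [
            _result(r.window_index, 100.0 if r.label == "compressions" else 0.0)
            for r in refs
        ]
        rep = evaluate_corpus([(results, refs)])
        for name in ("Se", "PPV", "Sp", "NPV"):
            assert rep.global_metrics[name] == pytest.approx(100.0)
        assert rep.ccf_per_episode[0].unsigned_error_pct == 0.0
        assert rep.rate_error_summary["median"] == pytest.approx(0.0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_corpus([])

    def test_report_dict_serializes(self):
        import json

        rep = evaluate_corpus([self._episode(5, 5)])
        blob = json.dumps(rep.to_dict())
        assert "global" in blob

    def test_flags_reference_rates_above_ceiling(self):
        results, refs = self._episode(3, 2)
        refs[0] = _ref(0, "compressions", 280.0)
        rep = evaluate_corpus([(results, refs)])
        assert rep.n_windows_reference_rate_above_max == 1


def test_median_iqr_uses_linear_interpolation():
    # documented quantile convention: numpy linear interpolation
    from ticpr.evaluation import _median_iqr

    s = _median_iqr([1.0, 2.0, 3.0, 4.0])
    assert s["median"] == pytest.approx(2.5)
    assert s["iqr"] == (pytest.approx(1.75), pytest.approx(3.25))
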