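"""Window-level evaluation of the compression detector.

Every 2-s detector output is classified against the annotation:

* TP - non-zero rate reported for a window with annotated compressions,
* FN - zero reported for a window with annotated compressions,
* FP - non-zero rate reported for a window without compressions,
* TN - zero reported for a window without compressions,

from which sensitivity Se = 100*TP/(TP+FN), positive predictive value
PPV = 100*TP/(TP+FP), specificity Sp = 100*TN/(TN+FP) and negative
predictive value NPV = 100*TN/(TN+FN) follow.  The reference rate of a
window is the inverse of the mean time between its annotated compression
instants; the reference chest compression fraction (CCF) of an episode is
the percentage of windows with annotated compressions, estimated by the
percentage of windows with detections.  Distribution summaries use median
(IQR) with linear quantile interpolation; per-episode means carry
normal-approximation 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .annotations import EpisodeAnnotation
from .detector import WindowResult
from .errors import ValidationError

__all__ = [
    "WindowReference",
    "ConfusionCounts",
    "SummaryStats",
    "EvaluationReport",
    "label_windows",
    "drop_excluded",
    "confusion",
    "figures_of_merit",
    "per_episode_summary",
    "rate_error",
    "ccf_metrics",
    "evaluate_corpus",
    "evaluate_episode",
]

Label = Literal["compressions", "no_compressions"]

#: A window is labeled "compressions" when at least this fraction of it
#: overlaps annotated compression series.
DEFAULT_OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class WindowReference:
    """Ground-truth label (and reference rate, when defined) for one window."""

    window_index: int
    label: Label
    reference_rate_cpm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.reference_rate_cpm is not None and not (
            np.isfinite(self.reference_rate_cpm) and self.reference_rate_cpm > 0
        ):
            raise ValidationError("reference_rate_cpm must be positive and finite")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class SummaryStats:
    """Mean with normal-approximation 95% CI over per-episode values."""

    mean: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    n: int


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def _bounds(window) -> tuple[float, float]:
    if hasattr(window, "start_s") and hasattr(window, "end_s"):
        return float(window.start_s), float(window.end_s)
    start, end = window
    return float(start), float(end)


def label_windows(
    annotation: EpisodeAnnotation,
    windows: Sequence,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> list[WindowReference]:
    """Label each window from the annotation and compute its reference rate.

    A window is labeled ``compressions`` when its overlap with the union of
    annotated series reaches ``overlap_fraction`` of the window length
    (default one half; the annotation itself never states how to label a
    window straddling a series boundary).  The reference rate is defined
    when >= 2 instants fall inside the half-open window as
    ``60*(n-1)/(t_last - t_first)`` cpm and is reported for both labels.

    ``windows`` may hold :class:`~ticpr.signal.AnalysisWindow` objects or
    plain ``(start_s, end_s)`` pairs.
    """
    instants = np.asarray(annotation.instances_s)
    refs = []
    for i, w in enumerate(windows):
        start, end = _bounds(w)
        covered = sum(_overlap(start, end, a, b) for a, b in annotation.series)
        label: Label = (
            "compressions"
            if covered >= overlap_fraction * (end - start)
            else "no_compressions"
        )
        inside = instants[(instants >= start) & (instants < end)]
        rate = None
        if inside.size >= 2 and inside[-1] > inside[0]:
            rate = 60.0 * (inside.size - 1) / (inside[-1] - inside[0])
        index = w.index if hasattr(w, "index") and not isinstance(w, tuple) else i
        refs.append(
            WindowReference(window_index=index, label=label, reference_rate_cpm=rate)
        )
    return refs


def drop_excluded(
    results: Sequence[WindowResult],
    references: Sequence[WindowReference],
    windows: Sequence,
    excluded: Sequence[tuple[float, float]],
) -> tuple[list[WindowResult], list[WindowReference]]:
    """Remove windows overlapping any excluded interval (shocks, pad gaps)."""
    keep_results, keep_refs = [], []
    for res, ref, w in zip(results, references, windows):
        start, end = _bounds(w)
        if any(_overlap(start, end, a, b) > 0 for a, b in excluded):
            continue
        keep_results.append(res)
        keep_refs.append(ref)
    return keep_results, keep_refs


def confusion(
    results: Sequence[WindowResult], references: Sequence[WindowReference]
) -> ConfusionCounts:
    """Count TP/TN/FP/FN over aligned detector outputs and references."""
    if len(results) != len(references):
        raise ValidationError("results and references have different lengths")
    tp = tn = fp = fn = 0
    for res, ref in zip(results, references):
        if res.window_index != ref.window_index:
            raise ValidationError(
                f"misaligned windows: result {res.window_index} vs "
                f"reference {ref.window_index}"
            )
        positive = ref.label == "compressions"
        if res.detected and positive:
            tp += 1
        elif res.detected and not positive:
            fp += 1
        elif not res.detected and positive:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den > 0 else None


def figures_of_merit(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """Se/PPV/Sp/NPV in percent; a zero-denominator ratio is ``None``."""
    return {
        "Se": _ratio(c.tp, c.tp + c.fn),
        "PPV": _ratio(c.tp, c.tp + c.fp),
        "Sp": _ratio(c.tn, c.tn + c.fp),
        "NPV": _ratio(c.tn, c.tn + c.fn),
    }


def per_episode_summary(values: Iterable[Optional[float]]) -> SummaryStats:
    """Mean and normal-approximation 95% CI (mean +/- 1.96*sd/sqrt(n)).

    ``None`` entries (episodes where the metric is undefined) are dropped;
    with fewer than two defined values the CI is undefined.
    """
    defined = [v for v in values if v is not None]
    n = len(defined)
    if n == 0:
        return SummaryStats(mean=None, ci_low=None, ci_high=None, n=0)
    mean = float(np.mean(defined))
    if n < 2:
        return SummaryStats(mean=mean, ci_low=None, ci_high=None, n=n)
    half = 1.96 * float(np.std(defined, ddof=1)) / np.sqrt(n)
    return SummaryStats(mean=mean, ci_low=mean - half, ci_high=mean + half, n=n)


@dataclass(frozen=True)
class RateErrorStats:
    """Rate-error distribution of one episode.

    Signed errors (reference - estimate, cpm) are collected over TP windows
    with a defined reference rate; FP windows contribute nothing.
    """

    signed_errors_cpm: list[float]
    median_unsigned_cpm: Optional[float]
    iqr_unsigned_cpm: tuple[Optional[float], Optional[float]]
    fraction_within_10_cpm: Optional[float]

    @property
    def n(self) -> int:
        return len(self.signed_errors_cpm)


def rate_error(
    results: Sequence[WindowResult], references: Sequence[WindowReference]
) -> RateErrorStats:
    """Signed and unsigned rate-error summaries for one episode."""
    if len(results) != len(references):
        raise ValidationError("results and references have different lengths")
    signed = [
        ref.reference_rate_cpm - res.rate_cpm
        for res, ref in zip(results, references)
        if res.detected
        and ref.label == "compressions"
        and ref.reference_rate_cpm is not None
    ]
    if not signed:
        return RateErrorStats([], None, (None, None), None)
    unsigned = np.abs(signed)
    q25, q75 = np.percentile(unsigned, [25, 75])
    return RateErrorStats(
        signed_errors_cpm=[float(e) for e in signed],
        median_unsigned_cpm=float(np.median(unsigned)),
        iqr_unsigned_cpm=(float(q25), float(q75)),
        fraction_within_10_cpm=float(np.mean(unsigned <= 10.0)),
    )


@dataclass(frozen=True)
class CCFMetrics:
    """Per-episode chest compression fraction: reference, estimate, error (%)."""

    reference_pct: float
    estimated_pct: float
    unsigned_error_pct: float


def ccf_metrics(
    results: Sequence[WindowResult], references: Sequence[WindowReference]
) -> CCFMetrics:
    """CCF from window fractions: annotated vs detected."""
    if len(results) != len(references) or not results:
        raise ValidationError("need equal-length, non-empty results/references")
    n = len(results)
    ref = 100.0 * sum(r.label == "compressions" for r in references) / n
    est = 100.0 * sum(r.detected for r in results) / n
    return CCFMetrics(
        reference_pct=ref, estimated_pct=est, unsigned_error_pct=abs(ref - est)
    )


def _median_iqr(values: Sequence[float]) -> dict:
    if len(values) == 0:
        return {"median": None, "iqr": (None, None), "n": 0}
    q25, q75 = np.percentile(values, [25, 75])
    return {
        "median": float(np.median(values)),
        "iqr": (float(q25), float(q75)),
        "n": len(values),
    }


@dataclass(frozen=True)
class EvaluationReport:
    """Corpus-level evaluation: global and per-episode detection metrics,
    rate-error and CCF-error summaries."""

    global_counts: ConfusionCounts
    global_metrics: dict[str, Optional[float]]
    per_episode_metrics: dict[str, list[Optional[float]]]
    per_episode_summary: dict[str, SummaryStats]
    rate_error_per_episode_median_cpm: list[Optional[float]]
    rate_error_summary: dict
    rate_error_pooled_fraction_within_10_cpm: Optional[float]
    ccf_per_episode: list[CCFMetrics]
    ccf_error_summary: dict
    n_episodes: int
    n_windows: int
    n_windows_reference_rate_above_max: int = 0
    per_episode_counts: list[ConfusionCounts] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_episodes": self.n_episodes,
            "n_windows": self.n_windows,
            "global": {
                "counts": {
                    "TP": self.global_counts.tp,
                    "TN": self.global_counts.tn,
                    "FP": self.global_counts.fp,
                    "FN": self.global_counts.fn,
                },
                "metrics": dict(self.global_metrics),
            },
            "per_episode": {
                name: {
                    "values": list(vals),
                    "mean": self.per_episode_summary[name].mean,
                    "ci_95": [
                        self.per_episode_summary[name].ci_low,
                        self.per_episode_summary[name].ci_high,
                    ],
                    "n": self.per_episode_summary[name].n,
                }
                for name, vals in self.per_episode_metrics.items()
            },
            "rate_error": {
                "per_episode_median_unsigned_cpm": list(
                    self.rate_error_per_episode_median_cpm
                ),
                "summary_over_episodes": dict(self.rate_error_summary),
                "pooled_fraction_within_10_cpm": (
                    self.rate_error_pooled_fraction_within_10_cpm
                ),
            },
            "ccf": {
                "per_episode": [
                    {
                        "reference_pct": m.reference_pct,
                        "estimated_pct": m.estimated_pct,
                        "unsigned_error_pct": m.unsigned_error_pct,
                    }
                    for m in self.ccf_per_episode
                ],
                "error_summary": dict(self.ccf_error_summary),
            },
            "n_windows_reference_rate_above_max": (
                self.n_windows_reference_rate_above_max
            ),
        }


def evaluate_corpus(
    episodes: Sequence[tuple[Sequence[WindowResult], Sequence[WindowReference]]],
    rate_max_cpm: float = 250.0,
) -> EvaluationReport:
    """Evaluate a corpus of episodes.

    Global detection metrics pool all windows; per-episode metrics are
    computed independently and summarized with mean and 95% CI.  Rate and
    CCF errors are summarized over episodes as median (IQR).  Windows whose
    reference rate exceeds ``rate_max_cpm`` (above the detector's ceiling)
    are still scored by the plain TP/FN definitions but their count is
    flagged in the report.
    """
    if len(episodes) == 0:
        raise ValidationError("corpus must contain at least one episode")

    counts = []
    per_metric: dict[str, list[Optional[float]]] = {
        k: [] for k in ("Se", "PPV", "Sp", "NPV")
    }
    rate_medians: list[Optional[float]] = []
    pooled_unsigned: list[float] = []
    ccf_list: list[CCFMetrics] = []
    n_windows = 0
    n_above = 0

    for results, references in episodes:
        c = confusion(results, references)
        counts.append(c)
        n_windows += c.total
        fom = figures_of_merit(c)
        for k in per_metric:
            per_metric[k].append(fom[k])
        re = rate_error(results, references)
        rate_medians.append(re.median_unsigned_cpm)
        pooled_unsigned.extend(abs(e) for e in re.signed_errors_cpm)
        ccf_list.append(ccf_metrics(results, references))
        n_above += sum(
            1
            for ref in references
            if ref.reference_rate_cpm is not None
            and ref.reference_rate_cpm > rate_max_cpm
        )

    total = ConfusionCounts()
    for c in counts:
        total = total + c

    defined_medians = [m for m in rate_medians if m is not None]
    pooled_frac = (
        float(np.mean(np.asarray(pooled_unsigned) <= 10.0))
        if pooled_unsigned
        else None
    )
    return EvaluationReport(
        global_counts=total,
        global_metrics=figures_of_merit(total),
        per_episode_metrics=per_metric,
        per_episode_summary={
            k: per_episode_summary(v) for k, v in per_metric.items()
        },
        rate_error_per_episode_median_cpm=rate_medians,
        rate_error_summary=_median_iqr(defined_medians),
        rate_error_pooled_fraction_within_10_cpm=pooled_frac,
        ccf_per_episode=ccf_list,
        ccf_error_summary=_median_iqr([m.unsigned_error_pct for m in ccf_list]),
        n_episodes=len(episodes),
        n_windows=n_windows,
        n_windows_reference_rate_above_max=n_above,
        per_episode_counts=counts,
    )


def evaluate_episode(
    results: Sequence[WindowResult],
    annotation: EpisodeAnnotation,
    window_s: float = 2.0,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> tuple[list[WindowResult], list[WindowReference]]:
    """Build aligned (results, references) for one episode.

    The window grid is reconstructed from the results' start times (falling
    back to index * window_s), then windows overlapping excluded annotation
    intervals are dropped.
    """
    bounds = []
    for res in results:
        start = res.start_s if res.start_s is not None else res.window_index * window_s
        bounds.append((start, start + window_s))
    refs = label_windows(annotation, bounds, overlap_fraction)
    refs = [
        WindowReference(
            window_index=res.window_index,
            label=ref.label,
            reference_rate_cpm=ref.reference_rate_cpm,
        )
        for res, ref in zip(results, refs)
    ]
    return drop_excluded(list(results), refs, bounds, annotation.excluded)
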