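"""Ground-truth episode annotations.

An annotated episode records the beginning and end of every chest-compression
series and the instant of every individual compression (identified in the
clinical workflow by its fluctuation in the TI signal).  Optional ``excluded``
intervals mark segments to drop from evaluation (shock artifacts,
pad-disconnection gaps).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .errors import ValidationError

#: Minimum credible spacing between two compressions (~300 cpm).
MIN_COMPRESSION_SPACING_S = 0.2

Interval = tuple[float, float]


def _check_intervals(intervals: list[Interval], what: str) -> list[Interval]:
    out = [(float(a), float(b)) for a, b in intervals]
    for a, b in out:
        if not b > a:
            raise ValidationError(f"{what} interval ({a}, {b}) has non-positive length")
    for (a0, b0), (a1, b1) in zip(out, out[1:]):
        if a1 < b0:
            raise ValidationError(
                f"{what} intervals ({a0}, {b0}) and ({a1}, {b1}) overlap or are unordered"
            )
    return out


@dataclass(frozen=True)
class EpisodeAnnotation:
    """Compression-series intervals plus individual compression instants.

    Invariants enforced at construction: series are time-ordered and
    non-overlapping; every instant lies inside exactly one series; within a
    series consecutive instants are more than 0.2 s apart.
    """

    series: list[Interval]
    instances_s: list[float]
    excluded: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        series = _check_intervals(list(self.series), "series")
        excluded = _check_intervals(list(self.excluded), "excluded")
        instances = [float(t) for t in self.instances_s]
        if instances != sorted(instances):
            raise ValidationError("compression instants must be time-ordered")
        starts = [a for a, _ in series]
        owner = []
        for t in instances:
            i = bisect_right(starts, t) - 1
            if i < 0 or not (series[i][0] <= t < series[i][1]):
                raise ValidationError(
                    f"compression instant {t} s lies outside every series"
                )
            owner.append(i)
        for (t0, i0), (t1, i1) in zip(
            zip(instances, owner), zip(instances[1:], owner[1:])
        ):
            if i0 == i1 and t1 - t0 <= MIN_COMPRESSION_SPACING_S:
                raise ValidationError(
                    f"instants {t0} and {t1} s closer than "
                    f"{MIN_COMPRESSION_SPACING_S} s"
                )
        object.__setattr__(self, "series", series)
        object.__setattr__(self, "excluded", excluded)
        object.__setattr__(self, "instances_s", instances)

    @property
    def total_compression_time_s(self) -> float:
        return sum(b - a for a, b in self.series)

    def to_dict(self) -> dict:
        d = {
            "series": [{"start_s": a, "end_s": b} for a, b in self.series],
            "instances_s": list(self.instances_s),
        }
        if self.excluded:
            d["excluded"] = [{"start_s": a, "end_s": b} for a, b in self.excluded]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EpisodeAnnotation":
        try:
            series = [(s["start_s"], s["end_s"]) for s in d["series"]]
            instances = list(d["instances_s"])
            excluded = [(s["start_s"], s["end_s"]) for s in d.get("excluded", [])]
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed annotation object: {exc}") from exc
        return cls(series=series, instances_s=instances, excluded=excluded)
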