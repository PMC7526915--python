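"""File formats: signal CSV, annotation JSON, results CSV, report JSON.

The canonical signal format is a two-column CSV ``time_s,impedance_ohm``
(header required, '.' decimal separator) with uniform sampling.  Annotations
travel as JSON ``{"series": [{"start_s", "end_s"}], "instances_s": [...]}``
with an optional ``excluded`` interval list.  Every CLI run also writes a
small JSON manifest so outputs can be reproduced.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import EpisodeAnnotation
from .detector import WindowResult
from .errors import ValidationError
from .signal import ImpedanceSignal

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_annotation_json",
    "write_annotation_json",
    "read_results_csv",
    "write_results_csv",
    "write_report_json",
    "read_report_json",
    "RunManifest",
]

#: Permitted jitter of sample times around the uniform grid (seconds).
TIME_JITTER_TOL_S = 1e-6


def read_signal_csv(path: str | Path) -> ImpedanceSignal:
    """Load a TI signal from ``time_s,impedance_ohm`` CSV, validating
    uniform sampling (within 1 us jitter) and finite values.

    Errors name the offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "impedance_ohm"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column '{col}'")
    t = df["time_s"].to_numpy(dtype=np.float64)
    z = df["impedance_ohm"].to_numpy(dtype=np.float64)
    for name, arr in (("time_s", t), ("impedance_ohm", z)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise ValidationError(
                f"{path}: non-finite {name} value at data row {bad[0] + 1}"
            )
    if t.size < 2:
        raise ValidationError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 2
        raise ValidationError(f"{path}: non-increasing time at data row {row}")
    fs = (t.size - 1) / (t[-1] - t[0])
    ideal = t[0] + np.arange(t.size) / fs
    jitter = np.max(np.abs(t - ideal))
    if jitter > TIME_JITTER_TOL_S:
        row = int(np.argmax(np.abs(t - ideal))) + 1
        raise ValidationError(
            f"{path}: non-uniform sampling (jitter {jitter:.2e} s at data row {row})"
        )
    # snap fs to a clean value when the grid is metronomic (e.g. 250.0)
    if abs(fs - round(fs)) < 1e-6 * max(1.0, abs(fs)):
        fs = float(round(fs))
    return ImpedanceSignal(z, fs=fs, t0=float(t[0]))


def write_signal_csv(path: str | Path, signal: ImpedanceSignal) -> None:
    """Write a TI signal; impedance at full precision so round-trips are
    bit-identical."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,impedance_ohm\n")
        for i, v in enumerate(signal.samples):
            fh.write(f"{signal.t0 + i / signal.fs:.6f},{float(v)!r}\n")


def read_annotation_json(path: str | Path) -> EpisodeAnnotation:
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: invalid JSON ({exc})") from exc
    return EpisodeAnnotation.from_dict(data)


def write_annotation_json(path: str | Path, annotation: EpisodeAnnotation) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(annotation.to_dict(), fh, indent=1)
        fh.write("\n")


_RESULT_COLUMNS = [
    "window_index",
    "start_s",
    "detected",
    "rate_cpm",
    "peak_lag_s",
    "peak_score",
]


def write_results_csv(path: str | Path, results: Sequence[WindowResult]) -> None:
    """Write per-window detector results (rates to one decimal cpm)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(_RESULT_COLUMNS) + "\n")
        for r in results:
            start = "" if r.start_s is None else f"{r.start_s:.3f}"
            lag = "" if r.peak_lag_s is None else f"{r.peak_lag_s:.6f}"
            score = "" if r.peak_score is None else f"{r.peak_score:.6f}"
            fh.write(
                f"{r.window_index},{start},{int(r.detected)},"
                f"{r.rate_cpm:.1f},{lag},{score}\n"
            )


def read_results_csv(path: str | Path) -> list[WindowResult]:
    df = pd.read_csv(path)
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing result columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        detected = bool(row.detected)
        out.append(
            WindowResult(
                window_index=int(row.window_index),
                detected=detected,
                rate_cpm=float(row.rate_cpm) if detected else 0.0,
                peak_lag_s=None if pd.isna(row.peak_lag_s) else float(row.peak_lag_s),
                peak_score=None if pd.isna(row.peak_score) else float(row.peak_score),
                start_s=None if pd.isna(row.start_s) else float(row.start_s),
            )
        )
    return out


def write_report_json(path: str | Path, report_dict: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_dict, fh, indent=1)
        fh.write("\n")


def read_report_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: invalid JSON ({exc})") from exc


@dataclass
class RunManifest:
    """Provenance of a CLI run: command, config, paths, seeds, version."""

    command: str
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)
            fh.write("\n")
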