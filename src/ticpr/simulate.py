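"""Seeded synthetic resuscitation-episode generator.

Clinical AED recordings of out-of-hospital cardiac arrest are proprietary, so
the detector and evaluator are exercised on synthetic TI episodes whose
statistical structure mirrors what is reported for such databases: episode
mean compression rates centred near 173 cpm (IQR roughly 157-190) spanning
60-250 cpm, a chest compression fraction (CCF) around 68%, alternating
compression series and pauses, slow ventilation/drift components, and
additive noise.

Waveform model
--------------
Within a compression series, instants follow a jittered inter-compression
interval.  Each compression contributes a smooth even pulse centred on its
instant: a Hann taper over one local period carrying the fundamental plus
configurable 2nd/3rd harmonics.  Adjacent pulses abut at the inter-compression
midpoints, producing the quasi-sinusoidal TI fluctuation seen on real traces
while stressing the detector's fundamental-vs-harmonic peak selection.
Ventilation and baseline drift are slow sinusoids with random phases; noise is
white Gaussian.  The same seed reproduces an episode bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotations import EpisodeAnnotation
from .errors import GenerationError
from .signal import ImpedanceSignal

__all__ = [
    "EpisodeScenario",
    "TruncatedNormalRates",
    "generate_episode",
    "benchmark_scenarios",
    "generate_benchmark",
]

#: Working sampling frequency of generated episodes (Hz).
GENERATOR_FS = 250.0

# Alternating structure: compression series of 15-60 s separated by pauses of
# 3-20 s (rhythm checks, ventilations), rescaled to the target CCF.
_SERIES_RANGE_S = (15.0, 60.0)
_PAUSE_RANGE_S = (3.0, 20.0)

#: Hard floor on the inter-compression interval (~299 cpm), matching the
#: annotation invariant that compressions are more than 0.2 s apart.
_MIN_INTERVAL_S = 0.2007


@dataclass(frozen=True)
class EpisodeScenario:
    """Parameters of one synthetic episode.

    Amplitudes are in ohms on the baseline-suppressed TI scale; the default
    compression fluctuation of 1 ohm with 0.1-ohm noise reflects the clear
    compression artifacts of pads well applied.  Ventilation (0.2 ohm at
    8/min) and drift (0.1 ohm at 0.05 Hz) model the residual slow artifacts
    that survive the device's baseline suppression.
    """

    duration_s: float = 60.0
    rate_cpm_mean: float = 110.0
    rate_cpm_jitter_sd: float = 5.0
    ccf_target: float = 0.68
    fluctuation_amp_ohm: float = 1.0
    harmonic_weights: tuple[float, ...] = (0.25, 0.1)
    ventilation_rate_pm: float = 8.0
    ventilation_amp_ohm: float = 0.2
    drift_amp_ohm: float = 0.1
    drift_freq_hz: float = 0.05
    noise_sd_ohm: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise GenerationError("duration_s must be > 0")
        if not 0.0 <= self.ccf_target <= 1.0:
            raise GenerationError("ccf_target must lie in [0, 1]")
        if not 40.0 <= self.rate_cpm_mean <= 320.0:
            raise GenerationError("rate_cpm_mean must lie in [40, 320] cpm")
        for name in (
            "fluctuation_amp_ohm",
            "ventilation_amp_ohm",
            "drift_amp_ohm",
            "noise_sd_ohm",
            "rate_cpm_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")


def _segment_plan(
    scenario: EpisodeScenario, rng: np.random.Generator
) -> list[tuple[float, float, bool]]:
    """Alternating (start, end, is_series) segments tiling [0, duration).

    Series and pause lengths are drawn uniformly, then rescaled so the
    continuous-time compression fraction equals ``ccf_target`` exactly.
    """
    d = scenario.duration_s
    ccf = scenario.ccf_target
    if ccf >= 1.0:
        return [(0.0, d, True)]
    if ccf <= 0.0:
        return [(0.0, d, False)]
    mean_cycle = (sum(_SERIES_RANGE_S) + sum(_PAUSE_RANGE_S)) / 2.0
    m = max(1, int(round(d / mean_cycle)))
    series = rng.uniform(*_SERIES_RANGE_S, size=m)
    pauses = rng.uniform(*_PAUSE_RANGE_S, size=m)
    series *= ccf * d / series.sum()
    pauses *= (1.0 - ccf) * d / pauses.sum()
    segments: list[tuple[float, float, bool]] = []
    t = 0.0
    for s, p in zip(series, pauses):
        segments.append((t, t + s, True))
        segments.append((t + s, t + s + p, False))
        t += s + p
    last = segments[-1]
    segments[-1] = (last[0], d, last[2])  # absorb float residue
    return segments


def _series_instants(
    t_start: float,
    t_end: float,
    scenario: EpisodeScenario,
    rng: np.random.Generator,
) -> list[float]:
    """Jittered compression instants within one series.

    Per-interval rates are Gaussian around the scenario mean; intervals are
    truncated at +/-20% of the nominal period so the instantaneous rate stays
    coherent within any 2-s window.  Half a period of margin is kept at both
    series ends so each pulse fits inside its series.
    """
    t_nom = 60.0 / scenario.rate_cpm_mean

    def draw_interval() -> float:
        rate = rng.normal(scenario.rate_cpm_mean, scenario.rate_cpm_jitter_sd)
        interval = 60.0 / max(rate, 1.0)
        interval = min(max(interval, 0.8 * t_nom), 1.2 * t_nom)
        return max(interval, _MIN_INTERVAL_S)

    instants = []
    t = t_start + 0.5 * draw_interval()
    while t <= t_end - 0.5 * t_nom + 1e-9:
        instants.append(t)
        t += draw_interval()
    return instants


def _pulse_shape(u: np.ndarray, harmonics: Sequence[float]) -> np.ndarray:
    """Even compression pulse on u in [-1/2, 1/2] (u in local periods).

    Hann taper times fundamental-plus-harmonics, normalized to unit peak.
    """
    taper = 0.5 * (1.0 + np.cos(2 * np.pi * u))
    carrier = np.cos(2 * np.pi * u)
    for i, w in enumerate(harmonics, start=2):
        carrier = carrier + w * np.cos(2 * np.pi * i * u)
    return taper * carrier / (1.0 + sum(harmonics))


def generate_episode(
    scenario: EpisodeScenario,
) -> tuple[ImpedanceSignal, EpisodeAnnotation]:
    """Generate one synthetic TI episode with its ground-truth annotation.

    The emitted signal is sampled at 250 Hz; annotated instants coincide with
    local extrema of the noiseless compression component.  Deterministic for
    a fixed scenario (including its seed).
    """
    rng = np.random.default_rng(scenario.seed)
    fs = GENERATOR_FS
    n = int(round(scenario.duration_s * fs))
    t = np.arange(n) / fs

    segments = _segment_plan(scenario, rng)
    t_nom = 60.0 / scenario.rate_cpm_mean
    series_intervals: list[tuple[float, float]] = []
    instants: list[float] = []
    for a, b, is_series in segments:
        if not is_series:
            continue
        if b - a < 1.5 * t_nom:
            raise GenerationError(
                f"series ({a:.2f}, {b:.2f}) s too short to hold a compression at "
                f"{scenario.rate_cpm_mean:.0f} cpm; ccf_target/duration infeasible"
            )
        series_intervals.append((a, b))
        instants.extend(_series_instants(a, b, scenario, rng))

    compression = np.zeros(n)
    if scenario.fluctuation_amp_ohm > 0:
        for i, ti in enumerate(instants):
            if i + 1 < len(instants) and _same_series(ti, instants[i + 1], series_intervals):
                period = instants[i + 1] - ti
            elif i > 0 and _same_series(instants[i - 1], ti, series_intervals):
                period = ti - instants[i - 1]
            else:
                period = t_nom
            lo = max(0, int(np.ceil((ti - period / 2) * fs)))
            hi = min(n, int(np.floor((ti + period / 2) * fs)) + 1)
            if hi <= lo:
                continue
            u = (t[lo:hi] - ti) / period
            compression[lo:hi] += scenario.fluctuation_amp_ohm * _pulse_shape(
                u, scenario.harmonic_weights
            )

    vent_phase = rng.uniform(0.0, 2 * np.pi)
    drift_phase = rng.uniform(0.0, 2 * np.pi)
    samples = compression.copy()
    if scenario.ventilation_amp_ohm > 0 and scenario.ventilation_rate_pm > 0:
        samples += scenario.ventilation_amp_ohm * np.sin(
            2 * np.pi * (scenario.ventilation_rate_pm / 60.0) * t + vent_phase
        )
    if scenario.drift_amp_ohm > 0 and scenario.drift_freq_hz > 0:
        samples += scenario.drift_amp_ohm * np.sin(
            2 * np.pi * scenario.drift_freq_hz * t + drift_phase
        )
    if scenario.noise_sd_ohm > 0:
        samples += rng.normal(0.0, scenario.noise_sd_ohm, size=n)

    annotation = EpisodeAnnotation(series=series_intervals, instances_s=instants)
    return ImpedanceSignal(samples, fs=fs), annotation


def _same_series(t0: float, t1: float, series: list[tuple[float, float]]) -> bool:
    return any(a <= t0 and t1 < b for a, b in series)


@dataclass(frozen=True)
class TruncatedNormalRates:
    """Episode mean-rate distribution: normal truncated to [low, high] cpm.

    Defaults reproduce the reported per-episode mean compression rate
    distribution (median 173 cpm, IQR 157-190, hence sd ~= 33/1.349) within
    the detectable 60-250 cpm span.
    """

    center_cpm: float = 173.0
    sd_cpm: float = 24.5
    low_cpm: float = 60.0
    high_cpm: float = 250.0

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd_cpm == 0:
            return self.center_cpm
        for _ in range(1000):
            r = rng.normal(self.center_cpm, self.sd_cpm)
            if self.low_cpm <= r <= self.high_cpm:
                return float(r)
        raise GenerationError("rate distribution truncation rejected 1000 draws")


def benchmark_scenarios(
    n_episodes: int,
    master_seed: int,
    rate_distribution: Optional[TruncatedNormalRates] = None,
    template: Optional[EpisodeScenario] = None,
) -> list[EpisodeScenario]:
    """Derive ``n_episodes`` scenarios deterministically from a master seed."""
    if n_episodes <= 0:
        raise GenerationError("n_episodes must be > 0")
    dist = rate_distribution or TruncatedNormalRates()
    template = template or EpisodeScenario()
    rng = np.random.default_rng(master_seed)
    scenarios = []
    for _ in range(n_episodes):
        rate = dist.sample(rng)
        seed = int(rng.integers(0, 2**31 - 1))
        scenarios.append(
            dataclasses.replace(template, rate_cpm_mean=rate, seed=seed)
        )
    return scenarios


def generate_benchmark(
    n_episodes: int,
    master_seed: int,
    rate_distribution: Optional[TruncatedNormalRates] = None,
    template: Optional[EpisodeScenario] = None,
) -> list[tuple[ImpedanceSignal, EpisodeAnnotation]]:
    """Generate a reproducible benchmark collection of episodes."""
    return [
        generate_episode(s)
        for s in benchmark_scenarios(n_episodes, master_seed, rate_distribution, template)
    ]
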