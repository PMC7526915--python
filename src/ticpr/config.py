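"""Detector configuration.

The detector analyses the transthoracic impedance (TI) signal in consecutive
non-overlapping 2-s windows and searches the normalized autocorrelation for a
periodicity peak at lags between ``lag_min_s`` and ``lag_max_s``.  With the
defaults (0.24-1.0 s) the detectable compression-rate range is 60-250
compressions per minute (cpm): rate = 60 / lag.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError

#: Detection threshold on the overlap-normalized autocorrelation peak score.
#: Calibrated on a dedicated synthetic corpus (see docs/methods.md): windows
#: fully inside a compression series score >= ~0.82, while noise and
#: slow-artifact windows rarely exceed 0.6; 0.70 maximizes the worst of
#: Se/PPV/Sp/NPV on that corpus with margin to the weakest true-compression
#: window.
DEFAULT_THRESHOLD = 0.70


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the TI compression detector.

    Parameters
    ----------
    window_s
        Analysis window length in seconds.  2 s guarantees at least two
        compressions per window at the slowest detectable rate (60 cpm).
    fs_target
        Working sampling frequency in Hz; input signals are resampled to it.
    lag_min_s, lag_max_s
        Autocorrelation peak-search lag range in seconds.  The endpoints map
        to the fastest/slowest detectable rates (60/lag).
    lpf_cutoff_hz
        Low-pass cutoff in Hz.  Must sit above the fundamental of the fastest
        detectable rate (250 cpm = 4.17 Hz) so that it attenuates harmonics
        and broadband noise but keeps every detectable fundamental.
    detrend
        Per-window trend removal applied after filtering: ``"linear"``
        (default) subtracts the least-squares line, suppressing slow
        ventilation/drift artifacts locally without the multi-second edge
        transients a sub-hertz zero-phase high-pass would introduce;
        ``"mean"`` subtracts only the window mean.
    threshold
        Detection threshold on the normalized autocorrelation peak score.
    refine_peak
        If true, refine the integer-lag peak by three-point parabolic
        interpolation (reduces the lag-quantization rate error, which grows
        to ~4 cpm at 250 cpm on a 250-Hz lag grid).
    """

    window_s: float = 2.0
    fs_target: float = 250.0
    lag_min_s: float = 0.24
    lag_max_s: float = 1.0
    lpf_cutoff_hz: float = 5.0
    detrend: str = "linear"
    threshold: float = DEFAULT_THRESHOLD
    refine_peak: bool = True

    def __post_init__(self) -> None:
        if self.fs_target <= 0:
            raise ConfigurationError("fs_target must be > 0")
        if self.window_s <= 0:
            raise ConfigurationError("window_s must be > 0")
        if not (0 < self.lag_min_s < self.lag_max_s < self.window_s):
            raise ConfigurationError(
                "lag range must satisfy 0 < lag_min_s < lag_max_s < window_s"
            )
        if not (0 < self.threshold < 1):
            raise ConfigurationError("threshold must lie in (0, 1)")
        if self.lpf_cutoff_hz <= 0 or self.lpf_cutoff_hz >= self.fs_target / 2:
            raise ConfigurationError("lpf_cutoff_hz must lie in (0, fs_target/2)")
        if self.lpf_cutoff_hz < 1.0 / self.lag_min_s:
            raise ConfigurationError(
                "lpf_cutoff_hz must not fall below the fastest detectable "
                f"fundamental ({1.0 / self.lag_min_s:.2f} Hz)"
            )
        if self.detrend not in ("linear", "mean"):
            raise ConfigurationError("detrend must be 'linear' or 'mean'")

    @property
    def rate_min_cpm(self) -> float:
        """Slowest detectable rate, 60 / lag_max_s."""
        return 60.0 / self.lag_max_s

    @property
    def rate_max_cpm(self) -> float:
        """Fastest detectable rate, 60 / lag_min_s."""
        return 60.0 / self.lag_min_s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "DetectorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "DetectorConfig":
        """Load a config from a TOML or JSON file mirroring the fields."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        return cls.from_mapping(data)
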