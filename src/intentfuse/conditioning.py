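"""Signal conditioning: band-pass filtering, MVIC normalisation,
truncation to a classification horizon, and sliding-window segmentation.

sEMG channels are band-pass filtered (10-500 Hz, 4th-order Butterworth) and
normalised by the per-muscle maximal-voluntary-contraction reference so all
muscles share a common unitless scale.  IMU channels pass through
untouched.  Filtering is single-pass causal by default, keeping the chain
valid for streaming use; zero-phase filtering is available via config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synthetic_data import RawTrial, SensorSpec

__all__ = [
    "FilterSpec",
    "WindowSpec",
    "bandpass",
    "mvic_normalise",
    "truncate",
    "windows",
    "window_count",
    "condition_trial",
]

logger = logging.getLogger(__name__)

_clip_warned: set[tuple[float, float]] = set()


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass parameters (defaults: 10-500 Hz, order 4)."""

    low_cut: float = 10.0
    high_cut: float = 500.0
    order: int = 4
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout (defaults: 200 ms windows, 50 ms step, 1000 ms
    horizon, i.e. consecutive windows overlap by 150 ms)."""

    length: float = 200.0
    step: float = 50.0
    horizon: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.length <= self.horizon:
            raise ValueError("need 0 < step <= length <= horizon")

    @property
    def n_windows(self) -> int:
        return int(np.floor((self.horizon - self.length) / self.step)) + 1


def bandpass(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Band-pass filter a 1-D signal; output length equals input length.

    An upper edge at or above the Nyquist frequency is clipped to
    0.99 x Nyquist (a digital band edge at Nyquist is undefined).
    """
    if fs <= 2 * spec.low_cut:
        raise ValueError(f"sampling rate {fs} too low for low_cut {spec.low_cut}")
    high = spec.high_cut
    nyq = fs / 2.0
    if high >= nyq:
        high = 0.99 * nyq
        if (spec.high_cut, fs) not in _clip_warned:  # warn once per edge/rate pair
            _clip_warned.add((spec.high_cut, fs))
            logger.warning(
                "high_cut %.6g Hz >= Nyquist %.6g Hz; clipped to %.6g Hz",
                spec.high_cut, nyq, high,
            )
    sos = sps.butter(spec.order, [spec.low_cut, high], btype="bandpass", fs=fs, output="sos")
    x = np.asarray(x, dtype=float)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def mvic_normalise(x: np.ndarray, mvic_reference: float) -> np.ndarray:
    """Scale a signal to units of the maximal-voluntary-contraction
    reference amplitude."""
    if mvic_reference <= 0:
        raise ValueError("mvic_reference must be positive")
    return np.asarray(x, dtype=float) / mvic_reference


def truncate(trial: RawTrial, horizon: float) -> RawTrial:
    """Drop all samples after ``horizon`` ms, for every sensor."""
    if horizon > trial.duration:
        raise ValueError(f"horizon {horizon} exceeds trial duration {trial.duration}")
    data = {}
    for sid, (t, x) in trial.data.items():
        mask = t <= horizon * (1 + 1e-12) + 1e-9  # tolerate timestamp round-off
        data[sid] = (t[mask], x[mask])
    return replace(
        trial,
        duration=horizon,
        data=data,
        provenance=trial.provenance + [f"truncate({horizon})"],
    )


def window_count(n_samples: int, length: int, step: int) -> int:
    """Number of length-``length`` windows advanced by ``step`` samples that
    fit wholly inside ``n_samples`` samples."""
    if n_samples < length:
        raise ValueError("signal shorter than one window")
    return (n_samples - length) // step + 1


def windows(x: np.ndarray, spec: WindowSpec, fs: float) -> np.ndarray:
    """Segment a 1-D signal into overlapping windows.

    Returns an array of shape (n_windows, window_samples); consecutive
    windows overlap by ``length - step`` ms.
    """
    x = np.asarray(x)
    length = int(round(spec.length * fs / 1000.0))
    step = int(round(spec.step * fs / 1000.0))
    n = window_count(x.shape[0], length, step)
    idx = np.arange(length)[None, :] + step * np.arange(n)[:, None]
    return x[idx]


def condition_trial(
    trial: RawTrial,
    sensors: list[SensorSpec],
    filter_spec: FilterSpec = FilterSpec(),
) -> RawTrial:
    """Apply the sEMG conditioning chain (band-pass then MVIC
    normalisation) to every sEMG channel of a trial; IMU streams pass
    through unchanged."""
    spec_by_id = {s.sensor_id: s for s in sensors}
    data = {}
    for sid, (t, x) in trial.data.items():
        spec = spec_by_id.get(sid)
        if spec is not None and spec.modality == "semg":
            fs = spec.sampling_rate
            y = np.column_stack(
                [bandpass(x[:, c], filter_spec, fs) for c in range(x.shape[1])]
            )
            y = mvic_normalise(y, spec.mvic_reference)
            data[sid] = (t, y)
        else:
            data[sid] = (t, x)
    return replace(
        trial,
        data=data,
        provenance=trial.provenance
        + [f"bandpass({filter_spec.low_cut}-{filter_spec.high_cut},o{filter_spec.order})",
           "mvic_normalise"],
    )
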