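"""Per-window sEMG features and per-trial IMU features.

The sEMG feature set is the standard myoelectric repertoire computed
within each 200 ms window: integrated EMG (IEMG), mean absolute value
(MAV), mean absolute value slope (MAVS, a cross-window difference),
variance about zero (VAR), root mean square (RMS), waveform length (WL),
autoregressive coefficients to fourth order (AR1..AR4) and the median and
mean frequency of the window periodogram (FMD, FMN).

The ``table1`` preset (default) holds the eleven within-window features
(MAVS excluded); ``full`` adds MAVS for twelve.  IMU sensors contribute
their raw channel values — orientation quaternion (4), accelerometer (3)
and magnetometer (3) — taken at the last sample at or before the
classification horizon, 10 values per IMU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .conditioning import WindowSpec, truncate, windows
from .synthetic_data import RawTrial, SensorSpec

__all__ = [
    "FeatureConfig",
    "SEMG_FEATURES_FULL",
    "SEMG_FEATURES_TABLE1",
    "ar_coefficients",
    "median_mean_frequency",
    "semg_features",
    "semg_feature_matrix",
    "imu_features",
    "assemble_feature_matrix",
    "FeatureMatrix",
]

SEMG_FEATURES_FULL = ("IEMG", "MAV", "MAVS", "VAR", "RMS", "WL",
                      "AR1", "AR2", "AR3", "AR4", "FMD", "FMN")
SEMG_FEATURES_TABLE1 = tuple(f for f in SEMG_FEATURES_FULL if f != "MAVS")


@dataclass(frozen=True)
class FeatureConfig:
    semg_features: tuple[str, ...] = SEMG_FEATURES_TABLE1
    ar_order: int = 4
    ar_estimator: str = "ls"      # "ls" (least-squares) | "burg"
    imu_mode: str = "last_sample"  # "last_sample" | "window_mean"

    def __post_init__(self) -> None:
        if len(set(self.semg_features)) != len(self.semg_features):
            raise ValueError("semg_features must be duplicate-free")
        unknown = set(self.semg_features) - set(SEMG_FEATURES_FULL)
        if unknown:
            raise ValueError(f"unknown sEMG features: {sorted(unknown)}")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if self.ar_estimator not in ("ls", "burg"):
            raise ValueError("ar_estimator must be 'ls' or 'burg'")

    @classmethod
    def preset(cls, name: str) -> "FeatureConfig":
        if name == "table1":
            return cls(semg_features=SEMG_FEATURES_TABLE1)
        if name == "full":
            return cls(semg_features=SEMG_FEATURES_FULL)
        raise ValueError(f"unknown preset {name!r}")

    @property
    def n_semg(self) -> int:
        return len(self.semg_features)


def ar_coefficients(x: np.ndarray, order: int, estimator: str = "ls") -> np.ndarray:
    """Autoregressive coefficients a_1..a_p of x_t = sum_k a_k x_{t-k} + e.

    ``ls`` solves the covariance-method normal equations explicitly;
    ``burg`` uses the Burg recursion (statsmodels), often preferred for
    very short windows but numerically a different estimator.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < order + 1:
        raise ValueError(f"window of {n} samples too short for AR order {order}")
    if estimator == "burg":
        from statsmodels.regression.linear_model import burg

        coefs, _ = burg(x, order=order, demean=True)
        return np.asarray(coefs)
    xm = x - x.mean()
    # Lag matrix: row t has xm[t-1], ..., xm[t-p]; solve the normal
    # equations (A'A) a = A'b directly (covariance method).
    cols = [xm[order - k - 1: n - k - 1] for k in range(order)]
    a_mat = np.column_stack(cols)
    b = xm[order:]
    gram = a_mat.T @ a_mat
    rhs = a_mat.T @ b
    try:
        return np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(gram) @ rhs


def median_mean_frequency(x: np.ndarray, fs: float) -> tuple[float, float]:
    """Median (FMD) and power-weighted mean (FMN) frequency of a window.

    Uses a single boxcar periodogram after mean removal.  FMD is the first
    grid frequency at which cumulative power reaches half the total.
    """
    f, p = sps.periodogram(np.asarray(x, dtype=float), fs=fs,
                           window="boxcar", detrend="constant")
    total = p.sum()
    if total <= 0:
        return 0.0, 0.0
    csum = np.cumsum(p)
    fmd = float(f[np.searchsorted(csum, total / 2.0)])
    fmn = float((f * p).sum() / total)
    return fmd, fmn


def semg_features(
    window: np.ndarray,
    prev_window_mav: float | None = None,
    config: FeatureConfig = FeatureConfig(),
    fs: float = 1000.0,
) -> np.ndarray:
    """Feature vector for one sEMG window, ordered per ``config``."""
    x = np.asarray(window, dtype=float)
    n = x.size
    if n < config.ar_order + 1:
        raise ValueError("window shorter than ar_order + 1 samples")
    absx = np.abs(x)
    mav = absx.mean()
    vals: dict[str, float] = {}
    req = set(config.semg_features)
    if "IEMG" in req:
        vals["IEMG"] = float(absx.sum())
    if "MAV" in req:
        vals["MAV"] = float(mav)
    if "MAVS" in req:
        vals["MAVS"] = float(mav - prev_window_mav) if prev_window_mav is not None else 0.0
    if "VAR" in req:
        vals["VAR"] = float((x**2).sum() / (n - 1))
    if "RMS" in req:
        vals["RMS"] = float(np.sqrt((x**2).mean()))
    if "WL" in req:
        vals["WL"] = float(np.abs(np.diff(x)).sum())
    if req & {"AR1", "AR2", "AR3", "AR4"}:
        coefs = ar_coefficients(x, config.ar_order, config.ar_estimator)
        for k in range(config.ar_order):
            name = f"AR{k + 1}"
            if name in req:
                vals[name] = float(coefs[k])
    if req & {"FMD", "FMN"}:
        fmd, fmn = median_mean_frequency(x, fs)
        vals["FMD"], vals["FMN"] = fmd, fmn
    out = np.array([vals[name] for name in config.semg_features])
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature value computed")
    return out


def semg_feature_matrix(
    signal: np.ndarray,
    window_spec: WindowSpec,
    fs: float,
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Per-window features for one sEMG channel: (n_windows, n_features).

    MAVS (when configured) is the MAV difference to the previous window,
    defined as 0 for the first window.
    """
    segs = windows(signal, window_spec, fs)
    prev: float | None = None
    rows = []
    for seg in segs:
        rows.append(semg_features(seg, prev, config, fs))
        prev = float(np.abs(seg).mean())
    return np.vstack(rows)


def imu_features(
    t: np.ndarray, x: np.ndarray, horizon: float, mode: str = "last_sample"
) -> np.ndarray:
    """Raw IMU channel values at the classification horizon.

    ``last_sample`` takes the last sample at or before ``horizon``;
    ``window_mean`` averages all samples up to the horizon.
    """
    # tolerate float round-off in timestamp construction at the horizon
    mask = np.asarray(t) <= horizon * (1 + 1e-12) + 1e-9
    if not mask.any():
        raise ValueError(f"no IMU sample at or before {horizon} ms")
    if mode == "window_mean":
        return np.asarray(x)[mask].mean(axis=0)
    return np.asarray(x)[mask][-1].astype(float)


@dataclass
class FeatureMatrix:
    """Per-sensor feature rows plus row-to-trial bookkeeping.

    For sEMG sensors ``values`` has one row per (trial, window) in trial-
    major order; for IMU sensors one row per trial.  ``trial_index`` maps
    each row to its position in ``trial_ids``.
    """

    sensor_id: str
    modality: str
    values: np.ndarray
    trial_index: np.ndarray
    window_index: np.ndarray | None
    feature_names: tuple[str, ...]


def assemble_feature_matrix(
    trials: list[RawTrial],
    sensors: list[SensorSpec],
    horizon: float,
    config: FeatureConfig = FeatureConfig(),
    window_spec: WindowSpec | None = None,
) -> tuple[dict[str, FeatureMatrix], dict[str, np.ndarray]]:
    """Build one feature matrix per sensor over conditioned trials.

    Returns ``(matrices, meta)`` where ``meta`` holds aligned per-trial
    arrays: ``trial_ids``, ``category``, ``activity``, ``participant``.
    Trials missing any sensor stream are excluded with a logged diagnostic.
    Row order is trial-major and identical across sensors.
    """
    import logging

    logger = logging.getLogger(__name__)
    if window_spec is None:
        window_spec = WindowSpec(horizon=horizon)
    elif window_spec.horizon != horizon:
        raise ValueError("window_spec.horizon must equal the requested horizon")

    wanted = [s.sensor_id for s in sensors]
    kept = [tr for tr in trials if all(sid in tr.data for sid in wanted)]
    for tr in trials:
        if tr not in kept:
            missing = [sid for sid in wanted if sid not in tr.data]
            logger.warning("trial %s missing sensors %s; excluded", tr.trial_id, missing)

    meta = {
        "trial_ids": np.array([tr.trial_id for tr in kept]),
        "category": np.array([tr.category_label for tr in kept]),
        "activity": np.array([tr.activity_label for tr in kept]),
        "participant": np.array([tr.participant_id for tr in kept]),
    }
    matrices: dict[str, FeatureMatrix] = {}
    for spec in sensors:
        rows, tidx, widx = [], [], []
        for i, tr in enumerate(kept):
            tcut = truncate(tr, horizon)
            t, x = tcut.data[spec.sensor_id]
            if spec.modality == "semg":
                fm = semg_feature_matrix(x[:, 0], window_spec, spec.sampling_rate, config)
                rows.append(fm)
                tidx.extend([i] * fm.shape[0])
                widx.extend(range(fm.shape[0]))
            else:
                rows.append(imu_features(t, x, horizon, config.imu_mode)[None, :])
                tidx.append(i)
        if spec.modality == "semg":
            values = np.vstack(rows) if rows else np.empty((0, config.n_semg))
            names = config.semg_features
            win = np.array(widx, dtype=int)
        else:
            values = np.vstack(rows) if rows else np.empty((0, 10))
            names = tuple(spec.channels)
            win = None
        matrices[spec.sensor_id] = FeatureMatrix(
            sensor_id=spec.sensor_id,
            modality=spec.modality,
            values=values,
            trial_index=np.array(tidx, dtype=int),
            window_index=win,
            feature_names=names,
        )
    return matrices, meta
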