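"""Shared signal transforms.

Three primitives used by every detector:

* :func:`acceleration_magnitude` — Euclidean norm of the triaxial
  accelerometer output, the orientation-invariant movement intensity on
  which the annotation convention is based;
* :func:`low_pass` — zero-phase Butterworth low-pass denoising;
* :func:`lag_lead_features` — per-timepoint difference features
  ``x[t] - x[t-k]`` (lag) and ``x[t] - x[t+k]`` (lead) feeding the
  gradient-boosted classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .imu_io import ImuRecording

__all__ = [
    "FilterSpec",
    "LagLeadSpec",
    "acceleration_magnitude",
    "low_pass",
    "lag_lead_features",
    "resolve_channel",
    "DERIVED_CHANNELS",
]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter configuration.

    Zero-phase filtering (forward-backward) is used so denoising adds no
    group delay: the evaluation of every detector is about event timing,
    and a causal filter would bias all detections late by construction.
    The effective magnitude response is the squared Butterworth response.
    """

    kind: str = "butterworth"
    order: int = 4
    cutoff_hz: float = 10.0
    mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.kind != "butterworth":
            raise ValueError(f"unsupported filter kind {self.kind!r}")
        if self.mode != "zero_phase":
            raise ValueError(f"unsupported filter mode {self.mode!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")

    def validate_rate(self, sample_rate_hz: float) -> None:
        if self.cutoff_hz >= sample_rate_hz / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must be below the Nyquist "
                f"frequency {sample_rate_hz / 2} Hz"
            )


@dataclass(frozen=True)
class LagLeadSpec:
    """Offsets (in samples) for the difference features.

    The default — lags 5..10 and leads 5..10 — yields 12 derived series
    per channel; at 100 Hz the offsets span 0.05–0.1 s, the time scale of
    within-step dynamics.
    """

    offsets_back: tuple[int, ...] = (5, 6, 7, 8, 9, 10)
    offsets_forward: tuple[int, ...] = (5, 6, 7, 8, 9, 10)

    def __post_init__(self) -> None:
        if not self.offsets_back and not self.offsets_forward:
            raise ValueError("at least one offset is required")
        if any(k < 1 for k in self.offsets_back + self.offsets_forward):
            raise ValueError("all offsets must be >= 1")

    @property
    def n_per_channel(self) -> int:
        return len(self.offsets_back) + len(self.offsets_forward)


def acceleration_magnitude(acc_x, acc_y, acc_z) -> np.ndarray:
    """Element-wise Euclidean norm ``sqrt(x^2 + y^2 + z^2)`` in m/s^2."""
    x = np.asarray(acc_x, dtype=float)
    y = np.asarray(acc_y, dtype=float)
    z = np.asarray(acc_z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError(
            f"axis length mismatch: {x.shape}, {y.shape}, {z.shape}"
        )
    return np.sqrt(x * x + y * y + z * z)


def low_pass(series, spec: FilterSpec, sample_rate_hz: float) -> np.ndarray:
    """Zero-phase low-pass filter one series.

    The DC component is preserved exactly (Butterworth gain is 1 at DC
    and the odd edge padding of the forward-backward pass keeps constant
    signals constant).
    """
    x = np.asarray(series, dtype=float)
    spec.validate_rate(sample_rate_hz)
    padlen = 3 * spec.order
    if len(x) <= 3 * (spec.order + 1):
        raise ValueError(
            f"series of length {len(x)} too short for zero-phase filtering "
            f"with order {spec.order}"
        )
    b, a = butter(spec.order, spec.cutoff_hz, btype="low", fs=sample_rate_hz)
    return filtfilt(b, a, x, padlen=padlen)


# ---------------------------------------------------------------------------
# derived channels and lag/lead features
# ---------------------------------------------------------------------------

def _magnitude_of(rec: ImuRecording, prefix: str) -> np.ndarray:
    return acceleration_magnitude(
        rec.channel(f"{prefix}_X"),
        rec.channel(f"{prefix}_Y"),
        rec.channel(f"{prefix}_Z"),
    )


def _yaw_rate(rec: ImuRecording) -> np.ndarray:
    yaw = rec.channel("Yaw")
    rate = np.empty_like(yaw)
    rate[1:] = np.diff(yaw)
    rate[0] = np.nan  # first difference undefined at t = 0
    return rate


#: Derived series available to the feature builder beyond the raw channels.
DERIVED_CHANNELS = {
    "Acc_magnitude": lambda rec: _magnitude_of(rec, "Acc"),
    "FreeAcc_magnitude": lambda rec: _magnitude_of(rec, "FreeAcc"),
    "Gyr_magnitude": lambda rec: _magnitude_of(rec, "Gyr"),
    "Yaw_rate": _yaw_rate,
}


def resolve_channel(rec: ImuRecording, name: str) -> np.ndarray:
    """Return a raw or derived channel by name."""
    if name in rec.channels:
        return rec.channel(name)
    if name in DERIVED_CHANNELS:
        return DERIVED_CHANNELS[name](rec)
    raise ValueError(
        f"unknown channel {name!r}: not in recording and not derivable "
        f"(derived channels: {sorted(DERIVED_CHANNELS)})"
    )


def lag_lead_features(
    rec: ImuRecording,
    spec: LagLeadSpec = LagLeadSpec(),
    channels=None,
) -> pd.DataFrame:
    """Per-timepoint lag/lead difference features.

    For channel ``c`` and offset ``k``, the lag feature is
    ``c[t] - c[t-k]`` and the lead feature ``c[t] - c[t+k]``.  Positions
    where the shifted index falls outside the recording carry NaN — the
    tree ensemble downstream handles missing values natively; zero
    padding would fabricate spurious edge changes instead.

    Column names are ``<channel>_lag<k>`` / ``<channel>_lead<k>``, lags
    first, in offset order, grouped by channel.
    """
    if channels is None:
        from .gbm_detector import DEFAULT_GBM_CHANNELS

        channels = DEFAULT_GBM_CHANNELS
    n = rec.n_samples
    data: dict[str, np.ndarray] = {}
    for name in channels:
        series = resolve_channel(rec, name)
        for k in spec.offsets_back:
            col = np.full(n, np.nan)
            if k < n:
                col[k:] = series[k:] - series[:-k]
            data[f"{name}_lag{k}"] = col
        for k in spec.offsets_forward:
            col = np.full(n, np.nan)
            if k < n:
                col[:-k] = series[:-k] - series[k:]
            data[f"{name}_lead{k}"] = col
    return pd.DataFrame(data)
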