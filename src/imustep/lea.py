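"""Unsupervised step detection via significant local extrema.

The premise: leg-movement changes leave local minima/maxima across many
channels at once.  The pipeline, per recording:

1. low-pass filter each configured channel;
2. find local extrema with a sliding dominance window (a point must be
   the strict extremum of the window centred on it);
3. keep only *significant* extrema — those deviating from their
   immediate surroundings by at least ``sig_sd_factor`` standard
   deviations (this discards extrema in motionless stretches);
4. merge channels: an extremum is *important* if it occurs on more than
   one channel at the same sample or has another extremum within
   ``importance_radius_s`` on any channel;
5. grow candidate step intervals: seed a 0.6 s interval at the first
   important extremum and absorb any further extremum that follows the
   interval's end by at most 0.12 s, extending the end to it;
6. trim leading extrema that are more than 0.12 s from their successor;
7. drop candidates that are too short (< 0.2 s), not dense enough
   (consecutive extrema more than 0.25 s apart, or fewer than two
   extrema), or too weak (peak acceleration magnitude below 11 m/s^2 —
   leg tremor rather than a step).

All second-valued thresholds convert to samples once, via
``round(x * sample_rate_hz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .imu_io import ImuRecording, StepInterval, seconds_to_sample
from .signal_prep import FilterSpec, acceleration_magnitude, low_pass

__all__ = [
    "LeaConfig",
    "Extremum",
    "ExtremumKind",
    "sliding_extrema",
    "significance_filter",
    "important_extrema",
    "grow_intervals",
    "trim_leading",
    "filter_intervals",
    "detect_lea",
]

LEA_DEFAULT_CHANNELS: tuple[str, ...] = (
    "Acc_X", "Acc_Y", "Acc_Z",
    "Gyr_X", "Gyr_Y", "Gyr_Z",
    "Roll", "Pitch", "Yaw",
)


class ExtremumKind(str, Enum):
    MIN = "min"
    MAX = "max"


@dataclass(frozen=True)
class Extremum:
    channel: str
    index: int
    kind: ExtremumKind
    value: float


@dataclass(frozen=True)
class LeaConfig:
    """All eight thresholds of the method, in their natural units."""

    channels: tuple[str, ...] = LEA_DEFAULT_CHANNELS
    extrema_window: int = 140
    sig_sd_factor: float = 0.5
    sig_neighborhood: int = 10
    importance_radius_s: float = 0.1
    seed_interval_s: float = 0.6
    extend_gap_s: float = 0.12
    min_duration_s: float = 0.2
    max_extrema_gap_s: float = 0.25
    min_peak_magnitude: float = 11.0
    filter: FilterSpec = field(default_factory=FilterSpec)

    def __post_init__(self) -> None:
        if self.extrema_window < 3:
            raise ValueError("extrema_window must be >= 3")
        if self.sig_sd_factor <= 0:
            raise ValueError("sig_sd_factor must be positive")
        if self.sig_neighborhood % 2 != 0 or self.sig_neighborhood < 2:
            raise ValueError("sig_neighborhood must be a positive even number")
        for name in (
            "importance_radius_s", "seed_interval_s", "extend_gap_s",
            "min_duration_s", "max_extrema_gap_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def sliding_extrema(series, window: int, channel: str = "") -> list[Extremum]:
    """Strict local extrema under a centred dominance window.

    Index ``i`` is reported as a maximum (minimum) iff ``series[i]`` is
    strictly greater (smaller) than every other value in the window of
    ``window`` samples centred on it — ``floor(window/2)`` samples
    before, the rest after, truncated at the edges.  Tied values are
    never extrema, so plateaus (and constant series) yield nothing.
    """
    x = np.asarray(series, dtype=float)
    if window < 3:
        raise ValueError("window must be >= 3")
    n = len(x)
    if n == 0:
        return []
    half_before = window // 2
    half_after = window - half_before - 1
    # origin shifts the (even-sized) window so it spans
    # [i - half_before, i + half_after]
    origin = (window - 1) // 2 - half_before
    wmax = maximum_filter1d(x, size=window, mode="nearest", origin=origin)
    wmin = minimum_filter1d(x, size=window, mode="nearest", origin=origin)
    out: list[Extremum] = []
    for i in np.flatnonzero((x == wmax) | (x == wmin)):
        lo = max(0, i - half_before)
        hi = min(n, i + half_after + 1)
        others = np.concatenate([x[lo:i], x[i + 1 : hi]])
        if others.size == 0:
            continue
        if x[i] > others.max():
            out.append(Extremum(channel, int(i), ExtremumKind.MAX, float(x[i])))
        elif x[i] < others.min():
            out.append(Extremum(channel, int(i), ExtremumKind.MIN, float(x[i])))
    return out


def significance_filter(
    extrema: list[Extremum],
    series,
    sd_factor: float = 0.5,
    neighborhood: int = 10,
) -> list[Extremum]:
    """Keep extrema deviating >= ``sd_factor`` SDs from their surroundings.

    The surroundings are the ``neighborhood/2`` samples on each side of
    the extremum, excluding it (truncated at edges).  Where the
    surroundings have zero spread, an extremum survives iff it deviates
    from them at all; a point equal to a flat neighbourhood — the
    motionless case — is removed.
    """
    if neighborhood % 2 != 0:
        raise ValueError("neighborhood must be even (split across both sides)")
    x = np.asarray(series, dtype=float)
    half = neighborhood // 2
    kept: list[Extremum] = []
    for e in extrema:
        i = e.index
        surrounding = np.concatenate(
            [x[max(0, i - half) : i], x[i + 1 : i + 1 + half]]
        )
        if surrounding.size == 0:
            continue
        dev = abs(e.value - surrounding.mean())
        sd = surrounding.std(ddof=1) if surrounding.size > 1 else 0.0
        if sd == 0.0:
            if dev > 0:
                kept.append(e)
        elif dev >= sd_factor * sd:
            kept.append(e)
    return kept


def important_extrema(
    per_channel: dict[str, list[Extremum]],
    radius_s: float = 0.1,
    sample_rate_hz: float = 100.0,
) -> list[int]:
    """Merge per-channel significant extrema into important-extrema indices.

    An index is kept iff extrema occur there on at least two channels,
    or some other extremum (any channel, any kind) lies within
    ``radius_s`` of it.  The result is deduplicated and sorted.
    """
    radius = seconds_to_sample(radius_s, sample_rate_hz)
    channels_at: dict[int, set[str]] = {}
    for channel, extrema in per_channel.items():
        for e in extrema:
            channels_at.setdefault(e.index, set()).add(channel)
    indices = np.array(sorted(channels_at), dtype=int)
    kept = []
    for pos, i in enumerate(indices):
        if len(channels_at[int(i)]) >= 2:
            kept.append(int(i))
            continue
        left = pos > 0 and i - indices[pos - 1] <= radius
        right = pos + 1 < len(indices) and indices[pos + 1] - i <= radius
        if left or right:
            kept.append(int(i))
    return kept


def _grow_groups(
    important: list[int],
    seed_len: int,
    extend_gap: int,
) -> list[list[int]]:
    """Group sorted extrema indices into candidate-step member lists."""
    groups: list[list[int]] = []
    i = 0
    n = len(important)
    while i < n:
        members = [important[i]]
        end = important[i] + seed_len
        i += 1
        while i < n:
            nxt = important[i]
            if nxt < end:
                members.append(nxt)
                i += 1
            elif nxt - end <= extend_gap:
                members.append(nxt)
                end = nxt + 1
                i += 1
            else:
                break
        groups.append(members)
    return groups


def _group_interval(members: list[int], seed_len: int, n_samples: int) -> StepInterval:
    end = max(members[0] + seed_len, members[-1] + 1)
    return StepInterval(members[0], min(end, n_samples))


def grow_intervals(
    important: list[int],
    seed_interval_s: float = 0.6,
    extend_gap_s: float = 0.12,
    sample_rate_hz: float = 100.0,
    n_samples: int | None = None,
) -> list[StepInterval]:
    """Grow candidate step intervals from sorted important extrema.

    Each interval is seeded with length ``seed_interval_s`` at its first
    extremum; an extremum past the current end but within
    ``extend_gap_s`` of it extends the end to that extremum.
    """
    if list(important) != sorted(important):
        raise ValueError("important extrema indices must be sorted")
    seed_len = seconds_to_sample(seed_interval_s, sample_rate_hz)
    extend_gap = seconds_to_sample(extend_gap_s, sample_rate_hz)
    if n_samples is None:
        n_samples = (important[-1] + seed_len + 1) if important else 0
    return [
        _group_interval(g, seed_len, n_samples)
        for g in _grow_groups(list(important), seed_len, extend_gap)
    ]


def trim_leading(
    groups: list[list[int]],
    extend_gap_s: float = 0.12,
    sample_rate_hz: float = 100.0,
) -> list[list[int]]:
    """Drop leading extrema too far (> ``extend_gap_s``) from their successor."""
    gap = seconds_to_sample(extend_gap_s, sample_rate_hz)
    trimmed = []
    for members in groups:
        members = list(members)
        while len(members) >= 2 and members[1] - members[0] > gap:
            members.pop(0)
        trimmed.append(members)
    return trimmed


def filter_intervals(
    candidates: list[tuple[StepInterval, list[int]]],
    rec: ImuRecording,
    min_duration_s: float = 0.2,
    max_extrema_gap_s: float = 0.25,
    min_peak_magnitude: float = 11.0,
) -> list[StepInterval]:
    """Final duration / density / magnitude filter.

    A candidate survives iff its duration is at least ``min_duration_s``,
    it holds at least two important extrema with every consecutive gap at
    most ``max_extrema_gap_s``, and the (raw) acceleration magnitude
    somewhere inside it reaches ``min_peak_magnitude``.
    """
    rec.require_channels(("Acc_X", "Acc_Y", "Acc_Z"))
    rate = rec.sample_rate_hz
    max_gap = seconds_to_sample(max_extrema_gap_s, rate)
    mag = acceleration_magnitude(
        rec.channel("Acc_X"), rec.channel("Acc_Y"), rec.channel("Acc_Z")
    )
    out = []
    for interval, members in candidates:
        if interval.duration_s(rate) < min_duration_s:
            continue
        if len(members) < 2:
            continue
        gaps = np.diff(members)
        if len(gaps) and gaps.max() > max_gap:
            continue
        if np.max(mag[interval.start : interval.end]) < min_peak_magnitude:
            continue
        out.append(interval)
    return out


def detect_lea(rec: ImuRecording, cfg: LeaConfig = LeaConfig()) -> list[StepInterval]:
    """Run the full local-extrema pipeline on one recording."""
    rec.require_channels(cfg.channels)
    rate = rec.sample_rate_hz
    per_channel: dict[str, list[Extremum]] = {}
    for name in sorted(cfg.channels):  # order-independent by construction
        filtered = low_pass(rec.channel(name), cfg.filter, rate)
        extrema = sliding_extrema(filtered, cfg.extrema_window, channel=name)
        per_channel[name] = significance_filter(
            extrema, filtered, cfg.sig_sd_factor, cfg.sig_neighborhood
        )
    important = important_extrema(per_channel, cfg.importance_radius_s, rate)

    seed_len = seconds_to_sample(cfg.seed_interval_s, rate)
    extend_gap = seconds_to_sample(cfg.extend_gap_s, rate)
    groups = _grow_groups(important, seed_len, extend_gap)
    groups = trim_leading(groups, cfg.extend_gap_s, rate)
    candidates = [
        (_group_interval(g, seed_len, rec.n_samples), g)
        for g in groups
        if g
    ]
    intervals = filter_intervals(
        candidates, rec,
        cfg.min_duration_s, cfg.max_extrema_gap_s, cfg.min_peak_magnitude,
    )
    # growing seeds are ordered, but trimming can stretch a re-derived
    # interval past the next seed; clip to keep the output disjoint
    clipped: list[StepInterval] = []
    for iv in sorted(intervals):
        if clipped and iv.start < clipped[-1].end:
            if iv.end <= clipped[-1].end:
                continue
            iv = StepInterval(clipped[-1].end, iv.end)
        clipped.append(iv)
    return clipped
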