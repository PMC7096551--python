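"""Reading and writing IMU recordings and step-annotation tables.

The on-disk formats are plain delimited text: one recording file per
animal-leg profile with a header row naming the channels and one row per
sample, and one annotation table with columns ``profile_id, leg_id,
start_s, end_s`` (seconds, written with 3 decimals).

Coordinate conventions used throughout the package
--------------------------------------------------
* Sample indices are 0-based.
* A :class:`StepInterval` is half-open ``[start, end)`` on the sample axis.
* Seconds and samples convert via ``round(seconds * sample_rate_hz)``.

Annotation files are rate independent (they store seconds); the sampling
rate is supplied when reading so intervals can be placed on the sample
axis of the recording they belong to.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The channel names a motion-tracker export may contain, in canonical order.
KNOWN_CHANNELS: tuple[str, ...] = (
    "Acc_X", "Acc_Y", "Acc_Z",
    "FreeAcc_X", "FreeAcc_Y", "FreeAcc_Z",
    "Gyr_X", "Gyr_Y", "Gyr_Z",
    "Mag_X", "Mag_Y", "Mag_Z",
    "Roll", "Pitch", "Yaw",
    "Quat_W", "Quat_X", "Quat_Y", "Quat_Z",
)

QUATERNION_CHANNELS: tuple[str, ...] = ("Quat_W", "Quat_X", "Quat_Y", "Quat_Z")

DEFAULT_SAMPLE_RATE_HZ = 100.0

#: tolerance on the unit-quaternion norm check
_QUAT_NORM_TOL = 1e-3


class FormatError(ValueError):
    """Structurally malformed file (missing header, ragged rows, ...)."""


class ParseError(ValueError):
    """A cell could not be parsed; carries the offending location."""

    def __init__(self, row: int, column: str, value: str):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(
            f"non-numeric value {value!r} at data row {row}, column {column!r}"
        )


def seconds_to_sample(seconds: float, sample_rate_hz: float) -> int:
    """Convert a time in seconds to the nearest sample index."""
    return int(round(seconds * sample_rate_hz))


@dataclass(frozen=True, order=True)
class StepInterval:
    """One step as a half-open ``[start, end)`` span of sample indices."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def start_s(self, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> float:
        return self.start / sample_rate_hz

    def end_s(self, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> float:
        return self.end / sample_rate_hz

    def duration_s(self, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ) -> float:
        return self.n_samples / sample_rate_hz

    def contains(self, t: int) -> bool:
        return self.start <= t < self.end


@dataclass
class ImuRecording:
    """Fixed-rate multichannel time series for one animal-leg profile.

    ``channels`` maps channel name to a 1-D float array; all arrays must
    share the same length.  Units follow the sensor documentation:
    acceleration in m/s^2, angular velocity in rad/s, Euler angles in
    degrees, quaternion components unitless.  Channel families may be
    absent (e.g. no magnetometer); each detector declares what it needs.
    """

    profile_id: str
    leg_id: str
    channels: dict[str, np.ndarray]
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.channels:
            raise ValueError("recording must contain at least one channel")
        self.channels = {
            name: np.asarray(series, dtype=float)
            for name, series in self.channels.items()
        }
        lengths = {name: len(s) for name, s in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        if self.n_samples < 1:
            raise ValueError("recording must contain at least one sample")
        if all(q in self.channels for q in QUATERNION_CHANNELS):
            norm = np.sqrt(
                sum(self.channels[q] ** 2 for q in QUATERNION_CHANNELS)
            )
            worst = float(np.max(np.abs(norm - 1.0)))
            if worst > _QUAT_NORM_TOL:
                raise ValueError(
                    f"quaternion norm deviates from 1 by {worst:.2e} "
                    f"(tolerance {_QUAT_NORM_TOL})"
                )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def key(self) -> tuple[str, str]:
        return (self.profile_id, self.leg_id)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present in recording "
                f"{self.profile_id}/leg {self.leg_id}"
            ) from None

    def require_channels(self, names) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ValueError(
                f"recording {self.profile_id}/leg {self.leg_id} is missing "
                f"required channel(s): {missing}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.channels)


@dataclass
class AnnotationSet:
    """Sorted, non-overlapping step intervals for one profile-leg."""

    profile_id: str
    leg_id: str
    intervals: list[StepInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals in {self.profile_id}/leg "
                    f"{self.leg_id}: [{a.start},{a.end}) and [{b.start},{b.end})"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def key(self) -> tuple[str, str]:
        return (self.profile_id, self.leg_id)

    def validate_against(
        self, rec: ImuRecording, min_peak_magnitude: float = 20.0
    ) -> None:
        """Check the annotation convention against its recording.

        Every annotated step must lie inside the recording and contain an
        acceleration-magnitude peak of at least ``min_peak_magnitude``
        (movements below that are, by convention, not annotated).
        """
        from .signal_prep import acceleration_magnitude

        mag = acceleration_magnitude(
            rec.channel("Acc_X"), rec.channel("Acc_Y"), rec.channel("Acc_Z")
        )
        for iv in self.intervals:
            if iv.end > rec.n_samples:
                raise ValueError(
                    f"interval [{iv.start},{iv.end}) exceeds recording "
                    f"length {rec.n_samples}"
                )
            peak = float(np.max(mag[iv.start : iv.end]))
            if peak < min_peak_magnitude:
                raise ValueError(
                    f"annotated step [{iv.start},{iv.end}) peaks at "
                    f"{peak:.2f} m/s^2 < {min_peak_magnitude} m/s^2"
                )


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_recording(
    path,
    *,
    sep: str = ",",
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    profile_id: str | None = None,
    leg_id: str | None = None,
) -> ImuRecording:
    """Read a delimited-text recording (header row + one row per sample).

    Unrecognised columns are preserved under their header names.  If
    ``profile_id``/``leg_id`` are not given they are recovered from a
    file name of the form ``<profile>_leg<leg>.csv``; otherwise the file
    stem becomes the profile id and the leg id defaults to ``"1"``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    header_line = text.splitlines()[0]
    header = [tok.strip() for tok in header_line.split(sep)]
    if any(_looks_numeric(tok) for tok in header):
        raise FormatError(
            f"{path}: first row looks like data, not a header "
            f"(numeric token in {header})"
        )
    for line_no, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        n_fields = len(line.split(sep))
        if n_fields != len(header):
            raise FormatError(
                f"{path}: ragged row at line {line_no + 1} "
                f"({n_fields} fields, header has {len(header)})"
            )
    try:
        frame = pd.read_csv(
            io.StringIO(text), sep=sep, engine="python", dtype=str,
            skipinitialspace=True, keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    if frame.shape[0] == 0:
        raise FormatError(f"{path}: header but no data rows")

    channels: dict[str, np.ndarray] = {}
    for col in frame.columns:
        raw = frame[col]
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.isna() & ~raw.str.strip().str.lower().isin(["nan", ""])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
            raise ParseError(row, str(col), str(raw.iloc[row - 1]))
        if col != "time_s":
            channels[str(col)] = values.to_numpy(dtype=float)

    if profile_id is None or leg_id is None:
        stem = os.path.splitext(os.path.basename(os.fspath(path)))[0]
        if "_leg" in stem:
            inferred_profile, _, inferred_leg = stem.rpartition("_leg")
        else:
            inferred_profile, inferred_leg = stem, "1"
        profile_id = profile_id if profile_id is not None else inferred_profile
        leg_id = leg_id if leg_id is not None else inferred_leg

    return ImuRecording(
        profile_id=profile_id,
        leg_id=leg_id,
        channels=channels,
        sample_rate_hz=sample_rate_hz,
    )


def write_recording(rec: ImuRecording, path, *, sep: str = ",") -> None:
    """Write a recording as delimited text, readable by :func:`read_recording`.

    Values are written with 10 significant digits so a round trip
    preserves them to at least 9 significant digits.
    """
    frame = rec.to_frame()
    frame.to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ["profile_id", "leg_id", "start_s", "end_s"]


def _annotation_frame_to_sets(
    frame: pd.DataFrame, sample_rate_hz: float
) -> list[AnnotationSet]:
    for col in _ANNOTATION_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"annotation table is missing column {col!r}")
    sets: list[AnnotationSet] = []
    for (pid, leg), group in frame.groupby(
        ["profile_id", "leg_id"], sort=True
    ):
        intervals = []
        for _, row in group.iterrows():
            start_s, end_s = float(row["start_s"]), float(row["end_s"])
            if end_s <= start_s:
                raise ValueError(
                    f"annotation for {pid}/leg {leg}: end_s {end_s} <= "
                    f"start_s {start_s}"
                )
            intervals.append(
                StepInterval(
                    seconds_to_sample(start_s, sample_rate_hz),
                    seconds_to_sample(end_s, sample_rate_hz),
                )
            )
        # AnnotationSet enforces sortedness and non-overlap
        sets.append(AnnotationSet(str(pid), str(leg), intervals))
    return sets


def read_annotations(
    path, *, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ, sep: str = ","
) -> list[AnnotationSet]:
    """Read a step-annotation table, one :class:`AnnotationSet` per profile-leg."""
    frame = pd.read_csv(path, sep=sep, dtype={"profile_id": str, "leg_id": str})
    return _annotation_frame_to_sets(frame, sample_rate_hz)


def annotations_to_frame(
    sets, *, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    method: str | None = None,
) -> pd.DataFrame:
    rows = []
    for aset in sets:
        for iv in aset.intervals:
            row = {
                "profile_id": aset.profile_id,
                "leg_id": aset.leg_id,
                "start_s": iv.start_s(sample_rate_hz),
                "end_s": iv.end_s(sample_rate_hz),
            }
            if method is not None:
                row["method"] = method
            rows.append(row)
    columns = _ANNOTATION_COLUMNS + (["method"] if method is not None else [])
    return pd.DataFrame(rows, columns=columns)


def write_annotations(
    sets, path, *, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    sep: str = ",", method: str | None = None,
) -> None:
    """Write annotation sets (optionally tagged with a detection method)."""
    frame = annotations_to_frame(
        sets, sample_rate_hz=sample_rate_hz, method=method
    )
    frame["start_s"] = frame["start_s"].map(lambda v: f"{v:.3f}")
    frame["end_s"] = frame["end_s"].map(lambda v: f"{v:.3f}")
    frame.to_csv(path, sep=sep, index=False)


def read_detections(
    path, *, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ, sep: str = ","
) -> dict[str, list[AnnotationSet]]:
    """Read a detections table (annotation schema + ``method`` column).

    Returns a mapping from method name to annotation sets.  A file
    without a ``method`` column is treated as a single unnamed method.
    """
    frame = pd.read_csv(path, sep=sep, dtype={"profile_id": str, "leg_id": str})
    if "method" not in frame.columns:
        return {"": _annotation_frame_to_sets(frame, sample_rate_hz)}
    return {
        str(method): _annotation_frame_to_sets(group, sample_rate_hz)
        for method, group in frame.groupby("method", sort=True)
    }
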