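"""Core waveform containers, validation, resampling and plain-text I/O.

The whole package works on two representations of a pulse signal:

* :class:`PulseRecord` — a raw, uniformly sampled multi-period pressure
  record straight off an acquisition system (nominally 150 Hz);
* :class:`PulsePeriod` — a single cardiac period normalized to exactly
  150 samples, the unit that the elastic distances and classifiers consume.

Time stamps default to 1-based sample indices, which makes the time-stamp
penalty of the elastic distances count "per sample".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Canonical order of the five pulse-pattern categories.  This order is
#: used everywhere a fixed class order matters (confusion matrices,
#: deterministic tie-breaking).
CLASS_ORDER: tuple[str, ...] = ("moderate", "slippery", "taut", "hollow", "unsmooth")

#: Number of samples in a normalized single-period waveform.
PERIOD_LENGTH: int = 150

#: Nominal sampling rate of raw records, in Hz.
DEFAULT_SAMPLING_RATE: float = 150.0


class ValidationError(ValueError):
    """Raised when a waveform container violates its invariants."""


class ParseError(ValueError):
    """Raised on malformed waveform CSV input; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _as_float_array(x: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class TimeSeries:
    """A finite real-valued series with strictly increasing time stamps."""

    values: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        values = _as_float_array(self.values, "values")
        timestamps = _as_float_array(self.timestamps, "timestamps")
        if len(values) == 0:
            raise ValidationError("empty series: values must contain at least one sample")
        if len(values) != len(timestamps):
            raise ValidationError(
                f"length mismatch: {len(values)} values vs {len(timestamps)} timestamps"
            )
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise ValidationError(f"non-finite value at index {bad[0]}")
        bad = np.flatnonzero(~np.isfinite(timestamps))
        if bad.size:
            raise ValidationError(f"non-finite timestamp at index {bad[0]}")
        if len(timestamps) > 1:
            nondec = np.flatnonzero(np.diff(timestamps) <= 0)
            if nondec.size:
                raise ValidationError(f"non-increasing at index {nondec[0] + 1}")
        values.setflags(write=False)
        timestamps.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "timestamps", timestamps)

    def __len__(self) -> int:
        return len(self.values)


def make_timeseries(
    values: Sequence[float] | np.ndarray,
    timestamps: Sequence[float] | np.ndarray | None = None,
) -> TimeSeries:
    """Build a validated :class:`TimeSeries`.

    When ``timestamps`` is omitted, 1-based integer sample indices
    ``1..n`` are assigned.
    """
    values = _as_float_array(values, "values")
    if timestamps is None:
        timestamps = np.arange(1, len(values) + 1, dtype=float)
    return TimeSeries(values=values, timestamps=np.asarray(timestamps, dtype=float))


def resample_linear(series: TimeSeries, target_length: int) -> TimeSeries:
    """Piecewise-linear resampling to ``target_length`` uniformly spaced points.

    The query grid spans the input time range exactly, so the first and
    last output values equal the input endpoints.
    """
    if target_length < 2:
        raise ValidationError(f"target_length must be >= 2, got {target_length}")
    if len(series) < 2:
        raise ValidationError("cannot interpolate a singleton series")
    t = series.timestamps
    query = np.linspace(t[0], t[-1], target_length)
    out = np.interp(query, t, series.values)
    out[0] = series.values[0]
    out[-1] = series.values[-1]
    return TimeSeries(values=out, timestamps=query)


@dataclass(frozen=True)
class PulseRecord:
    """A raw uniformly sampled pressure record."""

    series: TimeSeries
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.sampling_rate > 0):
            raise ValidationError(f"sampling_rate must be positive, got {self.sampling_rate}")
        t = self.series.timestamps
        if len(t) > 1:
            dt = np.diff(t)
            expected = 1.0 / self.sampling_rate
            if not np.allclose(dt, expected, rtol=1e-9, atol=0.0):
                raise ValidationError(
                    "timestamps are not uniform at the declared sampling rate "
                    f"({self.sampling_rate} Hz)"
                )

    def __len__(self) -> int:
        return len(self.series)


def make_record(
    values: Sequence[float] | np.ndarray,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    subject_id: str | None = None,
) -> PulseRecord:
    """Build a record from raw samples, assigning uniform timestamps ``k/fs``."""
    values = _as_float_array(values, "values")
    t = np.arange(len(values), dtype=float) / sampling_rate
    return PulseRecord(
        series=TimeSeries(values=values, timestamps=t),
        sampling_rate=sampling_rate,
        subject_id=subject_id,
    )


@dataclass(frozen=True)
class PulseLabel:
    """One of the five pulse-pattern categories."""

    category: str

    def __post_init__(self) -> None:
        if self.category not in CLASS_ORDER:
            raise ValidationError(
                f"unknown label {self.category!r}; valid labels are {', '.join(CLASS_ORDER)}"
            )

    def __str__(self) -> str:
        return self.category


@dataclass(frozen=True)
class PulsePeriod:
    """A single-period waveform normalized to exactly 150 samples.

    Implied timestamps are the integers ``1..150``.
    """

    values: np.ndarray
    label: PulseLabel | None = None

    def __post_init__(self) -> None:
        values = _as_float_array(self.values, "values")
        if len(values) != PERIOD_LENGTH:
            raise ValidationError(f"expected {PERIOD_LENGTH} samples, got {len(values)}")
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise ValidationError(f"non-finite value at index {bad[0]}")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def to_timeseries(self) -> TimeSeries:
        return make_timeseries(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class LabeledDataset:
    """Parallel sequences of normalized periods and their labels."""

    periods: list[PulsePeriod]
    labels: list[PulseLabel]

    def __post_init__(self) -> None:
        if len(self.periods) != len(self.labels):
            raise ValidationError(
                f"{len(self.periods)} periods but {len(self.labels)} labels"
            )
        for lab in self.labels:
            if not isinstance(lab, PulseLabel):
                raise ValidationError(f"labels must be PulseLabel, got {type(lab).__name__}")

    def __len__(self) -> int:
        return len(self.periods)

    @property
    def values(self) -> np.ndarray:
        """Stacked sample matrix of shape ``(n, 150)``."""
        return np.stack([p.values for p in self.periods])

    @property
    def label_strings(self) -> list[str]:
        return [lab.category for lab in self.labels]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_ORDER}
        for lab in self.labels:
            counts[lab.category] += 1
        return counts

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            periods=[self.periods[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# Plain-text I/O.  Floats are written with repr(), which round-trips
# exactly, so write -> read -> write is byte-identical.
# ---------------------------------------------------------------------------


def write_record_csv(record: PulseRecord, path: str | Path) -> None:
    """Write a record as ``time,value`` rows with a ``# fs=`` header comment."""
    lines = [f"# fs={float(record.sampling_rate)!r}", "time,value"]
    for t, v in zip(record.series.timestamps, record.series.values):
        lines.append(f"{float(t)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_record_csv(path: str | Path) -> PulseRecord:
    fs: float | None = None
    times: list[float] = []
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("fs="):
                    try:
                        fs = float(body[3:])
                    except ValueError:
                        raise ParseError(f"bad sampling rate {body[3:]!r}", lineno)
                continue
            if line == "time,value":
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"expected 2 columns, got {len(parts)}", lineno)
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(str(exc), lineno)
    if fs is None:
        raise ParseError("missing '# fs=' sampling-rate comment")
    if not values:
        raise ParseError("no samples found")
    return PulseRecord(
        series=TimeSeries(values=np.array(values), timestamps=np.array(times)),
        sampling_rate=fs,
    )


def write_dataset_csv(dataset: LabeledDataset, path: str | Path) -> None:
    """Write one period per row: 150 comma-separated values + label column."""
    lines = []
    for period, label in zip(dataset.periods, dataset.labels):
        lines.append(
            ",".join(repr(float(v)) for v in period.values) + f",{label.category}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_dataset_csv(path: str | Path) -> LabeledDataset:
    periods: list[PulsePeriod] = []
    labels: list[PulseLabel] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != PERIOD_LENGTH + 1:
                raise ParseError(
                    f"expected {PERIOD_LENGTH} samples + label, got {len(parts)} columns",
                    lineno,
                )
            label_str = parts[-1].strip()
            if label_str not in CLASS_ORDER:
                raise ParseError(
                    f"unknown label {label_str!r}; valid labels are {', '.join(CLASS_ORDER)}",
                    lineno,
                )
            try:
                vals = np.array([float(p) for p in parts[:-1]])
            except ValueError as exc:
                raise ParseError(str(exc), lineno)
            label = PulseLabel(label_str)
            periods.append(PulsePeriod(values=vals, label=label))
            labels.append(label)
    if not periods:
        raise ParseError("no periods found")
    return LabeledDataset(periods=periods, labels=labels)


def read_waveform_csv(path: str | Path):
    """Read either a Record CSV or a Period CSV, detected from the header."""
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#") or line == "time,value":
                return read_record_csv(path)
            return read_dataset_csv(path)
    raise ParseError("empty file")


def write_waveform_csv(obj: PulseRecord | LabeledDataset, path: str | Path) -> None:
    if isinstance(obj, PulseRecord):
        write_record_csv(obj, path)
    elif isinstance(obj, LabeledDataset):
        write_dataset_csv(obj, path)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
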