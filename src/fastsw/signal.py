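"""In-memory containers for orientation signals and their approximations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TimestampOrderError

__all__ = ["Signal", "SegmentSeries"]


def _validate_stream(timestamps: np.ndarray, values: np.ndarray) -> None:
    if timestamps.ndim != 1:
        raise ValueError("timestamps must be one-dimensional")
    if values.ndim != 2:
        raise ValueError("values must be two-dimensional (m, D)")
    if len(timestamps) != len(values):
        raise ValueError(
            f"length mismatch: {len(timestamps)} timestamps vs {len(values)} value rows"
        )
    if not (np.all(np.isfinite(timestamps)) and np.all(np.isfinite(values))):
        raise ValueError("timestamps and values must be finite")
    if len(timestamps) > 1:
        diffs = np.diff(timestamps)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise TimestampOrderError(
                f"timestamps must be strictly increasing (violated at row {row})"
            )


@dataclass(frozen=True)
class Signal:
    """An ordered multi-channel time series.

    ``timestamps`` holds seconds, shape (m,), strictly increasing;
    ``values`` holds amplitudes, shape (m, D).  Orientation streams use
    D = 4 with scalar-first unit-quaternion rows (w, x, y, z).
    """

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _validate_stream(self.timestamps, self.values)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def ndim_values(self) -> int:
        """Number of signal channels D."""
        return self.values.shape[1]

    @property
    def is_quaternion(self) -> bool:
        return self.values.shape[1] == 4

    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=1)


@dataclass(frozen=True)
class SegmentSeries:
    """A piecewise linear approximation: the ordered segment points.

    Segment points are a subset of the original samples — the defining
    property of sliding-window segmentation that keeps quaternion points on
    the unit sphere.  ``source_length`` records m, the length of the signal
    the series approximates, so the inverse compression ratio is
    ``len(series) / source_length``.
    """

    timestamps: np.ndarray
    values: np.ndarray
    source_length: int
    ssr_trace: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.timestamps):
            _validate_stream(self.timestamps, self.values)
        if self.source_length < 0:
            raise ValueError("source_length must be non-negative")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def icr(self) -> float:
        """Inverse compression ratio m~/m of this approximation."""
        if self.source_length == 0:
            raise ValueError("undefined ICR: empty source signal")
        return len(self) / self.source_length
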