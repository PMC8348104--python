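"""Approximation quality measures and the threshold-sweep protocol.

The two quality axes of a piecewise linear approximation of an orientation
stream are:

* the **inverse compression ratio** ICR = m~/m — segment points kept over
  original samples (lower = more compression); and
* the **average angular deviation** AAD — the mean, over all original
  timestamps, of the rotation angle between each original quaternion and the
  approximation SLERP-interpolated at that timestamp (reported in degrees,
  together with the standard deviation and maximum of the same per-sample
  deviations).

A third measure targets the segment points themselves: the angular deviation
of every emitted point against the original sample at the same timestamp.
For sample-subset methods (SW / fastSW) this is numerical noise, independent
of the compression level — the property that makes them fit for unit
quaternions, where extrapolated points would leave the unit sphere and
renormalisation would twist the orientation.

The sweep protocol approximates one signal at a grid of threshold values — a
leading 0 plus 204 points log-spaced over [1e-6, 1e3] (205 values spanning
nine orders of magnitude) — and emits one report row per threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ExtrapolationError
from .quaternion import angular_deviation, slerp_pairs
from .segmenter import DEFAULT_MAX_SEGMENT_LENGTH, segment_signal
from .signal import SegmentSeries, Signal
from .sliding_window import sw_segment_signal

__all__ = [
    "icr",
    "reconstruct",
    "DeviationStats",
    "aad",
    "segment_point_deviation",
    "default_threshold_grid",
    "ApproximationReport",
    "threshold_sweep",
    "reports_to_frame",
    "write_reports",
]


def icr(m_tilde: int, m: int) -> float:
    """Inverse compression ratio m~/m."""
    if m <= 0:
        raise ValueError("original signal length m must be positive")
    if not 1 <= m_tilde <= m:
        raise ValueError("segment point count must satisfy 1 <= m~ <= m")
    return m_tilde / m


def reconstruct(series: SegmentSeries, timestamps: Sequence[float]) -> Signal:
    """SLERP the segment-point series at the given timestamps.

    Each query timestamp is bracketed by its two neighbouring segment points
    and interpolated along the geodesic at the proportional time fraction.
    Queries hitting a segment-point timestamp return that point exactly
    (bitwise), so a lossless run reproduces the original stream verbatim.
    Timestamps outside the covered range raise :class:`ExtrapolationError`.
    """
    if len(series) < 1:
        raise ValueError("cannot reconstruct from an empty segment series")
    ts = np.asarray(timestamps, dtype=float)
    pt_t = series.timestamps
    pt_v = series.values
    if np.any(ts < pt_t[0]) or np.any(ts > pt_t[-1]):
        raise ExtrapolationError(
            f"timestamps outside the covered range [{pt_t[0]}, {pt_t[-1]}]"
        )
    if len(series) == 1:
        return Signal(ts, np.repeat(pt_v, len(ts), axis=0))

    hi = np.clip(np.searchsorted(pt_t, ts, side="right"), 1, len(pt_t) - 1)
    lo = hi - 1
    u = (ts - pt_t[lo]) / (pt_t[hi] - pt_t[lo])
    out = slerp_pairs(pt_v[lo], pt_v[hi], u)

    # exact hits return the stored point bitwise, not its interpolation
    exact_lo = ts == pt_t[lo]
    exact_hi = ts == pt_t[hi]
    out[exact_lo] = pt_v[lo[exact_lo]]
    out[exact_hi] = pt_v[hi[exact_hi]]
    return Signal(ts, out)


@dataclass(frozen=True)
class DeviationStats:
    """Mean / standard deviation / maximum of per-sample angular deviations (degrees)."""

    mean: float
    sd: float
    max: float


def aad(original: Signal, reconstructed: Signal) -> DeviationStats:
    """Average angular deviation between two aligned quaternion streams.

    Streams must share length and timestamps; the mean is the AAD, and the
    standard deviation and maximum of the same per-sample deviations are
    carried along for reporting.
    """
    if len(original) != len(reconstructed):
        raise ValueError("signals differ in length")
    if not np.array_equal(original.timestamps, reconstructed.timestamps):
        raise ValueError("signals differ in timestamps")
    devs = angular_deviation(original.values, reconstructed.values)
    devs = np.atleast_1d(devs)
    return DeviationStats(mean=float(devs.mean()), sd=float(devs.std()), max=float(devs.max()))


def segment_point_deviation(series: SegmentSeries, original: Signal) -> tuple[float, float]:
    """(max, mean) angular deviation of segment points vs the original samples.

    Every series timestamp must occur in the original signal.  For
    sample-subset segmenters the deviations are pure numerical noise; the
    measure exists to expose methods whose points leave the data.
    """
    idx = np.searchsorted(original.timestamps, series.timestamps)
    ok = (idx < len(original)) & np.isclose(
        original.timestamps[np.minimum(idx, len(original) - 1)], series.timestamps
    )
    if not np.all(ok):
        missing = series.timestamps[~ok]
        raise ValueError(f"segment-point timestamp not found in original signal: {missing[:3]}")
    devs = np.atleast_1d(angular_deviation(series.values, original.values[idx]))
    return float(devs.max()), float(devs.mean())


def default_threshold_grid(
    n: int = 205, low: float = 1e-6, high: float = 1e3
) -> np.ndarray:
    """Threshold grid for sweep evaluations: 0 followed by n-1 log-spaced values.

    Defaults give 205 thresholds — 0, then 204 points spread evenly in log
    space across the nine decades from 1e-6 to 1e3.
    """
    if n < 2:
        raise ValueError("need at least two grid points")
    return np.concatenate([[0.0], np.logspace(np.log10(low), np.log10(high), n - 1)])


@dataclass(frozen=True)
class ApproximationReport:
    """Quality summary for one (signal, threshold) segmentation run."""

    threshold: float
    m: int
    m_tilde: int
    icr: float
    aad: float
    sd_ad: float
    max_ad: float
    seg_point_max_ad: float
    seg_point_mean_ad: float


_ALGORITHMS: dict[str, Callable] = {
    "fastsw": segment_signal,
    "sw": sw_segment_signal,
}


def threshold_sweep(
    signal: Signal,
    thresholds: Iterable[float] | None = None,
    max_segment_length: int = DEFAULT_MAX_SEGMENT_LENGTH,
    algorithm: str | Callable = "fastsw",
    align_quaternion_signs: bool | None = None,
) -> list[ApproximationReport]:
    """Segment ``signal`` at every threshold and report quality per run.

    ``algorithm`` is ``"fastsw"``, ``"sw"``, or any callable with the
    ``segment_signal`` signature.  ``thresholds`` defaults to the 205-value
    grid of :func:`default_threshold_grid`.  Requires a unit-quaternion
    signal (D = 4), since the deviations are angular.
    """
    if signal.values.shape[1] != 4:
        raise ValueError("threshold_sweep expects a quaternion signal (D = 4)")
    if thresholds is None:
        thresholds = default_threshold_grid()
    segment = _ALGORITHMS[algorithm] if isinstance(algorithm, str) else algorithm

    reports = []
    for th in thresholds:
        th = float(th)
        if th < 0:
            raise ValueError("thresholds must be non-negative")
        series = segment(
            signal,
            th,
            max_segment_length=max_segment_length,
            align_quaternion_signs=align_quaternion_signs,
        )
        recon = reconstruct(series, signal.timestamps)
        stats = aad(signal, recon)
        sp_max, sp_mean = segment_point_deviation(series, signal)
        reports.append(
            ApproximationReport(
                threshold=th,
                m=len(signal),
                m_tilde=len(series),
                icr=series.icr,
                aad=stats.mean,
                sd_ad=stats.sd,
                max_ad=stats.max,
                seg_point_max_ad=sp_max,
                seg_point_mean_ad=sp_mean,
            )
        )
    return reports


def reports_to_frame(reports: Sequence[ApproximationReport]) -> pd.DataFrame:
    """Tabulate sweep reports, one row per threshold."""
    return pd.DataFrame([asdict(r) for r in reports])


def write_reports(path, reports: Sequence[ApproximationReport]) -> None:
    """Serialize sweep reports as comma-delimited text."""
    reports_to_frame(reports).to_csv(path, index=False, float_format="%.17g")
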