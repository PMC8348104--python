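"""fastSW: streaming sliding-window segmentation in constant time per sample.

The classic sliding-window (SW) segmenter grows a segment from the last
segment point, and for each new sample fits the line through the segment
origin and that sample (slope ``beta_d = y_dn / t_n`` per channel, in
origin-relative coordinates) and evaluates the segment's sum of squared
residuals (SSR).  When the SSR exceeds a user threshold, the previous sample
is frozen as the next segment point and the segment restarts there.  Because
segment points are always original samples, unit quaternions stay unit — but
SW must buffer the whole open segment and rescan it per sample, an O(n) cost.

fastSW produces the same boundaries without the buffer.  Expanding the SSR

    SSR_n = sum_d sum_j (y_dj - beta_d t_j)^2
          = sum_d [ sum_j y_dj^2 - 2 beta_d sum_j t_j y_dj + beta_d^2 sum_j t_j^2 ]

shows the per-channel sums over the open segment suffice.  To keep the state
well-scaled the sums are carried as running means (of t^2, t*y_d and y_d^2),
each updated as ``mean += (x - mean)/n``, and the SSR is recomposed per sample
as

    SSR_n = sum_d ( mean_y2_d - 2 beta_d mean_ty_d + beta_d^2 mean_t2 ) * (n-1)

using the means over the previous n-1 samples: the newest sample lies on the
trial line by construction and contributes no residual.  All of this is O(D)
per sample, independent of segment length.

The arithmetic below deliberately sticks to plain scalar operations on the
state so the identical code path can be cost-profiled with the instrumented
scalars of :mod:`fastsw.counting`.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import TimestampOrderError
from .quaternion import align_signs
from .signal import SegmentSeries, Signal

__all__ = ["FastSW", "segment_signal", "DEFAULT_MAX_SEGMENT_LENGTH"]

#: Maximum number of samples a segment may cover beyond its shared start
#: point.  Bounds the worst-case gap between consecutive segment points (and
#: hence the reconstruction latency); the achievable inverse compression
#: ratio is floored at 1/cap.
DEFAULT_MAX_SEGMENT_LENGTH = 1000


def _check_sample(t, values) -> None:
    if not math.isfinite(float(t)):
        raise ValueError("sample timestamp must be finite")
    for v in values:
        if not math.isfinite(float(v)):
            raise ValueError("sample values must be finite")


class FastSW:
    """Streaming segmenter state over a D-dimensional sample stream.

    Feed samples in timestamp order through :meth:`process`; it returns the
    newly frozen segment point when the current one closes, else ``None``.
    Call :meth:`finalize` after the last sample to close the open segment.
    The first sample (given to the constructor) is itself the first segment
    point and is *not* returned by :meth:`process`.
    """

    __slots__ = (
        "threshold",
        "cap",
        "ndim",
        "n",
        "origin_t",
        "origin_v",
        "pending",
        "prev_t",
        "mean_t2",
        "mean_ty",
        "mean_y2",
        "last_ssr",
    )

    def __init__(
        self,
        first_t: float,
        first_values: Sequence[float],
        threshold: float,
        max_segment_length: int = DEFAULT_MAX_SEGMENT_LENGTH,
    ) -> None:
        if threshold < 0:
            raise ValueError("threshold must be non-negative")
        if max_segment_length < 2:
            raise ValueError("max_segment_length must be at least 2")
        if len(first_values) < 1:
            raise ValueError("samples need at least one channel")
        _check_sample(first_t, first_values)
        self.threshold = threshold
        self.cap = int(max_segment_length)
        self.ndim = len(first_values)
        self.n = 0
        self.origin_t = first_t
        self.origin_v = tuple(first_values)
        self.pending = None  # newest accepted sample, candidate next point
        self.prev_t = first_t
        self.mean_t2 = 0.0
        self.mean_ty = [0.0] * self.ndim
        self.mean_y2 = [0.0] * self.ndim
        self.last_ssr = None  # SSR computed for the most recent sample

    # -- pieces exposed for inspection and testing --------------------------

    def slope(self, t, values):
        """Per-channel slope of the trial segment from the origin to (t, values)."""
        dt = t - self.origin_t
        if not dt > 0:
            raise TimestampOrderError("sample timestamp must exceed the segment origin's")
        ov = self.origin_v
        return [(values[d] - ov[d]) / dt for d in range(self.ndim)]

    def incremental_ssr(self, beta, n):
        """SSR of the open segment recomposed from the running means.

        ``n`` counts samples including the newest; only the previous ``n - 1``
        contribute residuals.  Returns 0 for n = 1.
        """
        prev = n - 1
        ssr = 0.0
        for d in range(self.ndim):
            bd = beta[d]
            ssr = ssr + (self.mean_y2[d] - 2.0 * bd * self.mean_ty[d] + bd * bd * self.mean_t2) * prev
        return ssr

    def update_means(self, tn, yn, n) -> None:
        """Fold the origin-relative sample (tn, yn) into the running means."""
        self.mean_t2 = self.mean_t2 + ((tn * tn) - self.mean_t2) / n
        for d in range(self.ndim):
            yd = yn[d]
            self.mean_ty[d] = self.mean_ty[d] + ((tn * yd) - self.mean_ty[d]) / n
            self.mean_y2[d] = self.mean_y2[d] + ((yd * yd) - self.mean_y2[d]) / n

    # -- the per-sample step -------------------------------------------------

    def process(self, t, values):
        """Advance the segmenter by one sample; return a frozen point or None.

        Constant cost per call: O(D) arithmetic regardless of how many
        samples the open segment already covers.
        """
        if not t > self.prev_t:
            raise TimestampOrderError(
                f"timestamps must be strictly increasing (got {t!r} after {self.prev_t!r})"
            )
        D = self.ndim
        if len(values) != D:
            raise ValueError(f"expected {D} channels, got {len(values)}")

        n = self.n + 1
        tn = t - self.origin_t
        ov = self.origin_v
        mean_ty = self.mean_ty
        mean_y2 = self.mean_y2
        mean_t2 = self.mean_t2
        prev = n - 1

        ssr = 0.0
        yn = [0.0] * D
        for d in range(D):
            yd = values[d] - ov[d]
            yn[d] = yd
            bd = yd / tn
            ssr = ssr + (mean_y2[d] - 2.0 * bd * mean_ty[d] + bd * bd * mean_t2) * prev
        self.last_ssr = ssr
        self.prev_t = t

        if ssr <= self.threshold and n <= self.cap:
            # sample accepted: fold into the means, keep it as the candidate point
            self.mean_t2 = mean_t2 + ((tn * tn) - mean_t2) / n
            for d in range(D):
                yd = yn[d]
                mean_ty[d] = mean_ty[d] + ((tn * yd) - mean_ty[d]) / n
                mean_y2[d] = mean_y2[d] + ((yd * yd) - mean_y2[d]) / n
            self.n = n
            self.pending = (t, tuple(values))
            return None

        # segment closes: the previously accepted sample becomes the point,
        # and the current sample opens the next segment relative to it
        point = self.pending
        self.origin_t, self.origin_v = point
        ov = self.origin_v
        self.n = 1
        tn = t - self.origin_t
        self.mean_t2 = tn * tn
        for d in range(D):
            yd = values[d] - ov[d]
            mean_ty[d] = tn * yd
            mean_y2[d] = yd * yd
        self.pending = (t, tuple(values))
        return point

    def finalize(self):
        """Close the open segment: return the last accepted sample, or None.

        Ensures the segment-point series spans the full recording so every
        original timestamp can be reconstructed by interpolation.  Returns
        ``None`` when no sample was processed since construction.
        """
        point = self.pending
        self.pending = None
        return point


def segment_signal(
    signal: Signal,
    threshold: float,
    max_segment_length: int = DEFAULT_MAX_SEGMENT_LENGTH,
    align_quaternion_signs: bool | None = None,
    record_ssr: bool = False,
) -> SegmentSeries:
    """Segment a whole signal with fastSW.

    ``align_quaternion_signs`` defaults to on for 4-channel (quaternion)
    signals: the stream is first made sign-continuous (q and -q are the same
    rotation) so component-space residuals reflect actual motion.  With
    alignment active, emitted points are samples of the aligned stream, i.e.
    original samples up to a possible overall sign flip.

    When ``record_ssr`` is true, the per-sample SSR values are attached to the
    returned series as ``ssr_trace`` (length m - 1: one entry per processed
    sample after the first).
    """
    m = len(signal)
    if m < 2:
        raise ValueError("need at least two samples to segment")
    values = signal.values
    if align_quaternion_signs is None:
        align_quaternion_signs = signal.values.shape[1] == 4
    if align_quaternion_signs:
        values = align_signs(values)

    ts = signal.timestamps.tolist()
    rows = values.tolist()

    seg = FastSW(ts[0], rows[0], threshold, max_segment_length)
    pts_t = [ts[0]]
    pts_v = [rows[0]]
    trace = [] if record_ssr else None

    process = seg.process
    if record_ssr:
        for i in range(1, m):
            out = process(ts[i], rows[i])
            trace.append(seg.last_ssr)
            if out is not None:
                pts_t.append(out[0])
                pts_v.append(list(out[1]))
    else:
        for i in range(1, m):
            out = process(ts[i], rows[i])
            if out is not None:
                pts_t.append(out[0])
                pts_v.append(list(out[1]))

    tail = seg.finalize()
    if tail is not None:
        pts_t.append(tail[0])
        pts_v.append(list(tail[1]))

    return SegmentSeries(
        timestamps=np.array(pts_t, dtype=float),
        values=np.array(pts_v, dtype=float),
        source_length=m,
        ssr_trace=None if trace is None else np.array(trace, dtype=float),
    )
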