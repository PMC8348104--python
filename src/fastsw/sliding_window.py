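"""Buffered sliding-window segmentation: the brute-force baseline and oracle.

Classic SW keeps every sample of the open segment in a buffer and, for each
new sample, recomputes the segment SSR by iterating over the buffer:

    SSR_n = sum_{j=1..n} sum_d (y_dj - beta_d t_j)^2

with y_dj and t_j origin-relative.  The emission rule, maximum-segment-length
cap and sign-alignment convention are shared with :mod:`fastsw.segmenter`, so
the two produce directly comparable (and, up to floating-point ordering,
identical) boundary sequences while differing only in how the SSR is
obtained: here O(n) per sample, there O(1).

Two SSR evaluation paths are provided.  ``brute_force_ssr`` is the literal
scalar loop, which also runs under the instrumented scalars of
:mod:`fastsw.counting` to exhibit the affine per-sample cost.  The whole-
signal driver uses a vectorized evaluation of the same formula for speed;
a test pins the two paths to each other.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import TimestampOrderError
from .quaternion import align_signs
from .segmenter import DEFAULT_MAX_SEGMENT_LENGTH, _check_sample
from .signal import SegmentSeries, Signal

__all__ = ["brute_force_ssr", "SlidingWindow", "sw_segment_signal"]


def brute_force_ssr(origin, samples, beta):
    """Direct SSR of buffered samples against the line with slope ``beta``.

    ``origin`` is the segment origin (t0, values0); ``samples`` an iterable of
    (t, values) with timestamps above the origin's.  Works with any scalar
    type supporting +,-,*; returns 0 for an empty buffer.
    """
    t0, v0 = origin
    D = len(v0)
    ssr = 0.0
    for (t, v) in samples:
        tj = t - t0
        for d in range(D):
            r = (v[d] - v0[d]) - beta[d] * tj
            ssr = ssr + r * r
    return ssr


class SlidingWindow:
    """Buffered SW segmenter with the same streaming interface as FastSW.

    ``scalar=True`` switches the SSR evaluation to the literal python loop of
    :func:`brute_force_ssr`, accepting instrumented scalars for cost
    profiling; the default path keeps the buffer in preallocated numpy arrays.
    """

    def __init__(
        self,
        first_t: float,
        first_values: Sequence[float],
        threshold: float,
        max_segment_length: int = DEFAULT_MAX_SEGMENT_LENGTH,
        scalar: bool = False,
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
        self.scalar = scalar
        self.origin_t = first_t
        self.origin_v = tuple(first_values)
        self.prev_t = first_t
        self.n = 0
        self.last_ssr = None
        if scalar:
            self.buffer: list = []  # list of (t, values)
        else:
            self.buf_t = np.empty(self.cap + 1, dtype=float)
            self.buf_v = np.empty((self.cap + 1, self.ndim), dtype=float)

    def process(self, t, values):
        """Advance by one sample; return a frozen segment point or None.

        Cost per call grows with the open segment's length: the whole buffer
        is rescanned to evaluate the SSR.
        """
        if not t > self.prev_t:
            raise TimestampOrderError(
                f"timestamps must be strictly increasing (got {t!r} after {self.prev_t!r})"
            )
        if len(values) != self.ndim:
            raise ValueError(f"expected {self.ndim} channels, got {len(values)}")
        self.prev_t = t
        n = self.n + 1

        if self.scalar:
            tn = t - self.origin_t
            beta = [(values[d] - self.origin_v[d]) / tn for d in range(self.ndim)]
            ssr = brute_force_ssr(
                (self.origin_t, self.origin_v), self.buffer + [(t, values)], beta
            )
        else:
            self.buf_t[n - 1] = t
            self.buf_v[n - 1] = values
            tn = t - self.origin_t
            yn = self.buf_v[n - 1] - self.origin_v
            beta = yn / tn
            ts = self.buf_t[:n] - self.origin_t
            ys = self.buf_v[:n] - self.origin_v
            resid = ys - ts[:, None] * beta
            ssr = float(np.einsum("ij,ij->", resid, resid))
        self.last_ssr = ssr

        if ssr <= self.threshold and n <= self.cap:
            if self.scalar:
                self.buffer.append((t, tuple(values)))
            self.n = n
            return None

        # close the segment at the previously buffered sample
        if self.scalar:
            point_t, point_v = self.buffer[-1]
            self.buffer = [(t, tuple(values))]
        else:
            point_t = float(self.buf_t[n - 2])
            point_v = tuple(self.buf_v[n - 2])
            self.buf_t[0] = t
            self.buf_v[0] = values
        self.origin_t = point_t
        self.origin_v = point_v
        self.n = 1
        return (point_t, point_v)

    def finalize(self):
        """Return the last buffered sample as the terminal point, or None."""
        if self.scalar:
            if not self.buffer:
                return None
            t, v = self.buffer[-1]
            self.buffer = []
            return (t, v)
        if self.n == 0:
            return None
        t = float(self.buf_t[self.n - 1])
        v = tuple(self.buf_v[self.n - 1])
        self.n = 0
        return (t, v)


def sw_segment_signal(
    signal: Signal,
    threshold: float,
    max_segment_length: int = DEFAULT_MAX_SEGMENT_LENGTH,
    align_quaternion_signs: bool | None = None,
    record_ssr: bool = False,
) -> SegmentSeries:
    """Segment a whole signal with buffered SW; same contract as fastSW's driver."""
    m = len(signal)
    if m < 2:
        raise ValueError("need at least two samples to segment")
    values = signal.values
    if align_quaternion_signs is None:
        align_quaternion_signs = signal.values.shape[1] == 4
    if align_quaternion_signs:
        values = align_signs(values)

    ts = signal.timestamps
    seg = SlidingWindow(float(ts[0]), tuple(values[0]), threshold, max_segment_length)
    pts_t = [float(ts[0])]
    pts_v = [list(values[0])]
    trace = [] if record_ssr else None

    for i in range(1, m):
        out = seg.process(float(ts[i]), values[i])
        if record_ssr:
            trace.append(seg.last_ssr)
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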