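"""The streaming segmenter: state updates, the incremental SSR, and Algorithm-level behavior."""

import numpy as np
import pytest

from fastsw.counting import CountedFloat, OpCounter
from fastsw.errors import TimestampOrderError
from fastsw.segmenter import FastSW, segment_signal
from fastsw.signal import Signal
from fastsw.sliding_window import brute_force_ssr
from fastsw.synth import MotionSpec, generate_quaternion_motion


def make_seg(first=(0.0, (0.0,)), threshold=1.0, cap=1000):
    return FastSW(first[0], first[1], threshold, cap)


class TestConstruction:
    def test_initial_state_zeroed(self):
        seg = FastSW(2.5, (1.0, -1.0, 0.5, 0.0), threshold=0.1)
        assert seg.n == 0
        assert seg.mean_t2 == 0.0
        assert seg.mean_ty == [0.0] * 4
        assert seg.mean_y2 == [0.0] * 4
        assert seg.origin_t == 2.5

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            FastSW(0.0, (0.0,), threshold=-1e-9)

    def test_cap_below_two_rejected(self):
        with pytest.raises(ValueError):
            FastSW(0.0, (0.0,), threshold=0.0, max_segment_length=1)

    def test_nonfinite_first_sample_rejected(self):
        with pytest.raises(ValueError):
            FastSW(0.0, (np.inf,), threshold=0.0)


class TestSlope:
    def test_hand_example(self):
        seg = FastSW(0.0, (1.0,), threshold=1.0)
        assert seg.slope(2.0, (2.0,)) == [0.5]

    def test_zero_rise_gives_zero_vector(self):
        seg = FastSW(0.0, (1.0, 2.0, 3.0, 4.0), threshold=1.0)
        assert seg.slope(1.0, (1.0, 2.0, 3.0, 4.0)) == [0.0] * 4

    def test_duplicate_timestamp_rejected(self):
        seg = FastSW(1.0, (1.0,), threshold=1.0)
        with pytest.raises(TimestampOrderError):
            seg.slope(1.0, (2.0,))

    def test_shared_scalar_divisor_across_dimensions(self):
        seg = FastSW(0.0, (0.0, 0.0), threshold=1.0)
        assert seg.slope(4.0, (1.0, 3.0)) == [0.25, 0.75]


class TestIncrementalSSR:
    def test_no_previous_samples_gives_zero(self):
        seg = FastSW(0.0, (0.0,), threshold=1.0)
        assert seg.incremental_ssr([1.23], n=1) == 0.0

    def test_hand_computed_instance(self):
        # origin (0, 0); first sample (1, 1.0); trial sample (2, 1.5)
        seg = FastSW(0.0, (0.0,), threshold=np.inf)
        seg.process(1.0, (1.0,))
        beta = seg.slope(2.0, (1.5,))
        assert beta == [0.75]
        assert seg.incremental_ssr(beta, n=2) == pytest.approx(0.0625, rel=1e-12)

    @pytest.mark.parametrize("ndim", [1, 4])
    def test_matches_brute_force_on_random_segments(self, rng, ndim):
        for _ in range(30):
            n = int(rng.integers(2, 51))
            ts = np.cumsum(rng.uniform(0.01, 0.1, n))
            vals = rng.normal(size=(n, ndim))
            origin_v = tuple(rng.normal(size=ndim))
            seg = FastSW(0.0, origin_v, threshold=np.inf, max_segment_length=100)
            for j in range(n - 1):
                seg.process(float(ts[j]), tuple(vals[j]))
            beta = seg.slope(float(ts[-1]), tuple(vals[-1]))
            got = seg.incremental_ssr(beta, n=n)
            want = brute_force_ssr(
                (0.0, origin_v), list(zip(ts[:-1], vals[:-1])), beta
            )
            assert got == pytest.approx(float(want), rel=1e-9, abs=1e-12)


class TestUpdateMeans:
    def test_mean_of_one(self):
        seg = FastSW(0.0, (0.0,), threshold=1.0)
        seg.update_means(1.0, (2.0,), n=1)
        assert (seg.mean_t2, seg.mean_ty, seg.mean_y2) == (1.0, [2.0], [4.0])

    def test_running_means_equal_direct_sums(self, rng):
        n_total = 1000
        ts = np.cumsum(rng.uniform(0.01, 0.05, n_total))
        ys = rng.normal(size=(n_total, 4))
        seg = FastSW(0.0, (0.0,) * 4, threshold=1.0)
        for n in range(1, n_total + 1):
            seg.update_means(float(ts[n - 1]), tuple(ys[n - 1]), n)
        assert seg.mean_t2 * n_total == pytest.approx(np.sum(ts**2), rel=1e-9)
        for d in range(4):
            assert seg.mean_ty[d] * n_total == pytest.approx(
                np.sum(ts * ys[:, d]), rel=1e-9, abs=1e-9
            )
            assert seg.mean_y2[d] * n_total == pytest.approx(
                np.sum(ys[:, d] ** 2), rel=1e-9
            )


class TestProcess:
    def test_constant_signal_emits_nothing_before_cap(self):
        seg = FastSW(0.0, (3.3,), threshold=0.0, max_segment_length=1000)
        for i in range(1, 500):
            assert seg.process(float(i), (3.3,)) is None

    def test_collinear_ramp_emits_nothing(self):
        # the incremental SSR of exactly-collinear data is zero up to the
        # cancellation noise of the running means, which scales with the
        # squared data magnitude times the segment length (~1e-11 here)
        seg = FastSW(0.0, (0.0,), threshold=1e-8, max_segment_length=1000)
        for i in range(1, 200):
            assert seg.process(float(i), (0.7 * i,)) is None
            assert seg.last_ssr == pytest.approx(0.0, abs=1e-8)

    def test_hand_trace_step_signal(self):
        # values [0, 0, 1, 1] at t = 0..3, threshold 0.1:
        # SSR jumps to 0.25 at t=2 and again at t=3 -> points (1, 0), (2, 1)
        seg = FastSW(0.0, (0.0,), threshold=0.1)
        assert seg.process(1.0, (0.0,)) is None
        assert seg.process(2.0, (1.0,)) == (1.0, (0.0,))
        assert seg.process(3.0, (1.0,)) == (2.0, (1.0,))
        assert seg.finalize() == (3.0, (1.0,))

    def test_cap_forces_emission_of_previous_sample(self):
        seg = FastSW(0.0, (0.0,), threshold=np.inf, max_segment_length=10)
        out = [seg.process(float(i), (0.0,)) for i in range(1, 12)]
        assert out[:10] == [None] * 10
        assert out[10] == (10.0, (0.0,))  # emitted when n would reach cap+1

    def test_timestamp_order_enforced(self):
        seg = FastSW(0.0, (0.0,), threshold=1.0)
        seg.process(1.0, (0.0,))
        with pytest.raises(TimestampOrderError):
            seg.process(1.0, (0.0,))
        with pytest.raises(TimestampOrderError):
            seg.process(0.5, (0.0,))

    def test_dimension_mismatch_rejected(self):
        seg = FastSW(0.0, (0.0, 0.0), threshold=1.0)
        with pytest.raises(ValueError):
            seg.process(1.0, (0.0,))

    def test_finalize_without_samples_returns_none(self):
        seg = FastSW(0.0, (0.0,), threshold=1.0)
        assert seg.finalize() is None


class TestSegmentSignal:
    def test_single_segment_gives_first_and_last(self):
        sig = Signal(np.arange(10.0), np.linspace(0, 1, 10)[:, None])
        series = segment_signal(sig, threshold=np.inf)
        assert len(series) == 2
        assert series.timestamps[0] == 0.0 and series.timestamps[-1] == 9.0

    def test_zero_threshold_on_noisy_data_keeps_every_sample(self, rng):
        m = 200
        sig = Signal(np.arange(float(m)), rng.normal(size=(m, 1)))
        series = segment_signal(sig, threshold=0.0)
        assert len(series) == m
        assert series.icr == 1.0
        assert np.array_equal(series.values, sig.values)

    def test_points_are_exactly_input_samples(self, motion_signal):
        for th in (1e-5, 1e-3, 1e-1):
            series = segment_signal(motion_signal, th)
            idx = np.searchsorted(motion_signal.timestamps, series.timestamps)
            assert np.array_equal(series.timestamps, motion_signal.timestamps[idx])
            assert np.array_equal(series.values, motion_signal.values[idx])

    def test_unit_norm_preserved_exactly(self, motion_signal):
        series = segment_signal(motion_signal, 1e-3)
        idx = np.searchsorted(motion_signal.timestamps, series.timestamps)
        assert np.array_equal(
            np.linalg.norm(series.values, axis=1),
            np.linalg.norm(motion_signal.values[idx], axis=1),
        )

    def test_cap_bounds_inter_point_spacing(self, suite):
        sig = suite["constant"]
        series = segment_signal(sig, threshold=np.inf, max_segment_length=100)
        idx = np.searchsorted(sig.timestamps, series.timestamps)
        assert np.max(np.diff(idx)) <= 100

    def test_point_count_nearly_monotone_in_threshold(self, suite):
        thresholds = np.concatenate([[0.0], np.logspace(-6, 3, 30)])
        for name in ("piecewise_1d", "slow_motion", "mixed"):
            counts = [len(segment_signal(suite[name], float(t))) for t in thresholds]
            running_min = counts[0]
            for c in counts[1:]:
                assert c <= running_min + 1
                running_min = min(running_min, c)

    def test_sign_alignment_default_for_quaternions(self, suite):
        sig = suite["sign_flip"]
        aligned = segment_signal(sig, 1e-2)  # default: alignment on for D=4
        raw = segment_signal(sig, 1e-2, align_quaternion_signs=False)
        # artificial hemisphere flips force extra breakpoints when not aligned
        assert len(raw) > len(aligned)
        # aligned points still match original samples up to overall sign
        idx = np.searchsorted(sig.timestamps, aligned.timestamps)
        assert np.array_equal(np.abs(aligned.values), np.abs(sig.values[idx]))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            segment_signal(Signal(np.array([0.0]), np.zeros((1, 1))), 1.0)


def counted_stream(n, cap, slope=0.5):
    """Run a collinear CountedFloat stream; return ops spent on each process call."""
    c = OpCounter()
    seg = FastSW(
        CountedFloat(0.0, c), tuple(CountedFloat(0.0, c) for _ in range(4)),
        threshold=1e18, max_segment_length=cap,
    )
    deltas = []
    for i in range(1, n + 1):
        before = c.total
        seg.process(CountedFloat(float(i), c), tuple(CountedFloat(slope * i, c) for _ in range(4)))
        deltas.append(c.total - before)
    return deltas


class TestConstantCost:
    def test_process_cost_independent_of_segment_length(self):
        deltas = counted_stream(1000, cap=2000)
        assert deltas[1] == deltas[999]
        assert len(set(deltas)) == 1  # every accepted sample costs the same
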