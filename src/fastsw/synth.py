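"""Seeded synthetic signal generators.

Two families of test inputs:

* exact piecewise-linear D-dimensional signals with known corner points, for
  recovery and equivalence testing of the segmenters; and
* unit-quaternion motion streams emulating wearable orientation-sensor
  recordings — 50 Hz streams alternating smooth motion phases (SLERP between
  random keyframe orientations) with rest phases, plus small rotational
  noise, matching the regime of public IMU motion-capture corpora (tens of
  seconds to minutes per recording, roughly 4000-10000 samples per stream).

Noise is applied as a small random rotation composed onto the clean
orientation rather than additive component noise, so every emitted sample is
a unit quaternion by construction, the way an orientation filter's output
is.  Keyframes are drawn uniformly on the rotation group (Shoemake's
subgroup-algorithm construction).  Every generator is fully determined by an
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quaternion import hamilton, normalize, slerp
from .signal import Signal

__all__ = [
    "MotionSpec",
    "random_unit_quaternion",
    "generate_piecewise_linear",
    "generate_quaternion_motion",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class MotionSpec:
    """Parameters of a synthetic orientation recording.

    duration      total length in seconds
    rate          sampling rate in Hz (wearable IMU default: 50)
    n_keyframes   number of random target orientations visited
    rest_fraction fraction of the duration spent motionless
    noise_deg     scale (degrees) of the per-sample rotational noise
    seed          integer seed; fully determines the stream
    """

    duration: float = 120.0
    rate: float = 50.0
    n_keyframes: int = 40
    rest_fraction: float = 0.3
    noise_deg: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.rest_fraction <= 1.0:
            raise ValueError("rest_fraction must lie in [0, 1]")
        if self.noise_deg < 0:
            raise ValueError("noise_deg must be non-negative")
        if self.n_keyframes < 1:
            raise ValueError("need at least one keyframe")


def random_unit_quaternion(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Uniform random rotation(s) as unit quaternions (Shoemake's method)."""
    n = 1 if size is None else size
    u1, u2, u3 = rng.random((3, n))
    a = np.sqrt(1.0 - u1)
    b = np.sqrt(u1)
    q = np.stack(
        [
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
            b * np.cos(2 * np.pi * u3),
        ],
        axis=1,
    )
    return q[0] if size is None else q


def generate_piecewise_linear(
    breakpoint_times,
    slopes,
    rate: float = 50.0,
    start_values=None,
    seed: int | None = None,
) -> Signal:
    """Exactly piecewise-linear signal with corners at the breakpoint times.

    ``breakpoint_times`` are K+1 strictly increasing instants; ``slopes`` is
    (K, D), one slope vector per piece.  The signal is sampled on the uniform
    1/rate grid starting at the first breakpoint (breakpoints landing on the
    grid therefore appear as samples).  ``start_values`` defaults to zeros,
    or is drawn standard-normal when a seed is given.
    """
    bt = np.asarray(breakpoint_times, dtype=float)
    slopes = np.atleast_2d(np.asarray(slopes, dtype=float))
    if bt.ndim != 1 or len(bt) < 2:
        raise ValueError("need at least two breakpoint times")
    if np.any(np.diff(bt) <= 0):
        raise ValueError("breakpoint times must be strictly increasing")
    if len(slopes) != len(bt) - 1:
        raise ValueError("need exactly one slope vector per piece")
    D = slopes.shape[1]

    if start_values is None:
        if seed is not None:
            start_values = np.random.default_rng(seed).standard_normal(D)
        else:
            start_values = np.zeros(D)
    start_values = np.asarray(start_values, dtype=float)

    n = int(np.floor((bt[-1] - bt[0]) * rate + 0.5)) + 1
    t = bt[0] + np.arange(n) / rate
    t = t[t <= bt[-1] + 1e-12]

    # corner values by accumulating each piece's rise
    corner_vals = np.vstack(
        [start_values, start_values + np.cumsum(slopes * np.diff(bt)[:, None], axis=0)]
    )
    piece = np.clip(np.searchsorted(bt, t, side="right") - 1, 0, len(slopes) - 1)
    values = corner_vals[piece] + slopes[piece] * (t - bt[piece])[:, None]
    return Signal(t, values)


def _phase_schedule(spec: MotionSpec, rng: np.random.Generator) -> np.ndarray:
    """Start times of the motion phases: (K-1, 2) array of [start, end].

    The K-1 transitions between consecutive keyframes are laid out over the
    duration with rest gaps (totalling rest_fraction of the duration)
    interleaved before, between and after them, with randomised relative
    gap sizes.
    """
    k = spec.n_keyframes - 1
    motion_total = spec.duration * (1.0 - spec.rest_fraction)
    if k == 0:
        return np.empty((0, 2))
    motion_lens = rng.dirichlet(np.full(k, 5.0)) * motion_total
    gap_lens = rng.dirichlet(np.full(k + 1, 5.0)) * (spec.duration - motion_total)
    starts = np.cumsum(gap_lens[:-1]) + np.concatenate([[0.0], np.cumsum(motion_lens[:-1])])
    return np.stack([starts, starts + motion_lens], axis=1)


def generate_quaternion_motion(spec: MotionSpec) -> Signal:
    """Synthesize a unit-quaternion orientation stream from a MotionSpec.

    SLERPs between uniformly random keyframe orientations over motion phases,
    holds still over rest phases, then composes per-sample rotational noise
    with angle ~ |N(0, noise_deg)| about a uniformly random axis.  Output
    rows are unit (within 1e-12) and sign-continuous.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate

    keys = np.atleast_2d(random_unit_quaternion(rng, spec.n_keyframes))
    phases = _phase_schedule(spec, rng)

    values = np.empty((n, 4))
    if len(phases) == 0:
        values[:] = keys[0]
    else:
        starts, ends = phases[:, 0], phases[:, 1]
        # index of the transition each sample is in (or has most recently passed)
        k = np.searchsorted(starts, t, side="right") - 1
        for i in range(n):
            ki = k[i]
            if ki < 0:
                values[i] = keys[0]
            elif t[i] >= ends[ki]:
                values[i] = keys[ki + 1]
            else:
                u = (t[i] - starts[ki]) / (ends[ki] - starts[ki])
                values[i] = slerp(keys[ki], keys[ki + 1], u)

    if spec.noise_deg > 0:
        angles = np.abs(rng.normal(0.0, np.radians(spec.noise_deg), n))
        axes = rng.normal(size=(n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        half = angles / 2.0
        dq = np.column_stack([np.cos(half), np.sin(half)[:, None] * axes])
        values = np.array([hamilton(values[i], dq[i]) for i in range(n)])

    values = normalize(values)
    # sign continuity by construction: flip rows whose predecessor-dot is negative
    dots = np.sum(values[:-1] * values[1:], axis=1)
    flips = np.where(dots < 0.0, -1.0, 1.0)
    values *= np.concatenate([[1.0], np.cumprod(flips)])[:, None]
    return Signal(t, values)


def make_fixture_suite(seed: int = 0) -> dict[str, Signal]:
    """Deterministic named bundle of test signals spanning the regimes of interest.

    Keys: ``constant``, ``linear_1d``, ``piecewise_1d``, ``piecewise_4d``,
    ``slow_motion``, ``fast_motion``, ``mixed``, ``sign_flip``.  The
    ``sign_flip`` stream carries injected hemisphere flips (consecutive dot
    products < 0) for exercising segmentation with alignment disabled.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    rng_pw1 = np.random.default_rng(seeds[0])
    pw1 = generate_piecewise_linear(
        breakpoint_times=np.arange(7) * 1.0,
        slopes=rng_pw1.uniform(-2.0, 2.0, size=(6, 1)),
        rate=50.0,
    )
    rng_pw4 = np.random.default_rng(seeds[1])
    pw4 = generate_piecewise_linear(
        breakpoint_times=np.arange(6) * 0.8,
        slopes=rng_pw4.uniform(-1.0, 1.0, size=(5, 4)),
        rate=50.0,
    )

    const_q = random_unit_quaternion(np.random.default_rng(seeds[2]))
    n_const = 500
    constant = Signal(np.arange(n_const) / 50.0, np.tile(const_q, (n_const, 1)))

    linear = generate_piecewise_linear(
        breakpoint_times=[0.0, 10.0], slopes=[[0.37]], rate=50.0
    )

    slow = generate_quaternion_motion(
        MotionSpec(duration=60.0, n_keyframes=6, rest_fraction=0.4, noise_deg=0.2, seed=seeds[3])
    )
    fast = generate_quaternion_motion(
        MotionSpec(duration=60.0, n_keyframes=80, rest_fraction=0.05, noise_deg=0.2, seed=seeds[4])
    )
    mixed = generate_quaternion_motion(
        MotionSpec(duration=120.0, n_keyframes=40, rest_fraction=0.3, noise_deg=0.5, seed=seeds[5])
    )

    flip_src = generate_quaternion_motion(
        MotionSpec(duration=30.0, n_keyframes=10, rest_fraction=0.2, noise_deg=0.3, seed=seeds[6])
    )
    rng_flip = np.random.default_rng(seeds[7])
    signs = np.ones(len(flip_src))
    flip_at = rng_flip.choice(np.arange(1, len(flip_src)), size=8, replace=False)
    for i in np.sort(flip_at):
        signs[i:] *= -1.0
    sign_flip = Signal(flip_src.timestamps, flip_src.values * signs[:, None])

    return {
        "constant": constant,
        "linear_1d": linear,
        "piecewise_1d": pw1,
        "piecewise_4d": pw4,
        "slow_motion": slow,
        "fast_motion": fast,
        "mixed": mixed,
        "sign_flip": sign_flip,
    }
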