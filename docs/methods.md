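# Methods

## The segmentation model

A D-channel signal S = (s₁ … s_m) with strictly increasing timestamps is
approximated by connected linear segments whose endpoints ("segment
points") are a subset of the original samples. A segment grows from its
origin — the most recent segment point s̃ᵢ₋₁ — and for each new sample sₙ
the trial segment is the line through the origin and sₙ, with per-channel
slope βd = y_dn / tₙ in origin-relative coordinates (y_dj = υ(sⱼ,d) −
υ(s̃ᵢ₋₁,d), tⱼ = τ(sⱼ) − τ(s̃ᵢ₋₁)). The segment error is the sum of squared
residuals (SSR) of all covered samples against that line. The greedy
emission rule: while SSRₙ ≤ TH and the segment covers at most `cap` samples
beyond its origin, accept sₙ; otherwise freeze the previously accepted
sample as the next segment point and restart the segment there, with sₙ as
its first sample. After the last sample, the final accepted sample is
emitted as the terminal point so that the point series spans the full
recording and every original timestamp can be interpolated. (The stream
format leaves the fate of the open segment unspecified; emitting its last
sample is this package's choice, made so that reconstruction never needs to
extrapolate.)

Two implementations share this exact emission rule and differ only in how
SSRₙ is obtained:

* **Buffered SW** (`sliding_window`) stores the open segment and evaluates
  the SSR definition directly — O(n) time and memory per sample.
* **fastSW** (`segmenter`) expands the square and keeps running means of
  tⱼ², tⱼ·y_dj and y_dj², updated as m ← m + (x − m)/n, recomposing
  SSRₙ = Σd (y²̄_d − 2βd·t̄y_d + βd²·t²̄)·(n−1) in O(D) — constant in the
  segment length. The newest sample lies on the trial line by construction,
  so only the previous n−1 samples contribute. Means (rather than raw sums)
  keep the state well-scaled on long segments.

The two are "quasi-equal": mathematically identical, but the two evaluation
orders round differently, so when some prefix SSR lands within numerical
noise of TH the algorithms can split one sample apart. The equivalence
tests therefore compare boundaries only when every prefix SSR clears the
threshold by more than 1e-9·max(1, TH), and compare the SSR traces at
relative 1e-9 with an absolute floor of 1e-9 (cancellation makes tiny SSRs
accurate only in absolute terms: the incremental SSR of exactly collinear
data is rounding noise of either sign, of order `mean(y²)·n·1e-16`). For
the same reason the "a single linear piece never splits" behaviour holds
for any threshold above that noise floor, but not at TH = 0 exactly.

## Quaternion conventions

Components are scalar-first (w, x, y, z); q and −q encode the same rotation.
The angular deviation Δ(q₀,q₁) = 2·arccos |⟨q₀,q₁⟩| is reported in degrees;
the dot product is clamped to [0, 1] before the arccos, and bitwise-identical
(±) pairs short-circuit to exactly 0°, since otherwise the dot product's
last-bit rounding reports ~1e-6° for identical inputs. SLERP interpolates
along the shortest arc (hemisphere-flipping its second argument when
⟨q₀,q₁⟩ < 0) with constant angular velocity; when sin of the inter-quaternion
angle falls below 1e-8 it degrades to normalized linear interpolation, where
the two are indistinguishable at double precision.

Quaternion streams are made sign-continuous before segmentation (flip a
sample when its dot with the predecessor is negative; on by default for
D = 4, off otherwise). Component-space residuals would otherwise see a
hemisphere flip as a huge jump and split spuriously. With alignment active,
emitted points equal samples of the aligned stream — original samples up to
an overall sign, i.e. the same rotations.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| TH | user choice | per-segment SSR bound, in squared amplitude units of the signal (quaternion components are unitless, so TH is unitless too); 0 keeps every sample, larger values trade angular error for compression |
| cap (`max_segment_length`) | 1000 | most samples a segment may cover beyond its shared origin; bounds memory/latency on the receiving side and floors the ICR at 1/cap |
| sweep grid | 0 + 204 points log-spaced on [1e-6, 1e3] | 205 thresholds spanning nine decades, used by the sweep protocol to trace ICR-vs-error curves |
| sign alignment | on for D = 4 | hemisphere continuity preprocessing (above) |

## Synthetic signals

`generate_quaternion_motion` emulates what a wearable orientation filter
emits: 50 Hz unit-quaternion streams a few minutes long (the default 120 s
yields 6000 samples, inside the 4040–10180-samples-per-file range typical
of public IMU motion-capture corpora). Uniformly random keyframe
orientations (Shoemake's subgroup construction) are visited by SLERP over
motion phases, interleaved with rest phases totalling `rest_fraction`
(default 0.3) of the duration; per-sample noise is a small random rotation
of angle |N(0, noise_deg)| (default 0.5°, a typical orientation-filter
noise floor) about a random axis, composed onto the clean orientation so
samples stay exactly unit-norm. Defaults were fixed once from these
considerations. What the generator does **not** model: biomechanical
couplings between joints, gyroscope drift and filter transients,
magnetometer disturbance, or the spectral structure of specific activities.
Passing tests therefore certify the algorithmic contracts (exactness,
equivalence, cost, recovery) on realistic dynamics — not reconstruction
quality on any particular real recording.

`generate_piecewise_linear` produces exactly piecewise-linear signals with
corners on the sampling grid, for recovery tests: with corner deviation δ
and TH below ~δ²/4, the greedy rule flags the first post-corner sample and
emits its predecessor — the corner itself.

## Cost accounting

Costs are stated architecture-neutrally as counts of scalar multiplications,
additions/subtractions and divisions, tallied by running the *same* code
path on instrumented scalars (`counting.CountedFloat`). Composing two
rotations costs 28 scalar operations in quaternion form (16 mul + 12 add)
versus 45 (27 + 18) for the naive 3×3 matrix product. Processing one
accepted 4-channel sample costs fastSW a constant 77 operations regardless
of segment length, while buffered SW's count grows affinely with its buffer
(21 ops per buffered sample in this accounting). Comparisons and negation
are counted as free.

## Numerical and design choices

* Threshold comparison is inclusive (SSRₙ ≤ TH accepts the sample).
* The cap accepts a sample while n ≤ cap, so a segment covers at most cap
  samples beyond its origin; a constant 100,000-sample signal under
  cap 1000 yields exactly 101 points (ICR 0.00101, the 1/cap floor).
* Timestamps must be strictly increasing; duplicates are rejected, never
  merged (the slope divides by tₙ).
* The running-mean update is m ← m + (x − m)/n throughout.
* Reconstruction returns segment points bitwise at their own timestamps,
  so a TH = 0 run reproduces the original stream verbatim (AAD exactly 0).
* All state arithmetic is double precision.

## Problem sizes

The test suite checks oracle equivalence on 100 seeded signals (D ∈ {1, 4},
200–2000 samples) × 20 thresholds, incremental-SSR correctness on segments
up to 1000 samples, and the sweep-based exactness properties on 3 fixtures
× the full 205-value grid. The reproduction script uses 20 motion fixtures
of 6000 samples × 205 thresholds and the 100,000-sample constant signal.

## Known limitations

* At thresholds within rounding distance of a prefix SSR, fastSW and SW may
  place a boundary one sample apart (quasi-equality); both operating points
  are valid SW outputs.
* The incremental SSR can be slightly negative (cancellation); it is
  compared against TH as-is, which is harmless since the noise floor is far
  below any useful threshold.
* Sign alignment assumes the *stream's* flips are artefacts; signals whose
  genuine dynamics cross hemispheres within one sampling interval (>90°
  per sample) would be misread, but at 50 Hz that is far beyond human
  motion.
* ICR/AAD numbers on synthetic fixtures characterize the algorithms, not
  any specific real dataset.
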