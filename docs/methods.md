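# Methods

## Recognition model

The classifier is a nearest-template ensemble over dynamic time warping
distances. A query gait cycle (or prefix of one) is represented as a
`d × m` matrix of `d` sensor channels; each voter — one per training
subject — holds one averaged reference template per locomotive state
(LW, LW-SC, LW-SD) plus the z-score statistics of its training cycles.
A voter normalises the query with its own statistics, computes the mDTW
distance to each of its three templates, and votes for the nearest; the
ensemble's label is the plurality vote, with ties resolved by the smallest
mean distance over **all** voters (the tie is flagged in the prediction
record). Argmin ties inside a single voter are broken by the fixed state
order LW, LW-SC, LW-SD — deterministic and logged.

### DTW kernel

Pointwise cost is the single-sample Euclidean norm over channels
(absolute difference for one channel). The cumulative matrix uses the
standard three-predecessor recurrence with cumulative-sum boundary
conditions; the reported distance is the raw terminal cost `C(m,n)`
without path-length normalisation — all templates compared against a query
have equal status, so normalisation cannot change the argmin, and the raw
cost keeps the DP exactly equal to the minimum over enumerable warping
paths (which is how the kernel is tested). Backtracking prefers the
diagonal predecessor, then vertical, then horizontal: deterministic and
biased toward short paths. No warping window is applied by default; none
is needed at these sequence lengths (~120 samples per cycle at 100 Hz).

Two multichannel strategies are implemented. The default, *dependent*
mDTW, warps vector-valued samples along one shared path — all channels
constrain the same time alignment, which is the physically sensible choice
when the channels are simultaneous measurements of one limb trajectory.
The *independent* variant (per-channel scalar DTW, distances summed) is
kept for ablation. Both reduce exactly to scalar DTW for one channel.

### Early (prefix) recognition

A partial cycle covering fraction `p ∈ (0, 1]` from toe-off is compared
against the first `round(p·L)` samples of each template ("prefix"
matching). The alternative — matching the prefix against the full template
with a free endpoint on the template side (`min` over the last DP row) —
is implemented behind `prefix_mode="open_end"`. Prefix matching is the
default because a partial cycle aligned to a full template accrues
spurious warping cost for the unseen remainder, biasing all distances
upward and, more importantly, unevenly across templates of different
lengths. Prefixes shorter than 4 samples are rejected.

Normalisation statistics are fitted on the voters' full training cycles
and applied to the query, never fitted on the prefix itself: z-scoring a
30% prefix with its own statistics would shift and scale it by
phase-dependent quantities and break comparability across fractions.

## Preprocessing

- **Filtering**: second-order low-pass Butterworth at 15 Hz cutoff,
  applied forward–backward (zero phase). Processing is offline, so the
  non-causal zero-phase variant is preferred; note it squares the
  magnitude response (doubles attenuation in dB), which the test suite
  checks against the prewarped analytic response.
- **Normalisation**: z-score with sample standard deviation (ddof = 1),
  fitted per channel on training data, applied to queries (see above).
- **Thigh-angle extraction**: accelerometer gravity tilt
  (`atan2(a_y, a_z)`, degrees) is fused with the integrated gyro rate by
  a complementary filter (gyro weight α = 0.98), and the fused angle is
  smoothed by a two-state Kalman filter (state = [tilt, gyro bias];
  gyro-driven prediction, fused-angle measurement). The hand-off between
  the two filters is a design interpretation: the complementary-filter
  angle serves as the Kalman measurement. Defaults
  `q_angle = 1e-3 deg²/s`, `q_bias = 3e-3 (deg/s)²/s`,
  `r_angle = 0.5 deg²` were chosen on the synthetic generator such that
  the fused estimate beats both accelerometer-only and gyro-only
  estimates on a known trajectory with noisy, biased sensors; they are
  config values, not constants.

## Segmentation

Cycles run toe-off → next toe-off (swing first). Toe-off is detected from
the in-shoe FSRs: a stance interval is recognised when both heel and ball
pressures exceed `threshold + hysteresis` (defaults 0.05 + 0.02 normalised
pressure), and the event fires at the first sample where both drop below
the threshold, refined to the nearest local extremum of the
instrumented-shank accelerometer z-axis (the push-off spike) within
±50 ms. Candidates closer than the minimum cycle duration (0.6 s) to the
previous event are rejected; segmented cycles outside [0.6, 2.5] s are
dropped and logged, standing in for manual curation. The combination rule
(FSR threshold + accel refinement) is a design decision — the unloading
of the foot is the physical signature of toe-off, and the accelerometer
pins the sample. Mode labels attach to a cycle when its midpoint falls
inside a labelled interval.

## Augmentation

Transition cycles are expanded by (a) amplitude scaling at 96, 98, 102,
104%, (b) time resampling (linear interpolation onto a uniform grid) by
the same four factors — symmetric small perturbations, reused for length
because no separate resampling factors are canonical — and (c) AWGN at
SNR 30, 35, 40, 45 dB (noise variance = per-channel mean square power
/ 10^(SNR/10), seeded). The default spec therefore multiplies a class by
exactly 13. Augmentation runs after filtering and before normalisation
(z-scoring commutes with amplitude scaling, so the scaled copies are
informative only through resampling/noise interactions — documented, and
the order is switchable). Derived cycles inherit subject and label and
carry a provenance link to their raw original; evaluation folds split by
subject, which subsumes original/derived pairing, and a provenance audit
(`audit_loso_hygiene`) verifies it. At the library level LOSO evaluation
takes `augment_spec=None` (raw queries only); the CLI `evaluate` command
augments transitional query cycles by default while templates are always
built from raw cycles.

## Templates

Per (subject, mode): cycles are linearly resampled to the rounded mean
length of the contributing cycles and averaged element-wise (an optional
median is available for outlier-heavy data, off by default). The mean
length is computed per mode, so templates of different modes may differ
in length. Averaging `N` cycles of prototype + i.i.d. noise reduces RMSE
as `σ/√N`, which the tests verify by Monte Carlo.

## Evaluation

- LOSO: templates from all other subjects; subjects missing a mode are
  excluded from voting pools with a warning. "Overall accuracy" is pooled
  (micro) accuracy over all evaluated cycles; F1 is macro-averaged over
  the three classes because of the heavy LW imbalance.
- Forward selection: greedy, starting from the best single channel by
  pooled LOSO accuracy, adding the accuracy-maximising channel each step,
  stopping when no candidate **strictly** improves (ties stop) or a
  channel budget is reached. The best rejected candidate is recorded in
  the trace so the non-strict reading of the stopping rule can also be
  inspected.
- Personalization: a subject's cycles are split per mode (first half
  templates, second half evaluation); the personalized single-voter model
  is compared against the user-independent ensemble on the same held-out
  half across prefix fractions.

## Synthetic study conditions

The generator emulates the structure of a 9-subject wearable gait study:
100 Hz sampling, ~1.2 ± 0.08 s cycles, 10% LW-SC and 10% LW-SD transition
rates (with at least two cycles per mode per subject so template sets are
always buildable), per-subject lognormal amplitude gain (σ = 0.1) and
Gaussian phase shift (σ = 20 ms), and white sensor noise at a configurable
SNR (30 dB for the noisy benchmark). Mode prototypes are 4-harmonic series
per channel with deterministic per-channel coefficients; the transitions
add offsets bounded away from zero from the very start of the cycle, so
swing-phase recognition is possible by construction (validated at
generation time). FSR channels follow an analytic swing-zero /
stance-plateau pattern whose unloading completes exactly at the cycle
boundary, and the shank accelerometer z-axis carries a Gaussian push-off
spike at toe-off — giving the detector an exact ground truth.

Benchmark sizes used by the test suite and the reproduction script
(9 subjects × 12 cycles for LOSO sweeps; 5 × 15 for channel selection;
3 × 15 for detection) are the package's chosen desk-scale study
conditions: large enough that voting, selection and sweeps are exercised
with every mode present per subject, small enough to iterate on freely.

What the generator does **not** emulate: real gait morphologies (the
prototypes are analytic, not recorded curves), stance-phase dynamics
beyond the FSR pattern, cross-channel correlated noise, non-stationary
drift, or amputee-specific gait asymmetries. Passing tests therefore
demonstrate the correctness and internal consistency of the pipeline and
its claimed properties — not field performance on human data; on real
recordings the separability of modes at small prefixes is an empirical
question.

## Numerical choices and degenerate inputs

- Distances and averages in float64; the DP kernel is numba-compiled with
  a row-rolling variant for distance-only calls.
- Resampling is linear interpolation (exact on affine signals, endpoint
  preserving); `round()` half-to-even on lengths.
- Constant channels: z-scoring a constant signal is an error at the API
  level; inside template building a constant channel passes through
  centred with unit divisor and a warning (it carries no information
  either way).
- Zero-power channels make SNR undefined: augmentation raises.
- Ties: argmin by fixed mode order; vote ties by mean distance then mode
  order; backtracking diagonal-first.

## Known limitations

- The recognizer operates per (partial) cycle; there is no streaming
  controller, no stance-phase modes, and no steady stair cycles.
- Independent-strategy mDTW reports per-channel paths but the summed
  distance only; no channel weighting.
- No DTW barycenter averaging for templates; plain resample-and-average
  as specified.
- The voting scheme is unweighted one-subject-one-vote; distance-weighted
  voting exists behind a flag but is untuned.
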