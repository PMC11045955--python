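# gaitdtw

Swing-phase recognition of locomotion modes and mode transitions from
wearable gait sensors, using multidimensional dynamic time warping (mDTW)
template matching with multi-subject majority voting.

## The problem

A powered lower-limb prosthesis must know, early in the swing phase, whether
the user is about to keep walking on level ground (LW), transition into
stair climbing (LW-SC), or into stair descent (LW-SD): the power-demanding
part of the stride is the stance phase that follows, and the joint
controller has to be in the right mode before the foot lands. `gaitdtw`
implements a lightweight intent recognizer for this setting. Gait cycles are
segmented so they **start at toe-off** (swing phase first, inverting the
usual heel-strike convention), and a partial cycle — the first 10–100% of
the stride — is classified by comparing it against per-subject reference
templates of each locomotive state.

## The method

Two sequences `X = x_1..x_m` and `Y = y_1..y_n` (vector-valued samples over
the selected sensor channels) are aligned by dynamic time warping. With the
pointwise distance matrix `D[i,j] = ||x_i − y_j||`, the cumulative cost is

```
C(i,j) = D(i,j) + min( C(i−1,j), C(i,j−1), C(i−1,j−1) )
```

with `C(1,1) = D(1,1)` and cumulative sums on the first row and column; the
DTW distance is `C(m,n)`, and backtracking the minimal predecessors yields
the optimal warping path. The multidimensional extension used by default is
the *dependent* strategy: one shared warping path over vector-valued
samples (an *independent* per-channel variant is available for ablation).

On top of the kernel:

- **Templates** — per subject and per mode, cycles are resampled to their
  average length and averaged sample by sample; each subject's three-mode
  template set also stores the per-channel z-score statistics of its
  training cycles, so queries are normalised into template space.
- **Voting** — every subject's template set is one voter (nearest template
  by mDTW distance); the final label is the plurality vote, ties broken by
  the smallest mean distance across all voters.
- **Early recognition** — a query prefix (e.g. the first 30% of the cycle)
  is matched against the same fraction of each template.
- **Class balancing** — rare transition cycles are augmented by amplitude
  scaling (96/98/102/104%), time resampling, and additive white Gaussian
  noise at 30/35/40/45 dB SNR, with full provenance tracking.
- **Evaluation** — leave-one-subject-out (LOSO: the held-out subject's own
  templates never vote), prefix-fraction sweeps, greedy forward channel
  selection, and personalized-vs-generic template comparison.
- **Synthetic benchmark** — a generator of multi-subject, multichannel gait
  recordings (harmonic mode prototypes, per-subject amplitude/phase
  variation, cycle-length jitter, FSR stance/swing traces, sensor noise)
  with exact ground truth, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from gaitdtw import (DEFAULT_SIGNAL_CHANNELS, GeneratorSpec, dtw,
                     loso_evaluate, make_benchmark)

# the DP on a toy pair: 1 warps onto the run of 2s, 3 onto the run of 3s
r = dtw(np.array([1., 2, 3]), np.array([2., 2, 2, 3, 3]))
print(r.distance)   # 1.0
print(r.path)       # [(0, 0), (1, 1), (1, 2), (2, 3), (2, 4)]

# a 9-subject synthetic study at 30 dB sensor SNR, classified from the
# first 30% of each gait cycle with 6 channels, leave-one-subject-out
spec = GeneratorSpec(n_subjects=9, n_cycles=12, noise_snr_db=30.0, seed=5)
cycles, _ = make_benchmark(spec)
report = loso_evaluate(cycles, list(DEFAULT_SIGNAL_CHANNELS[:6]),
                       prefix_fraction=0.3)
print(f"pooled accuracy: {report.overall_accuracy_pct:.2f}%  "
      f"macro F1: {report.overall_macro_f1:.4f}")
# pooled accuracy: 100.00%  macro F1: 1.0000
print(report.confusion)
# [[71  0  0]
#  [ 0 18  0]
#  [ 0  0 19]]
```

The confusion matrix rows/columns follow the fixed order LW, LW-SC, LW-SD:
all 71 level-walking, 18 stair-ascent-transition and 19
stair-descent-transition cycles of the held-out subjects are recognised
from the first 30% of the cycle.

The same pipeline is available as a CLI (`gaitdtw simulate | segment |
augment | templates | classify | evaluate | select-channels`); see
`gaitdtw --help`.

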