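# Methods

## The detection and classification model

`minipsc` analyses single-channel recordings of spontaneous postsynaptic
currents (or analogous fluorescence transients). The canonical event
waveform is a peak-scaled difference of two exponentials

    f(t) = s · (e^(−t/τ_d) − e^(−t/τ_r)),    0 < τ_r < τ_d,

with `s` chosen so `max f = 1`; the multiplying coefficient of the kernel is
then the event's peak amplitude, and the peak occurs at
`t_peak = τ_r τ_d/(τ_d−τ_r) · ln(τ_d/τ_r)`.

Candidate events are found by FFT deconvolution: the recording's spectrum is
divided by the zero-padded kernel's spectrum and transformed back. An event
resembling the template contributes an approximate delta of height equal to
its amplitude at its onset, while noise is amplified at the high frequencies
where the kernel spectrum is small. The quotient is therefore band-pass
filtered (defaults 1 and 200 Hz) before thresholding. One candidate is taken
per contiguous supra-threshold region, at that region's maximum; the
detector peak sample is the event's onset estimate.

Candidates are then screened by one of two criteria:

* **Pearson screening** — keep candidates whose Pearson correlation with the
  template over the post-onset window reaches a threshold in [−1, 1]
  (−1 = no screening);
* **Random forest** — a 400-tree bagged ensemble (Gini impurity, 4 of the
  10 features considered per split, unlimited depth) trained on labelled
  candidates; prediction by majority vote, with a tied vote resolving to
  *reject*, biasing toward false-positive suppression. The out-of-bag (OOB)
  error is reported as the internal estimate of prediction error.

The 10 features per candidate are peak amplitude, 10–90% rise time,
half-width, fitted decay time constant, area, Pearson r against the
template, pre-onset baseline SD, time-to-peak, window skewness, and detector
peak height — a set chosen to span amplitude, kinetics, shape match and
noise context. The feature list is versioned inside every model file and a
model refuses to classify events computed under a different version. This
particular set is this package's own; other tools using the same general
approach define their own feature sets, and no equivalence is implied.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| template τ_r, τ_d | ms | 0.44, 6.12 | typical mEPSC template for 40 kHz whole-cell data |
| kernel duration | ms | 8·τ_d | truncates <0.04% of the tail |
| detector band | Hz | 1, 200 | high-pass removes drift; low-pass controls division-amplified noise |
| detection threshold | σ | 3 | sensitive enough to hand the classifier most true events plus a usable pool of false candidates |
| Pearson threshold | – | 0.5 | balanced TPR/FPR in the synthetic study |
| forest size | trees | 400 | OOB error plateaus well before this on ~100-candidate training sets |
| matching tolerance | ms | 1.2 | onset agreement window used by every evaluation |

## The synthetic-data generator

Each simulated event draws amplitude and kinetics from log-normal
distributions (exp of normal draws): log-amplitude N(2.46, 0.35) pA,
log-rise N(−0.31, 0.60) ms, log-decay N(1.48, 0.46) ms — modes 10.4 pA,
0.51 ms, 3.55 ms — with the decay redrawn until it exceeds the rise. Onsets
are uniform over the record (optionally spaced by a minimum inter-event
interval); each event's own peak-scaled kernel is placed by FFT circular
convolution of equal-length vectors, so an event near the end wraps to the
start (ground truth records the pre-wrap onset). Noise is white Gaussian,
default RMS 2.43 pA, matching the rolling-window RMS of real whole-cell
recording noise from CA1 pyramidal neurons; a user-supplied noise trace can
be substituted. The random stream is consumed per event in the order
amplitude → rise → decay → onset, so a seed fully determines a simulation.

What the generator does *not* emulate: real patch-clamp noise is not white —
it carries 1/f drift, correlated channel noise, and occasional artifacts.
White noise at matched RMS produces *fewer* false detector crossings at 3 σ
(~10–25 per 9.9 s wave versus ~50–70 on real recording noise), so
classification on these simulations is somewhat easier than on real data:
training sets carry ~50–60 candidates per wave rather than ~100, OOB errors
are lower (≲2% versus ~5%), and pipeline accuracies a few points higher.
Passing tests therefore demonstrate correctness of the machinery and
realistic relative behaviour of the criteria, not absolute performance on
real recordings.

## The evaluation suite

Detected and reference onsets are aligned by greedy one-to-one
nearest-neighbour matching within the tolerance (closest pair first, ties
to the earlier reference time). Greedy matching can be suboptimal when
several events crowd within twice the tolerance; at physiological event
rates this regime is negligible, and the matcher never over-matches. From
the accepted/rejected partition: TP = accepted ∧ matched, FP = accepted ∧
unmatched, TN = rejected ∧ unmatched, FN = reference with no accepted
match. A rejected candidate that *does* match a reference event counts
toward nothing itself — the missed event surfaces as a FN. Metrics: FPR =
FP/(FP+TN), TPR = TP/(TP+FN), accuracy = (TP+TN)/total, FDR = FP/(FP+TP); a
metric with a zero denominator is returned as `None`, never silently NaN.

Inter-rater agreement uses the Matthews correlation coefficient
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) (0 by convention at a
zero marginal), computed over the union of two raters' candidate pools
aligned by onset matching; a slot absent from one rater's pool counts as
rejected by that rater. Grid summaries use the mean of off-diagonal
entries. Condition differences are tested by the exact paired permutation
test: all 2^n sign assignments of the per-subject differences are
enumerated (n ≤ 25), and the two-tailed p is the proportion of assignments
whose |mean difference| reaches the observed one, the observed assignment
included — so p ≥ 2/2^n for a nonzero effect with distinct values. A
Monte-Carlo mode with the (1+hits)/(1+draws) estimator covers larger n.

## Numerical choices

* **Zero-phase band-pass.** The 2nd-order Butterworth high- and low-pass
  stages are realised in the frequency domain as the magnitude-squared
  Butterworth response — exactly the response of forward–backward
  time-domain filtering, but free of edge transients on the noisy quotient
  and numerically robust for a 1 Hz cutoff at 40 kHz sampling (a normalized
  cutoff of 5·10⁻⁵ makes time-domain SOS coefficients ill-conditioned). The
  wrap-around boundary matches the circular convolution of the simulator.
* **No Wiener regularization.** The FFT division is raw; the band-pass is
  the noise control. An optional `eps` floor on kernel-spectrum bins exists
  but is off by default.
* **Noise SD of the detector** is estimated by fitting a Gaussian to a
  40-bin histogram of the central 80% of detector values (initialized at
  IQR/1.349), falling back to MAD·1.4826. Sparse event spikes lie far
  outside the central 80% and do not bias the estimate (<1% error on pure
  Gaussian values at n = 10⁵, <1% with 1% large outliers).
* **Template fitting** uses trust-region least squares on
  baseline + A·kernel(t−t₀; τ_r, τ_d) with log-parameterized constants
  (τ_d = τ_r + e^δ enforces τ_r < τ_d), initialized from the 10% onset
  crossing, the peak, and the 1/e decay time. Noiseless synthetic events are
  recovered to <1%.
* **Windows and intervals.** Sample indexing is 0-based; time intervals are
  half-open [start, end) seconds. Event windows span [onset − 1 ms,
  onset + kernel duration); the baseline is the 1 ms pre-onset mean, or the
  first 0.25 ms after onset when the event sits at the record start
  (flagged truncated). Splitting keeps a non-dividing tail as a shorter
  final wave flagged `remainder` rather than discarding data.
* **Degenerate inputs.** Zero-variance windows raise on Pearson
  computation; single-class label sets raise on training; a constant
  detector yields σ = 0; confusion metrics with empty denominators return
  `None`.

## Problem sizes used by the standard study

The accuracy study (`minipsc.benchmark.run_accuracy_study`, also driven by
`scripts/acceptance.py`) simulates 4 training + 4 test waves of 40 events
over 9.9 s at 40 kHz, trains one forest per training wave on
oracle-labelled candidates, and classifies each test wave with a different
model — the package's standard evaluation geometry. Per-wave seeds derive
from one master seed through `numpy.random.SeedSequence`.

## Known limitations

* ABF and other proprietary acquisition formats are not read; convert to
  CSV/TSV, raw int16 + JSON sidecar, or the documented HDF5 layout.
* Events are assumed positive-going; negate inward-current recordings
  before analysis.
* Overlapping events are detected but their windows are extracted
  independently — no subtraction of neighbouring fits, so amplitude and
  area of heavily overlapping events are biased.
* Greedy matching, not optimal assignment (see above).
* Model files are portable across machines, not across feature versions or
  other implementations.
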