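# Methods

`ictalscope` re-creates a complete seizure-detection pipeline for chronic
single-channel intracranial EEG: fixed 5-s analysis windows are transformed
into one of five input modalities, a small neural network classifies each
window, and a rule-based post-processing stage assembles window-level
positives into seizure events. Because the chronic recordings such pipelines
are developed on cannot be redistributed, the package ships a synthetic
generator that reproduces the statistical contrast the method exploits, and
every quantitative claim in the test suite is made on that synthetic data.

## Segmentation scheme

Training segments use two different strides because ictal EEG is scarce:
windows slide inside each annotated event with a 0.25-s stride (a 10-s event
yields 21 seizure segments), while non-seizure segments tile the 5 minutes
before and after each event with a 2.5-s stride (119 windows per full
flank). At test time, windows tile the whole record at 2.5 s; a record of
`T` seconds yields `floor((T-5)/2.5)+1` windows. Two choices the window
arithmetic forces but that are otherwise open:

* flanks are clipped at record boundaries and windows overlapping *any*
  annotated event are dropped, so no non-seizure training segment contains
  ictal samples;
* the ground-truth label of a continuous test window is *seizure* iff its
  overlap with annotated events is at least 50% of the window. The threshold
  is configurable (`label_windows(..., overlap_frac=...)`); any fixed rule
  here only moves a handful of border windows per event.

All times are float seconds from record start and intervals are half-open
`[onset, offset)`, which makes window/event overlap arithmetic exact on the
2.5-s grid.

## Input modalities

For a 5-s segment at 1,000 Hz (5,000 samples):

| modality | shape | construction |
| --- | --- | --- |
| `raw500` | 500 | block-average downsampling to 100 Hz (mean of 10 samples per point) |
| `pgram100` | 100 | periodogram of the full-rate segment (0.2-Hz bins), power averaged in 1-Hz bands `[k, k+1)`, k = 0..99 |
| `stft_img` | 20x50 | Hamming-window STFT (0.5-s window, 75% overlap) of the 100-Hz trace, `log(1+|S|)`, anti-aliased resize to 20 frequency rows x 50 time columns, per-segment min-max to [0,1] |
| `wave_img` | 40x250 | binary rasterization of the 500-point trace, 2 samples per column, connected vertically to the previous column |
| `ctx_img` | 40x750 | three `wave_img` blocks taken 2.5 min before, at, and 2.5 min after the window (clamped at record edges, never zero-padded) |

Numerical details worth recording:

* The 1-Hz band averaging is the only way to get 100 non-trivial points
  between 0 and 99 Hz from a 5-s segment: the 100-Hz downsampled trace
  cannot reach 99 Hz, so the periodogram is computed at full rate.
* STFT window length/overlap and the log compression are free parameters of
  the image; they are fixed as above and exposed as keyword arguments.
  75% of the 50-sample window rounds to 38 overlap samples.
* Rasterization uses a *per-recording* display gain (`RasterScale`: center =
  record median, half-range = half the 0.5-99.5 percentile span), not
  per-segment min-max. Per-segment scaling would erase the amplitude
  difference between ictal and background EEG, which is precisely the signal
  the amplitude gate and, in part, the classifiers rely on. Amplitudes
  outside the scale clip to the top/bottom row; row index increases
  downward, positive amplitude up.
* An all-zero segment maps to an all-zero STFT image (min-max guard).

## Classifiers

Four families, all ending in a 2-node softmax:

* **fcnn** — two ReLU hidden layers (default 256, 64) with dropout 0.3;
* **rnn_lstm** — consecutive sample pairs form the input sequence (250 steps
  for `raw500`, 50 for `pgram100`); a 20-unit LSTM with forget-gate bias 1;
  the hidden outputs are averaged over time before the output layer. No
  dropout: there is no fully connected hidden layer in this family;
* **cnn1d / cnn2d** — two convolution(stride 1)-maxpool(stride 2) blocks
  (defaults: 32 then 64 filters, kernel 5 for 1-D and 3x3 for 2-D), then two
  dense hidden layers (128, 64) with dropout 0.3.

The published architecture table is not available; the widths above are this
package's defaults and everything is configurable per family. None of the
package's checks depend on particular widths.

Training is minibatch Adam (lr 0.001, beta 0.9/0.999, batch 128 by default)
on cross-entropy, with a random 10% validation split, early stopping on
validation loss (patience 3 epochs, min-delta 0 — the patience is a choice,
only the criterion is given upstream), and restoration of the
best-validation parameters. Class imbalance (~1:3 in training) is left
unweighted by default.

The layers, backpropagation and Adam are implemented in numpy (convolution
inner loops jitted with numba, with an equivalent numpy fallback). Gradients
of every family are verified against central finite differences in the test
suite. With a single integer seed controlling initialization, the validation
split, batch order and dropout masks, training is bit-reproducible;
inference disables dropout and is deterministic.

1-D inputs are z-scored per feature with training-set statistics before
entering a network; `pgram100` is z-scored on a `log1p` scale because raw
band power spans several orders of magnitude. Images are already in [0,1].
This preprocessing is the package's own choice; nothing upstream specifies
input scaling.

## Event detection

Positively classified windows whose start times lie within 10 s of each
other (inclusive; starts live on a 2.5-s grid, so start-to-start distance is
the natural metric) merge into one candidate spanning first start to last
start + 5 s. Single-window candidates are removed. A candidate survives only
if its mean absolute amplitude is >= 1.2x (inclusive) that of the nearby
EEG. "Nearby" is not defined upstream; here it is symmetric flanks of
max(event duration, 30 s) per side, excluding samples inside other
candidates; if one side is missing the other is used alone, and with no
flank at all the candidate is rejected with a warning. A detection counts as
true if it overlaps any annotated event (half-open intervals); event
sensitivity is over annotated events and FDR is false detections per hour
analyzed.

## Synthetic data generator

The generator emulates only what the pipeline consumes:

* **background**: 1/f^alpha Gaussian noise (alpha = 1 by default, RMS 50 uV)
  via spectral shaping, plus biphasic interictal spikes at a Poisson rate
  (0.05 Hz by default) with random polarity and ~4x background amplitude —
  these produce exactly the isolated false-positive windows the
  singleton-removal rule exists for;
* **seizures**: a jittered impulse train at a per-event rate drawn from
  3-8 Hz, convolved with a spike-wave complex spanning ~one cycle (keeping
  the spectral fundamental at the spiking rate), with a 0.5-s low-amplitude
  onset ramp and 1-s offset decay. The trace is scaled so its mean absolute
  amplitude is `amplitude_gain` (default 2.0) times the background's, which
  keeps the 1.2x detector gate satisfiable by construction;
* **assembly**: durations uniform in 8.34-61.25 s (the span of annotated
  event durations in the recordings this stands in for), onsets placed with
  >= 360 s pairwise gaps so +/-5-min training flanks never touch a
  neighbouring event, and >= 120 s from record edges. Events replace the
  background (plus 20% bleed-through) rather than adding to it.

What it does **not** model: non-stationary background state (sleep/wake),
electrode artifacts, evolving within-seizure frequency dynamics,
channel-correlated noise (multi-channel records are independent channels),
and the full morphological variety of real ictal EEG. Consequently the
synthetic classification task is *easier* than the real one: passing the
end-to-end checks demonstrates that the pipeline is wired correctly and that
every architecture can learn the ictal/interictal contrast, not that the
reported real-data performance would be reproduced.

## Statistics

Confusion counts may be non-integer (means over repeated runs); the metric
formulas accept them directly. Metric values shown next to published tables
are truncated, not rounded, to 3 decimals — the published values are
reproducible from the printed mean counts only under truncation. ROC/AUC is
trapezoidal (scikit-learn curve; the tests verify equality with an O(n^2)
pairwise oracle including ties). Two classifiers scored on the same windows
are compared with a paired permutation test: statistic |AUC_A - AUC_B|, null
built by swapping each window's score pair independently with probability
1/2, p = (1 + #{null >= observed}) / (1 + 1000). The original description of
the ROC permutation test leaves the statistic ambiguous; the AUC-difference
swap test used here is checked against exhaustive enumeration at n = 6 and
for type-I error calibration under the null. A textbook one-way ANOVA F is
provided for comparing FP/FN counts across families; per-run counts are also
exported as CSV for external stats software.

## Benchmark problem sizes

`experiment.benchmark_config()` fixes the package's standard synthetic
experiment: one 1-h training record with 3 seizures (~215 seizure / ~715
non-seizure segments — above the 200/600 floor the end-to-end checks
require), one independent 1-h test record, one training repeat per
combination, 8 epochs maximum, and compact widths (8/16 conv filters, 64/32
or 32/16 dense). These sizes were chosen once as the smallest configuration
on which all nine combinations separate the classes clearly on a single CPU
core; the reference-scale defaults (five repeats, 32/64 filters, 50 epochs)
remain the library defaults for real use.

## Known limitations

* EDF support is read-oriented; the built-in writer emits minimal 16-bit
  EDF sufficient for round-tripping signals and sampling rate, not full
  patient metadata.
* The RNN averages LSTM *hidden outputs* over time; averaging cell states is
  a plausible alternative reading of the upstream description.
* Multi-channel records are carried through I/O and segmentation
  (per-channel), but the experiment runner and event detector operate on one
  channel at a time; no cross-channel fusion rule is provided.
* `stft_img` orientation is frequency rows x time columns and `wave_img` is
  amplitude rows x time columns; both are conventions, configurable at the
  transform level.
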