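# Methods

This note documents the models, conventions and numerical choices behind
emgmotion, in the spirit of a package reference manual: what each stage
assumes, which knobs matter, and what the synthetic experiments do and do
not demonstrate.

## Data model

A `Recording` is a sample-aligned triple: an `n_samples × n_channels`
signal matrix in raw sensor units, a per-sample movement label
(`stimulus`, 0 = rest) and a per-sample repetition index (`repetition`,
0 during rest, 1..6 during a movement). This mirrors the Ninapro MAT
layout. The reader accepts both the original (`stimulus`/`repetition`)
and the refined, movement-aligned (`restimulus`/`rerepetition`) annotation
dialects and prefers the refined ones when both are present — they are the
recommended movement annotations — recording the choice on the object and
allowing an override via `field_map`. Classic (v7) and HDF5-backed (v7.3)
MAT files are both supported; v7.3 arrays are transposed on read because
MATLAB stores them column-major. Sampling rate is not stored in all
Ninapro files, so it is a required argument when absent (200 Hz for DB5,
2000 Hz for DB7).

## Synthetic signal model

The generator reproduces the acquisition protocol — per movement class,
six repetitions of 5 s activity each followed by 3 s of rest — with
amplitude-modulated Gaussian noise: rest is zero-mean noise of standard
deviation `baseline_noise_sd` (default 0.01, arbitrary units), and during
a movement the per-channel SD is scaled by `1 + a_{c,ch} · (1 + ε_rep)`
where `a` is the class-by-channel activation matrix and `ε_rep ~
N(0, envelope_jitter_sd)` is redrawn per repetition (default SD 0.1,
mimicking trial-to-trial amplitude variability). Multi-subject datasets
additionally perturb the activation matrix per subject with the same
relative SD. Default activations are drawn once from U(0.5, 4.0) per
class/channel, which makes classes distinct in their cross-channel
amplitude *pattern*, not just in overall level.

This captures exactly the statistical structure the time-domain features
measure — amplitude and turn statistics per channel — and nothing more: no
motor-unit physiology, no realistic power spectrum, no electrode-shift or
fatigue effects, no label noise at movement boundaries beyond the sharp
transition itself. Near-perfect accuracy on this generator therefore
demonstrates that the pipeline is wired correctly (no leakage, correct
splits, features informative, optimizer converging), not that comparable
accuracy would be reached on real recordings, where class overlap is
physiological.

By construction a 5 s/3 s protocol yields a rest fraction of 3/8 of the
samples; optional inter-class rest padding (`inter_class_rest_s`) raises
this toward the roughly one-half rest share seen in full acquisition
sessions.

## Windowing conventions

Durations convert to samples by `round(fs · ms / 1000)`; at 200 Hz and
2 kHz every standard window size is integral, so no ambiguity arises.
Windows start at offsets 0, S, 2S, … and the trailing partial window is
dropped, giving `floor((N − W)/S) + 1` windows. Each window takes the
modal per-sample label; ties break toward rest when rest is among the tied
labels, otherwise toward the smallest class index — conservative toward
no-movement, since for a prosthesis a spurious command is worse than a
missed one. Windows straddling movement boundaries are kept (the usage
simulation needs them); a `strict` mode drops non-unanimous windows for
ablations.

Train/test routing is by repetition (default {1,3,4,6} / {2,5}). Rest
windows carry repetition 0, so they are routed by the repetition of the
nearest preceding movement sample; this keeps rest represented in both
splits with disjoint provenance. Leading rest with no preceding movement
defaults to the training split.

## Features

Per channel and window: RMS, MAV, MAV slope, ZC, SSC, waveform length, in
that column order. The threshold gate uses strict sign inequalities (an
exact zero never crosses) and a closed `≥ T` amplitude condition; the
summation ranges are restricted to indices where every referenced
neighbour sample exists. MAV slope follows the segment-difference
definition; the segment count is configurable and defaults to two equal
halves (split index `⌊W/2⌋`), keeping the feature count at six per channel
for every window size. Default thresholds: 0.01 for DB5-tagged data
(applied to values as stored; the stored Myo units are not guaranteed to
be volts), 1e-8 / 1e-6 for DB7 intact / amputee groups, always
overridable.

Standardization uses the population estimator (divide by n), declared and
fixed so worked examples reproduce exactly. Zero-variance columns are
flagged and centered only (they map to 0). Statistics always come from the
training split; the parameter object is frozen, so the test path has no
fitting surface.

## Classifier

Input → 512 → 256 → 256 → K with batch normalization after each hidden
linear map (before the ReLU, the common reading of "each layer followed
by" normalization and activation), 20% inverted dropout after each hidden
activation, linear + softmax output. He-uniform initialization
(`U(±√(6/fan_in))`). Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7) at learning
rate 0.005; "decay" 1e-5 is interpreted as per-update learning-rate decay
`lr_t = lr/(1 + decay·t)`, with L2 weight decay available as the
alternative interpretation via `decay_mode="weight"`. Cross-entropy clips
probabilities at 1e-12 before the log. Exact probability ties in
prediction resolve to the lowest class index. The class list is the sorted
set of labels seen in training, rest included, so the network has
(movements + 1) outputs.

Defaults of 100 epochs, batch size 256, no early stopping and no
validation split are the package's own reproducibility-first choices; the
synthetic tasks in the tests and in `scripts/acceptance.py` use 40 epochs
(12–20 inside the threshold search, with batch 64 because inner-split
training sets are small), which is ample for convergence at those problem
sizes (≈3200 training windows × 48 features for the ten-class task).

The implementation is pure numpy with hand-written backpropagation; with
a fixed seed, initialization, shuffling and dropout masks are fully
determined, so repeated runs agree bitwise.

## Evaluation

Overall accuracy is trace/total of the confusion matrix. Macro recall
(reported as balanced accuracy) and macro precision average per-class
ratios over classes *present in the ground truth*; classes absent from the
truth have undefined recall and are excluded (and listed in the report),
while classes present but never predicted contribute precision 0. Macro F1
is the harmonic mean of the two macro values, not the mean of per-class
F1. Rest participates in the macro averages by default; `exclude_rest`
switches it off, and reports record which mode was used. Recall bands are
`≥ 0.8` (practical), `[0.6, 0.8)` and `< 0.6`, with a closed lower bound
at 0.8.

The threshold grid search scans 1e-4 … 1e-12 by factors of 10 (nine
candidates), scoring balanced accuracy. Scoring on evaluation data would
leak the choice, so the default fits on repetitions {1,3,4} and scores on
{6} — an inner split of the training repetitions — with a
`score_on_test` option for exact replication of the
score-on-evaluation-data variant. Ties select the larger threshold (the
more conservative noise gate).

## Usage simulation

`simulate` slides the trained model over an uncut recording, including
rest and transitions; labels are used only to annotate the trace. Spans of
constant non-rest truth are located, and a margin of 2 windows per span
edge (one window of genuine boundary overlap plus one of majority-label
lag) is classed as transitional; errors there are reported separately from
mid-movement errors, which are the ones that would abruptly switch a
prosthesis mid-action. The margin is configurable, as is an optional
majority-vote smoothing over the last k predictions (off by default; all
reported numbers are unsmoothed).

## Experiment sweeps

`run_experiment` iterates subjects × window sizes with per-cell seeds
derived from the master seed via `SeedSequence`, so the whole sweep is
reproducible and individual cells are independent. Cell failures are
recorded and skipped, not fatal. Per-subject models are the default
(matching mean ± SD reporting across subjects); a pooled mode trains one
model per window size on all subjects' training windows. The 8-channel
condition of a 16-channel recording is expressed as a column-index list
and defaults to the first eight columns (which armband that corresponds to
depends on the acquisition metadata of the source dataset; the choice is
explicit and overridable).

## Known limitations

- The synthetic generator's separability means synthetic accuracies are
  near ceiling and say nothing quantitative about real-data performance.
- Real Ninapro archives must be supplied by the user; only the DB5/DB7
  field layouts (plus a generic `field_map`) are supported.
- The epoch count, batch size and validation protocol of the original
  experiments on real data are not publicly specified, so exact
  replication of published accuracies is not guaranteed by construction.
- Offline only: segmentation is batch, not a real-time ring buffer, and no
  latency measurement is included.
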