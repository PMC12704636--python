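# Methods

## Problem and approach

Conventional sleep scoring segments the night into fixed 30-second
epochs, each assigned a single predominant stage, and marks arousals
(abrupt EEG frequency shifts of at least 3 s, preceded by at least 10 s
of stable sleep) as separate events. This representation cannot place
sleep-to-wake transitions more precisely than the epoch boundary, and
it splits physiologically similar phenomena — wakefulness and arousals
— across two annotation streams. somnoseg implements an epoch-free
alternative: a two-state *sleep* versus *wakefulness-like* segmentation
at resolutions down to 1 second, where "wakefulness-like" consolidates
scored wake and arousals into one continuously-timed class.

The pipeline has four parts:

1. **Label construction.** Conventional annotations are converted into
   temporally-continuous-style binary training labels: stages are
   binarized (W → wake-like; N1/N2/N3/REM → sleep), arousal events are
   overlaid onto the 1-second lattice as wake-like, and a heuristic
   correction refines sleep-to-wake transition points (below).
2. **Segmentation model.** A 1-D U-Net over the 128 Hz sample axis
   emits a per-cell two-class softmax; an average-pooling segment head
   sets the output resolution.
3. **Transfer learning.** The model pre-trained on modified
   conventional labels is fine-tuned on continuously scored data with
   participant-grouped 4-fold cross-validation.
4. **Evaluation.** Percentage concordance, Cohen's κ, sensitivity and
   specificity for the wake-like class, total sleep time (TST), sleep
   efficiency, the sleep-to-wake transition index, misclassified-run
   histograms, confidence statistics, and cohort-level Pearson /
   Bland–Altman agreement.

## Label construction rules

*Arousal incorporation.* Every 1-second cell with non-zero overlap with
an arousal interval becomes wake-like. Cells are never changed toward
sleep, so the operation is monotone and idempotent. Arousals marked
inside wake-scored epochs do not change those cells (they are already
wake-like) but still participate in the correction step.

*Heuristic transition correction.* When conventional scoring marks an
entire epoch as wake, the true transition often occurred at an arousal
onset inside the epoch. For each arousal whose onset (i) falls in a
wake-scored epoch, (ii) lies strictly in the first half of that epoch,
and (iii) follows a sleep-scored epoch, the cells from the epoch onset
up to the arousal onset are reassigned to sleep. Design choices the
source rules leave open, fixed here: "first half" is read strictly
(an onset exactly at the midpoint does not qualify); an arousal
spanning an epoch boundary is attributed to the epoch containing its
onset; the first qualifying arousal per epoch wins and later arousals
in the same epoch are ignored; cells at or after an arousal onset are
never altered, and with a fractional onset only cells fully before it
are reassigned. Wake epochs that follow sleep but contain no arousal
are not adjusted.

*Standalone smoothing (post-prediction).* A 1-second prediction of one
class surrounded by the opposite class is smoothed using the model's
probabilities: if the mean probability of the standalone's class over
the 3-second window centred on it is below 0.5 the lone cell is
flipped; otherwise the whole window is reassigned to the standalone's
class. Standalones are detected on the unmodified input and edits are
applied left to right to a working copy, which makes the operation
deterministic; cells at the grid boundary lack a two-sided window and
are left unchanged.

*Rasterization.* Continuous interval annotations are discretized by
cell-majority occupancy; an exact 50/50 tie resolves to wake-like
(conservative for detecting disruption). The simulated conventional
scorer uses the opposite tie rule for epochs (an exact half-epoch of
wake stays sleep), reflecting scorer conservatism; the two tie rules
are deliberately distinct.

## Signal preprocessing

Channels are processed per recording in a fixed order: referential
derivation (e.g. C4−M1) → zero-phase band-pass → polyphase resampling
to 128 Hz → robust clipping → robust normalization → trimming to the
scored region. Choices:

- Band-pass: 4th-order Butterworth, 0.3–35 Hz, applied
  forward-backward (`sosfiltfilt`) so event timing is not shifted.
  Even-reflection padding sized as three time constants of the 0.3 Hz
  edge (3·fs/0.3 samples) suppresses edge transients that the default
  padding leaves behind.
- Resampling: `scipy.signal.resample_poly` at the rational ratio to
  128 Hz; an input already at 128 Hz passes through unchanged.
- Clipping: samples outside median ± k·IQR are clipped, k = 20 by
  default, with order statistics computed over the whole channel. A
  constant channel (IQR = 0) passes through with a logged warning.
- Normalization: subtract median, divide by IQR; falls back to the
  standard deviation when the IQR is zero and to a unit divisor when
  both are zero.

All times are seconds from the recording start and intervals are
half-open `[onset, offset)`; trimming advances `start_offset_s` so
annotation times remain alignable.

## Network and training

The segmenter is a 1-D U-Net implemented directly on numpy arrays with
hand-written backpropagation (verified against finite differences in
the test suite): one same-padded convolution + ELU per encoder level,
pair max-pooling between levels, nearest-neighbour upsampling with
skip concatenation in the decoder, filter counts growing by ~√2 per
level, and a segment head that average-pools the full-resolution
feature map over `resolution_s × 128` samples before a pointwise
2-class softmax. Defaults: depth 2, 8 base filters, kernel 9 — sized
for the synthetic experiments; depth and filters are configuration,
not constants, and deeper settings suit full-night clinical data.

Training minimizes class-weighted cross-entropy (weights inverse to
class frequency) with Adam on randomly sampled 60-second windows
aligned to the label grid, one random (EEG, EOG) channel pair per
window. Early stopping monitors Cohen's κ on held-out validation
recordings (patience 3–5 rounds) and the best-κ weights are restored.
Default learning rates are 1e-3 for pre-training and 1e-4 for
fine-tuning, chosen for the convergence horizon of the small default
model; both are exposed in configuration. All randomness flows from a
single integer seed, so runs are reproducible.

At inference the softmax probabilities are computed per available
(EEG, EOG) pair and averaged across pairs; hard labels are the argmax
with the p = 0.5 tie resolving to wake-like, consistent with the
rasterization tie rule. Long recordings are processed in 10-minute
blocks with a 30-second halo on each side so block boundaries do not
perturb interior cells. A trailing partial cell is dropped with a
warning.

Transfer learning partitions recordings into 4 folds with
`GroupKFold` so no participant spans folds, fine-tunes all weights at
the reduced rate on three folds, and validates on the fourth. The
final model is the fold model with the highest validation κ;
ensembling the fold models was considered and rejected to keep the
deployed artifact a single network.

## Synthetic data

The generator defines the study conditions for every experiment:

- **Truth process:** an alternating renewal process with exponential
  sleep/wake bout durations (means 300 s and 60 s; the night starts
  awake), plus arousal-analogue intrusions inserted into sleep bouts
  as a Poisson process at 10 events per hour of sleep. Each intrusion
  lasts at least 3 s (3 s + an exponential excess of mean 4 s) and
  requires at least 10 s of uninterrupted sleep before it; candidates
  violating the gap or overflowing the bout are rejected, which thins
  the realized rate by a few percent.
- **Signals:** per channel, pink base noise (5 µV) plus a sleep
  component (delta 0.5–3 Hz at 30 µV and theta 4–7 Hz at 20 µV) and a
  wake component (alpha 8–12 Hz at 25 µV plus 6 µV broadband), mixed
  by a wake envelope with 0.5 s raised-cosine crossfades at state
  changes. EOG channels add slow (0.3 Hz) rolling waves around
  wake-to-sleep transitions. Amplitudes were set so that alpha/theta
  band dominance separates the states in every 30-second window.
- **Conventional scorer:** epochs are labeled W when wake-like
  occupies strictly more than half the epoch (sleep epochs are emitted
  uniformly as N2 — stage identity is irrelevant after binarization);
  arousal events are all truth wake intervals ≥ 3 s preceded by ≥ 10 s
  of sleep, marked regardless of the epoch's own label.
- **Distribution shift** (for the transfer experiment): wake alpha
  amplitude ×0.45, broadband ×1.8, sleep delta and theta ×0.6, 12 µV
  of alpha intrusion into sleep (emulating "alpha-delta sleep", a
  documented EEG pattern in older and clinical populations), mean
  sleep bout ×0.7, arousal rate ×1.5. Because channels are robustly
  normalized, amplitude-only changes barely move the learned decision
  boundary; the alpha intrusion is what creates a genuine domain gap —
  a model pre-trained on the default population drops to fold κ of
  roughly 0.4–0.7 on shifted nights before fine-tuning.

The default night is 30 minutes — a deliberately scaled-down problem
size that keeps the full train/evaluate/transfer cycle at minutes of
CPU time while exercising every pipeline stage; all experiment sizes
below use it. What the generator does *not* emulate: sleep spindles,
K-complexes, REM eye movements, respiratory events, artifacts beyond
stationary noise, inter-scorer disagreement, or non-stationarity
within a state. Passing the synthetic experiments therefore
demonstrates that the pipeline's machinery is correct and that the
model can learn spectrally defined state distinctions; it does not
certify clinical-grade performance on real polysomnography, which the
much harder spectral overlap of real EEG would reduce.

## Experiment sizes and expected behaviour

- *Label-modification study:* 200 nights; the modified labels agree
  with rasterized truth at least as well as plain binarized epochs on
  ≥ 95% of nights (in practice, on all of them, gaining ~3 percentage
  points of concordance on average).
- *Scaled-down learning:* 20 training + 5 held-out nights, depth-2
  model, ≤ 6 epochs; held-out 1-second concordance ≥ 90% and κ ≥ 0.75.
  The synthetic task is easier than real scoring, so realized values
  are well above these floors.
- *Transfer learning:* 12 shifted nights from 8 participants (4 with
  repeat nights), 4 grouped folds, 4 fine-tuning epochs per fold; mean
  fold κ after fine-tuning exceeds the pre-trained model's κ.

## Numerical and degenerate-input choices

- Cohen's κ returns 1 when both scorings are the identical single
  class (observed and chance agreement both 1), and 0 when chance
  agreement is 1 but observed agreement is not.
- Sensitivity/specificity with an empty denominator are reported as
  missing (None), never as 0.
- Pearson correlation with a zero-variance series is reported missing.
- Grids of unequal length are truncated to the common span with a
  logged warning; comparing grids of different resolutions or onsets
  is a contract error.
- The EDF writer quantizes to 16-bit integers over the per-channel
  peak range; round-trips are exact only to that resolution.
- Mean prediction confidence is computed on pre-smoothing
  probabilities by default (the smoothing operation consumes, not
  produces, probabilities).

## Known limitations

- Only two-state scoring; no five-stage continuous staging, REM/NREM
  substructure, or arousal subtyping.
- The numpy network is CPU-only and sized for scaled-down
  experiments; training full-scale clinical models would require a GPU
  framework.
- EDF files with mixed per-channel sampling rates are returned at the
  unified rate chosen by the mne reader rather than native rates.
- The simulated conventional scorer is deterministic; real inter-rater
  variability is not modelled.
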