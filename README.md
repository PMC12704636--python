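# somnoseg

Epoch-free, high-temporal-resolution sleep/wake classification for
polysomnography (PSG).

Conventional sleep scoring divides the night into fixed 30-second
epochs, each labeled with a single predominant stage, while arousals —
abrupt EEG shifts of ≥ 3 s preceded by ≥ 10 s of stable sleep — live in
a separate event stream. That representation cannot localize
sleep-to-wake transitions inside an epoch and splits physiologically
similar phenomena (wake and arousal) across two annotation systems.
somnoseg is for sleep researchers who want a two-state, *temporally
continuous* alternative: per-second probabilities of sleep versus a
consolidated **wakefulness-like** class (wake + arousals), with the
agreement and fragmentation metrics to validate them against
continuously scored references.

The package provides:

- **Label construction** — converts 30-s stages + arousal events into
  1-second binary labels: binarization (W → wake-like, N1/N2/N3/REM →
  sleep), arousal overlay at 1-s resolution, and a heuristic correction
  that moves a sleep→wake transition to the arousal onset when the
  arousal sits in the first half of a wake epoch that follows sleep.
- **`SleepWakeSegmenter`** — a scikit-learn-style estimator wrapping a
  1-D U-Net over 128 Hz EEG+EOG pairs with a softmax segment head at a
  configurable resolution (1–30 s); class-weighted cross-entropy,
  early stopping on validation Cohen's κ, probability-averaged
  multi-pair inference, and participant-grouped 4-fold fine-tuning
  (`finetune`) for transfer learning.
- **`PsgPreprocessor`** — derivation, zero-phase 0.3–35 Hz band-pass,
  polyphase resampling to 128 Hz, robust clipping (median ± 20·IQR) and
  robust normalization, trimming to the scored region. EDF in/out.
- **Evaluation** — percentage concordance, Cohen's κ, wake
  sensitivity/specificity, TST, sleep efficiency, the sleep-to-wake
  transition index (transitions/h), misclassified-run histograms,
  prediction-confidence statistics, and cohort Pearson/Bland–Altman
  agreement; plus probability-driven smoothing of standalone 1-s
  predictions.
- **Synthetic PSG generator** — a continuous two-state ground-truth
  process with AASM-consistent arousal structure, spectrally distinct
  sleep/wake signals, and a simulated conventional 30-s scorer, so the
  entire pipeline is testable without any data download.

For κ and the label algebra in standard notation: with observed
agreement p_o and chance agreement p_e from the marginal label
frequencies, κ = (p_o − p_e)/(1 − p_e); the transition index is
#{t : y_t = sleep, y_{t+1} = wake-like} per hour of recording.

## Worked example

Simulate six short nights, train a small segmenter on five, and score
the held-out night against the continuous ground truth:

```python
import somnoseg as ss

nights = ss.make_dataset(6, ss.SimConfig(), seed=7)
pre = ss.PsgPreprocessor()
recs = [pre.transform_record(n.record) for n in nights]
labels = [ss.build_labels(n.epochs, n.arousals, "modified") for n in nights]

est = ss.SleepWakeSegmenter(depth=2, base_filters=8, max_epochs=3,
                            random_state=0)
est.fit(recs[:5], labels[:5], validation=(recs[5:], labels[5:]))

truth = ss.rasterize(nights[5].truth, 1)       # continuous reference at 1 s
pred = est.predict([recs[5]])[0]
report = ss.compute_report(pred, truth, est.predict_proba([recs[5]])[0])
print(f"concordance {report.concordance_pct:.2f}%  kappa {report.kappa:.3f}")
print(f"TST {report.tst_min:.1f} min  S->W index {report.s2w_index_per_h:.1f}/h")
```

```
concordance 99.78%  kappa 0.994
TST 22.1 min  S->W index 22.0/h
```

Concordance is the percentage of 1-second cells on which the model and
the continuous reference agree; κ corrects that for chance. TST is the
predicted total sleep time of the 30-minute night and the S→W index
counts distinct sleep-to-wake transitions per hour — the fragmentation
measure that epoch-based scoring cannot produce at this granularity.
(Synthetic signals are far more separable than real EEG; on clinical
data, agreement in the high-80s/low-90s is the realistic regime.)

The same pipeline is scriptable from the shell:

```bash
somnoseg simulate --n 6 --seed 7 --out data/
somnoseg train --data data/ --seed 0 --out run/
somnoseg predict --model run/model.npz --data data/ --smooth --out pred/
somnoseg evaluate --pred pred/night_005_pred.csv --ref ref.csv --out metrics.json
```

## Layout

- `src/somnoseg/signal_io.py` — PSG containers, EDF/HDF5 I/O, preprocessing
- `src/somnoseg/hypnogram.py` — label algebra and conversions
- `src/somnoseg/model.py`, `src/somnoseg/_nn.py` — estimator and network
- `src/somnoseg/simulate.py` — synthetic PSG generator
- `src/somnoseg/evaluation.py` — metrics
- `src/somnoseg/cli.py` — `somnoseg` command-line pipeline
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
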