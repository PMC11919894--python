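# pediscreen

Deep-learning screening of 12-lead electrocardiograms in school-age
children, built around a frequency-domain representation of the ECG.

School ECG screening programs ask one question of every recording: *does
this ECG contain any guideline abnormality that warrants secondary
examination?* Rule-based interpreters answer it with high sensitivity but
poor specificity, flagging large numbers of healthy children. `pediscreen`
implements an alternative: a convolutional classifier that reads a compact
spectral representation of the 12-lead waveform together with the child's
age and sex, plus the full evaluation machinery needed to compare it
fairly against a conventional interpreter. Because real pediatric
screening waveforms are not publicly shareable, the package ships a
physiologically structured 12-lead ECG simulator so the entire pipeline is
testable and demonstrable end to end.

It is aimed at researchers prototyping ECG screening models and at
methodologists who need the comparator-aware evaluation statistics
(matched-sensitivity operating points, McNemar tests, decision curves) in
one place.

## Method

1. **Spectral tensorization** (`pediscreen.preprocess`). R peaks are found
   with the Pan–Tompkins detector (band-pass 5–15 Hz, derivative,
   squaring, 150 ms integration, adaptive thresholds). The waveform
   between the **second and last R peak** is extracted, each lead is
   Fourier-transformed into amplitude and phase, low-passed at 50 Hz, the
   lead axis is rearranged into the Cabrera sequence
   (aVL, I, −aVR, II, aVF, III, V1…V6), and the retained frequency grid is
   resampled to 400 bins — yielding a **2 × 12 × 400** tensor
   (amplitude/phase × leads × frequency).
2. **Classifier** (`pediscreen.model`). A 21-weight-layer VGG-style
   network: private two-convolution stems for the amplitude and phase
   channels, channel-concatenation, a 14-convolution trunk with pooling
   mostly along the frequency axis, and three dense layers with the
   (age/18, sex) vector concatenated before the first. Trained with
   binary cross-entropy and Adam under 5-fold cross-validation split at
   the *patient* level; each fold checkpoints its minimum-validation-loss
   epoch, and the ensemble prediction is the mean of the five sigmoid
   outputs. The network runs on a small self-contained numpy engine
   (`pediscreen.nnet`), which keeps training deterministic and exposes the
   intermediate gradients that saliency mapping needs.
3. **Evaluation** (`pediscreen.evaluation`). ROC/AUC, the Youden-J
   operating point, the matched-sensitivity operating point (threshold
   chosen so the model's sensitivity equals the comparator's, making the
   specificities comparable), accuracy/sensitivity/specificity/PPV/NPV
   with percentile-bootstrap CIs, McNemar's paired test, decision-curve
   net benefit, and per-finding reports.
4. **Explanation** (`pediscreen.explain`). Grad-CAM at a chosen
   convolutional layer produces a 12 × 400 spectral saliency map, which is
   carried back to the time domain by inverse FFT using the record's own
   phase spectrum and rendered under the Cabrera-ordered waveforms.
5. **Simulation** (`pediscreen.synth`). A sum-of-Gaussians dipole beat
   model projected onto the 12 leads (Einthoven's II = I + III holds by
   construction) with injectable abnormalities — ST-T change, complete and
   incomplete right bundle branch block, axis deviation, ventricular
   hypertrophies, WPW, Brugada pattern, SVT, third-degree AV block,
   PVCs — each scaled by a severity in [0, 1], plus an intentionally
   overcalling rule-based comparator used as plumbing.

## Worked example

Screening metrics from a 2×2 table (the counts below are the conventional
interpreter's verdicts on a 310-ECG test cohort with 84 abnormal records,
of which it flagged 208):

```python
>>> from pediscreen.evaluation import ConfusionTable, metrics
>>> report = metrics(ConfusionTable(tp=80, fp=128, fn=4, tn=98), seed=0)
>>> round(report.accuracy.value, 2), round(report.specificity.value, 2)
(0.57, 0.43)
>>> report.accuracy
Estimate(value=0.5741935483870968, ci_low=0.5225806451612903, ci_high=0.6290322580645161)
```

The interpreter catches 80 of 84 abnormal ECGs (sensitivity 0.95) but
mislabels 128 of 226 normal ones, so only 38% of its referrals are true
positives — the high-sensitivity/low-specificity profile that motivates a
learned model.

A full simulate → preprocess → train → evaluate → explain cycle:

```bash
pediscreen run --seed 7 --out runs/demo
```

writes `summary.json` (AUC, both operating points with bootstrapped
metrics, McNemar p-value, per-finding table), `decision_curve.csv`,
`predictions.tsv` and a saliency overlay PNG. On the default desk-scale
configuration (600 training / 310 test synthetic records, 27% abnormal)
the held-out AUC is typically 0.93–0.97.

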