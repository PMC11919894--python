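# Methods

This note records the modelling assumptions, parameter choices and known
limitations of `pediscreen`, in the spirit of a model-description appendix.

## Spectral representation

The classifier never sees the raw waveform. A record is reduced to a
2 × 12 × 400 tensor as follows.

**QRS detection.** The Pan–Tompkins chain runs on lead II (the largest R
amplitude under the simulator's lead geometry; the detector lead is
configurable): zero-phase Butterworth band-pass 5–15 Hz, five-point
derivative, squaring, 150 ms moving-window integration, adaptive
signal/noise thresholds with a 200 ms refractory period and a searchback
pass at half threshold, then refinement of each detection to the waveform
extremum within ±50 ms. Fewer than three detections raises an
`InsufficientBeatsError`, since no segment can be extracted.

**Segmentation.** The analyzed segment is `[r[1], r[-1])` — from the
second R peak (inclusive) to the last (exclusive), 0-based. The half-open
convention makes the segment length exactly the sum of the interior RR
intervals and keeps repeated runs byte-identical.

**Fourier transform.** Per lead, a real-input FFT with amplitude scaling
2/L (1/L at DC and Nyquist), so a unit-amplitude sinusoid yields a bin
amplitude of ≈1 mV regardless of segment length. Bins with frequency
≤ 50 Hz are retained: `B = floor(50 L / fs) + 1`. With resizing disabled
the (amplitude, phase) pair inverts to the 50 Hz-low-passed segment to
within 1e-9 relative error (tested).

**Cabrera reordering.** The lead axis is rearranged to
aVL, I, −aVR, II, aVF, III, V1…V6 — the frontal leads in contiguous
anatomical angle order with aVR sign-inverted, chest leads appended. The
reorder is applied to the time-domain segment before the FFT; because
negation commutes with the Fourier transform this is equivalent to
negating the spectrum (phase shift by π), and it keeps the operation a
pure, invertible permutation-with-sign on real arrays.

**Resizing.** Amplitude is linearly interpolated from the B native bins
onto 400 equally spaced frequencies over [0, 50] Hz. Phase is interpolated
on the *unwrapped* phase and rewrapped to (−π, π]; naive interpolation in
the wrapped domain would create spurious discontinuities at ±π crossings.
When B > 400 values are interpolated at the target frequencies, not
averaged. The tensor keeps `(L, fs, B, amp_b, phase_b)` as metadata so the
mapping can be inverted.

**Meta vector.** (age_years/18, sex) with male = 1, female = 0.

## Classifier

A VGG-style network with 21 weight layers: two convolutions per input stem
(amplitude and phase branches, fused by channel concatenation), a trunk of
14 convolutions in five blocks (base widths 64·2, 128·3, 256·3, 512·3,
512·3), and three dense layers (128, 32, 1-sigmoid) with the meta vector
concatenated before the first. All kernels are 3×3. Max pooling shrinks
the frequency axis at every block boundary (including once between the
stems and the trunk) and the lead axis only at the last two boundaries,
because that axis has extent 12. Under this schedule the 12th
convolutional layer (counting the amplitude stem 1–2, then the trunk 3–16)
sees a 12 × 25 feature map.

Training: binary cross-entropy on logits, Adam, batch 32, 5-fold
cross-validation with folds split at the patient level (a child's repeat
ECGs never straddle a fold). Each fold checkpoints the epoch with the
lowest validation loss; test-time prediction is the mean of the five fold
models' sigmoid outputs — the simplest exchangeable combination rule.

Two presets:

| preset | width multiplier | learning rate | epochs | purpose |
|---|---|---|---|---|
| `paper` | 1 | 1e-7 | 100 | the published recipe, full width |
| `desk` | 1/16 | 1e-3 | 4 | single-CPU runs in minutes |

The desk preset is the package's working scale: the tests and the
acceptance script train it on 600-record cohorts and evaluate on
310-record cohorts (27% abnormal, injected severities ≥ 0.7), where it
reaches held-out AUC ≈ 0.95. The paper preset's learning rate is tuned to
a much larger real cohort and is retained for fidelity, not for desk use.

**Input normalization.** The network is fed
`(log10(amplitude + 1e-6) − μ)/σ` (μ, σ estimated on the training group
and stored with the ensemble) and `phase/π`. Raw spectra span four orders
of magnitude in mV and stall gradient descent; the log-standardization is
a property of the model, not of the tensor contract, which stays in mV.

**Engine.** The layers, Adam and backpropagation are implemented directly
in numpy (`pediscreen.nnet`): im2col + BLAS matmul convolutions,
non-overlapping max pooling with crop, inverted dropout, a numerically
stable sigmoid/BCE head. This keeps single-threaded training exactly
reproducible from a seed and exposes any layer's post-ReLU activations and
their gradients, which grad-CAM consumes without framework hooks.

## Synthetic cohorts

**Beat model.** Each beat is a sum of Gaussian wavelets (P, Q, R, S, T and
optional extras) on a rotating dipole. A wavelet carries a frontal-plane
and a horizontal-plane angle. Leads I, II, III are cosine projections of
the dipole in the frontal plane, attenuated by the cosine of the
horizontal angle; the augmented leads are *derived* (aVR = −(I+II)/2,
aVL = (I−III)/2, aVF = (II+III)/2), so Einthoven's identity and the
augmented-lead identities hold to machine precision at zero noise. Chest
leads V1…V6 are cosine projections in the horizontal plane at fixed
electrode angles (−60°, −40°, −20°, 0°, +20°, +40°) with a shared
attenuation constant 0.8.

**Rhythm.** RR intervals are 60/HR × (1 + jitter), jitter Gaussian with
σ = 4% of RR by default. Resting heart rate follows the pediatric schedule
HR = 120 − 4·(age − 6) bpm with ±10% between-subject jitter; the exact
slope is immaterial to the pipeline, only the age–rate coupling matters
(it gives the age input something to explain). Records carry the true
R-peak sample indices and QRS onset/offset windows as ground truth.

**Abnormalities.** Each finding deforms the normal template monotonically
in a severity s ∈ [0, 1]: axis deviation rotates the QRS wavelets by
s·90°; complete RBBB widens the QRS (×(1+0.4s)) and adds a
rightward-anterior R′; incomplete RBBB is the milder version; RVH adds an
R-synchronous rightward-anterior component (tall V1 R); LVH scales R and S
voltages; ST-T abnormality depresses the ST segment (−0.25s mV) and
flattens/inverts T; Brugada adds a right-precordial coved ST hump; WPW
shortens PR and adds a delta wave; SVT raises the rate to 185 + 35s bpm
with damped P waves; third-degree AV block slows the ventricular rate to
55 − 5s bpm with an independent 95 bpm P train; PVC replaces every k-th
beat with a wide ectopic complex, k shrinking with severity. Cohort
sampling uses a finding mixture proportional to the prevalences of a
pediatric screening test group (ST-T abnormality dominant, then complete
RBBB, axis abnormality, RVH, …), 27% abnormal by default, severities
uniform on [0.7, 1.0], ages uniform on 6–18, and ~35% of patients
contributing a repeat ECG of the same class.

**Comparator.** A rule-based stand-in flags a record when any coarse
measurement (maximum QRS width, frontal axis outside 5–105°, V1 or V6 R
amplitude, ST deviation, rate limits) trips. Its thresholds sit close to
normal variability, so it is sensitive (≈1.0) and unspecific (≈0.4) on
simulated cohorts — the profile of a conservative screening interpreter.
It is plumbing for end-to-end demonstrations and is never a label source.

**What the simulator does not emulate.** Real electrode artifacts, baseline
wander beyond a small low-frequency drift, respiratory modulation,
pediatric normal-limit tables, multi-finding records, and the full
morphological variability of real hearts. Passing tests therefore
demonstrate that the pipeline is implemented correctly and that the
classifier can learn cleanly separable spectral signatures — not that the
reported AUC transfers to real pediatric ECGs.

## Evaluation conventions

- **Bootstrap CIs.** Percentile bootstrap, B = 2000, seeded; resampling
  records of a fixed 2×2 table is realized as a multinomial draw over its
  four cells. Statistics with empty denominators are reported as
  undefined, never 0.
- **Youden threshold.** Candidates are midpoints between adjacent unique
  probabilities (plus outer sentinels), so the returned threshold sits
  strictly between the groups it separates; ties break toward the higher
  threshold (higher specificity).
- **Matched-sensitivity threshold.** The largest threshold whose
  sensitivity still clears the target — the most specific operating point
  satisfying the floor.
- **McNemar.** Exact two-sided binomial on the discordant counts when
  b + c < 25, continuity-corrected chi-square otherwise; p = 1 when there
  are no discordant pairs.
- **Per-finding reports.** For finding F the positives are the records
  carrying F and the negatives are *all* other records, including records
  with different abnormalities; the comparator keeps its fixed flags, the
  model's threshold is matched to the comparator's sensitivity on F, and
  McNemar is applied to the paired specificity outcomes over the negative
  set. This negatives convention reproduces the arithmetic of published
  per-finding screening tables; it inflates apparent specificity
  differences when findings co-occur, which is why it is stated here
  prominently.
- **Decision curves.** Net benefit = TP/n − (FP/n)·pt/(1−pt) − harm with
  harm = 0 by default; the comparator contributes a flat curve from its
  fixed verdicts; treat-all and treat-none are included.

## Saliency

Grad-CAM at conv layer 12 (configurable): channel weights are the spatial
means of the logit gradients, the weighted feature-map sum is rectified,
bilinearly upsampled to 12 × 400 and max-normalized; ensemble CAMs are
averaged over the five fold models. The CAM is then treated as a surrogate
amplitude spectrum: each lead row is resampled from the 400-bin display
grid back to the record's native B-bin FFT grid (the inverse of the resize
interpolation), combined with the record's own phase spectrum and inverted
to the time domain. Saliency is the absolute value smoothed with a 40 ms
moving average and max-normalized per record; the map is linear in the CAM
up to that final normalization. The 40 ms window and the warm colormap of
the overlay are rendering choices.

On desk-trained ensembles and synthetic complete-RBBB records, the mean
saliency inside the true QRS windows (±60 ms) exceeds the record-wide mean
in well over 70% of records (tested at n = 50) — a weak localization check,
not a faithfulness audit.

## Numerical and degenerate-input choices

- Train-count rounding in the patient split is round-half-up; the split is
  a seeded permutation of the sorted patient list.
- The WFDB dialect uses gain 1000 ADC units/mV (1 µV resolution), format
  16; only the subset the package writes is parsed. The CSV/JSON bundle
  round-trips float64 samples losslessly via `repr`.
- All stage seeds derive from one global seed by a fixed affine scheme; no
  stage reads system entropy.
- Pooling crops trailing rows/columns that do not fill a window
  (25 → 12 under a 1×2 pool).
- Zero-amplitude records, single-class folds, fingerprint mismatches and
  out-of-range grad-CAM indices fail fast with named errors.

## Limitations

The classifier's reported performance is on simulated data whose
abnormalities are, by construction, spectrally separable; real-world
validation would require real annotated pediatric ECGs. The paper-scale
training recipe (lr 1e-7, 100 epochs, full width) is provided but not
exercised at desk scale. The per-finding evaluation inherits the
overall-abnormality output: it measures how well one global score ranks
records with a given finding, not a finding-specific detector.
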