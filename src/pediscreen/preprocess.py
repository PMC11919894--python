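"""Raw record -> 2 x 12 x 400 spectral tensor.

Pipeline: Pan-Tompkins QRS detection on the detector lead; extraction of
the window from the second to the last R peak; per-lead real FFT into
amplitude and phase; low-pass truncation at 50 Hz; Cabrera reordering of
the lead axis (aVL, I, -aVR, II, aVF, III, V1..V6, with aVR sign-inverted);
linear resize of the retained frequency grid to 400 bins. The metadata
needed to invert the mapping (segment length, sampling rate, retained-bin
count, original per-lead phase) travels with the tensor so saliency maps
can be carried back to the time domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .io import ECGRecord, LEAD_NAMES

#: Cabrera presentation: frontal leads in contiguous anatomical angle order
#: with aVR inverted, then the chest leads appended V1 -> V6.
CABRERA_ORDER: tuple[str, ...] = (
    "aVL", "I", "-aVR", "II", "aVF", "III",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


class InsufficientBeatsError(RuntimeError):
    """Fewer than three QRS complexes detected: no segment can be extracted."""


@dataclass
class PreprocessConfig:
    fs: float = 500.0
    lowpass_hz: float = 50.0
    n_freq_bins: int = 400
    detector_lead: str = "II"
    band_hz: tuple[float, float] = (5.0, 15.0)
    mwi_ms: float = 150.0
    refractory_ms: float = 200.0
    refine_ms: float = 50.0
    cabrera_order: tuple[str, ...] = CABRERA_ORDER

    def validate(self) -> "PreprocessConfig":
        if not (0 < self.lowpass_hz < self.fs / 2):
            raise ValueError("lowpass_hz must lie below the Nyquist frequency")
        if self.n_freq_bins < 2:
            raise ValueError("n_freq_bins must be at least 2")
        return self


@dataclass
class QRSAnnotation:
    r_sample_indices: list[int]
    detector_lead: str


@dataclass
class SegmentedECG:
    """Per-lead samples over [second R, last R), equal length across leads."""

    leads: dict[str, np.ndarray]
    segment_length: int
    fs: float
    record_id: str


@dataclass
class SpectralTensor:
    """Model input: amplitude and phase channels on a 12 x 400 grid.

    ``values[0]`` is amplitude (mV, non-negative), ``values[1]`` phase
    (radians in (-pi, pi]); the lead axis is in Cabrera order and the
    frequency axis spans [0, lowpass_hz] Hz in 400 equal steps. ``amp_b``
    and ``phase_b`` keep the un-resized spectra on the ``n_bins_retained``
    native bins for inverse mapping.
    """

    values: np.ndarray                 # (2, 12, 400)
    segment_length: int
    fs: float
    lowpass_hz: float
    n_bins_retained: int
    amp_b: np.ndarray                  # (12, B), Cabrera order
    phase_b: np.ndarray                # (12, B), Cabrera order
    record_id: str

    def validate(self) -> "SpectralTensor":
        if self.values.shape != (2, 12, self.values.shape[2]):
            raise ValueError("tensor must have shape (2, 12, n_freq_bins)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains non-finite values")
        if np.any(self.values[0] < 0):
            raise ValueError("amplitude channel must be non-negative")
        return self


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection
# ---------------------------------------------------------------------------

def detect_qrs(record: ECGRecord, cfg: Optional[PreprocessConfig] = None) -> QRSAnnotation:
    """Classic Pan-Tompkins chain with adaptive thresholds and searchback.

    Band-pass 5-15 Hz, five-point derivative, squaring, 150 ms moving-window
    integration, signal/noise running thresholds with a 200 ms refractory
    period, searchback at half threshold when an expected beat is missed,
    and refinement of each detection to the waveform extremum within
    +/-50 ms on the detector lead.
    """
    cfg = (cfg or PreprocessConfig()).validate()
    fs = record.fs
    x = np.asarray(record.leads[cfg.detector_lead], dtype=float)
    n = len(x)

    sos = signal.butter(2, cfg.band_hz, btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.convolve(bp, np.array([1.0, 2.0, 0.0, -2.0, -1.0]) / 8.0, mode="same")
    sq = deriv ** 2
    w = max(1, int(round(cfg.mwi_ms / 1000.0 * fs)))
    mwi = np.convolve(sq, np.ones(w) / w, mode="same")

    refractory = int(round(cfg.refractory_ms / 1000.0 * fs))
    peaks, _ = signal.find_peaks(mwi, distance=max(1, refractory // 2))
    if len(peaks) == 0 or float(mwi.max()) <= 0:
        raise InsufficientBeatsError(f"record {record.record_id!r}: no activity on detector lead")

    init = mwi[: int(2 * fs)]
    spki = 0.6 * float(init.max())
    npki = 0.5 * float(init.mean())
    threshold = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_hist: list[float] = []
    for p in peaks:
        if accepted and p - accepted[-1] < refractory:
            continue
        if mwi[p] > threshold:
            # searchback: a long gap hides a low-amplitude beat
            if accepted and rr_hist:
                rr_avg = float(np.mean(rr_hist[-8:]))
                if p - accepted[-1] > 1.66 * rr_avg:
                    seg = mwi[accepted[-1] + refractory : p - refractory // 2]
                    if len(seg) > 0:
                        q = int(np.argmax(seg)) + accepted[-1] + refractory
                        if mwi[q] > 0.5 * threshold:
                            rr_hist.append(q - accepted[-1])
                            accepted.append(q)
            if accepted:
                rr_hist.append(p - accepted[-1])
            accepted.append(int(p))
            spki = 0.125 * float(mwi[p]) + 0.875 * spki
        else:
            npki = 0.125 * float(mwi[p]) + 0.875 * npki
        threshold = npki + 0.25 * (spki - npki)

    # refine to the local waveform extremum (largest baseline deviation)
    half = int(round(cfg.refine_ms / 1000.0 * fs))
    baseline = float(np.median(x))
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(n, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi] - baseline))))
    refined = sorted(set(refined))
    out = []
    for r in refined:
        if not out or r - out[-1] >= refractory:
            out.append(r)
    if len(out) < 3:
        raise InsufficientBeatsError(
            f"record {record.record_id!r}: only {len(out)} beats detected")
    return QRSAnnotation(r_sample_indices=out, detector_lead=cfg.detector_lead)


def extract_segment(record: ECGRecord, ann: QRSAnnotation) -> SegmentedECG:
    """Samples in [second R, last R), half-open, identical across leads."""
    r = ann.r_sample_indices
    if len(r) < 3:
        raise InsufficientBeatsError(
            f"record {record.record_id!r}: need at least 3 R peaks, got {len(r)}")
    start, stop = int(r[1]), int(r[-1])
    L = stop - start
    if L < int(record.fs * 0.4):
        raise InsufficientBeatsError(
            f"record {record.record_id!r}: segment of {L} samples is too short")
    leads = {name: np.asarray(record.leads[name], dtype=float)[start:stop]
             for name in LEAD_NAMES}
    return SegmentedECG(leads=leads, segment_length=L, fs=record.fs,
                        record_id=record.record_id)


# ---------------------------------------------------------------------------
# Spectral transform and inverse
# ---------------------------------------------------------------------------

def _amp_scale(L: int) -> np.ndarray:
    """Per-bin scaling so a unit sinusoid yields bin amplitude ~1 mV."""
    nb = L // 2 + 1
    s = np.full(nb, 2.0 / L)
    s[0] = 1.0 / L
    if L % 2 == 0:
        s[-1] = 1.0 / L
    return s


def spectral_transform(
    x: np.ndarray, fs: float, lowpass_hz: float = 50.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Real-input DFT -> (amplitude, phase, frequencies) on the retained grid.

    Amplitude uses 2/L scaling (1/L at DC and Nyquist); bins with frequency
    <= ``lowpass_hz`` are retained: B = floor(lowpass * L / fs) + 1.
    """
    x = np.asarray(x, dtype=float)
    L = x.shape[-1]
    if L < 2:
        raise ValueError("degenerate segment")
    coef = np.fft.rfft(x, axis=-1)
    B = int(np.floor(lowpass_hz * L / fs)) + 1
    B = min(B, coef.shape[-1])
    amp = np.abs(coef[..., :B]) * _amp_scale(L)[:B]
    phase = np.angle(coef[..., :B])
    freqs = np.arange(B) * fs / L
    return amp, phase, freqs


def inverse_spectral(
    amp: np.ndarray, phase: np.ndarray, L: int, fs: float
) -> np.ndarray:
    """Invert :func:`spectral_transform`: rebuild the low-passed signal.

    Bins above the retained band are treated as zero, so the output is the
    50 Hz low-passed segment, not the raw one.
    """
    amp = np.asarray(amp, dtype=float)
    B = amp.shape[-1]
    nb = L // 2 + 1
    scale = _amp_scale(L)[:B]
    coef = np.zeros(amp.shape[:-1] + (nb,), dtype=complex)
    coef[..., :B] = amp / scale * np.exp(1j * np.asarray(phase))
    return np.fft.irfft(coef, n=L, axis=-1)


def cabrera_reorder(per_lead: dict[str, np.ndarray],
                    order: Sequence[str] = CABRERA_ORDER) -> np.ndarray:
    """Stack per-lead data into Cabrera order; the '-aVR' row is negated.

    A pure permutation with one sign flip, hence invertible
    (:func:`cabrera_restore`).
    """
    rows = []
    for name in order:
        neg = name.startswith("-")
        key = name[1:] if neg else name
        if key not in per_lead:
            raise KeyError(f"missing lead {key!r}")
        row = np.asarray(per_lead[key], dtype=float)
        rows.append(-row if neg else row)
    return np.stack(rows)


def cabrera_restore(data: np.ndarray,
                    order: Sequence[str] = CABRERA_ORDER) -> dict[str, np.ndarray]:
    """Inverse of :func:`cabrera_reorder`."""
    out = {}
    for i, name in enumerate(order):
        neg = name.startswith("-")
        key = name[1:] if neg else name
        out[key] = -data[i] if neg else data[i]
    return out


def resize_spectrum(
    amp: np.ndarray, phase: np.ndarray, src_freqs: np.ndarray,
    n_freq_bins: int = 400, fmax: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate spectra onto ``n_freq_bins`` bins over [0, fmax].

    Amplitude is interpolated directly; phase is interpolated on the
    unwrapped phase and rewrapped to (-pi, pi]. When the source grid is
    denser than the target, values are interpolated at the target
    frequencies (not averaged).
    """
    src_freqs = np.asarray(src_freqs, dtype=float)
    if src_freqs.shape[-1] < 2:
        raise ValueError("need at least 2 source bins to resize")
    target = np.linspace(0.0, fmax, n_freq_bins)
    amp = np.asarray(amp, dtype=float)
    was_1d = amp.ndim == 1
    amp2 = np.atleast_2d(amp)
    phase2 = np.atleast_2d(np.asarray(phase, dtype=float))
    amp_out = np.stack([np.interp(target, src_freqs, row) for row in amp2])
    ph_out = np.stack([
        _wrap_phase(np.interp(target, src_freqs, np.unwrap(row))) for row in phase2
    ])
    if was_1d:
        amp_out, ph_out = amp_out[0], ph_out[0]
    return amp_out, ph_out, target


def _wrap_phase(p: np.ndarray) -> np.ndarray:
    out = np.mod(p + np.pi, 2 * np.pi) - np.pi
    out[out == -np.pi] = np.pi
    return out


def build_meta_vector(record: ECGRecord) -> np.ndarray:
    """(age/18, sex code); male = 1, female = 0."""
    return np.array([record.age_years / 18.0, 1.0 if record.sex == "male" else 0.0])


def build_input_tensor(
    record: ECGRecord, cfg: Optional[PreprocessConfig] = None
) -> tuple[SpectralTensor, np.ndarray]:
    """Full chain: detect -> extract -> Cabrera -> FFT -> low-pass -> resize."""
    cfg = (cfg or PreprocessConfig()).validate()
    record.validate()
    ann = detect_qrs(record, cfg)
    seg = extract_segment(record, ann)
    mat = cabrera_reorder(seg.leads, cfg.cabrera_order)   # (12, L), time domain
    amp_b, phase_b, freqs = spectral_transform(mat, seg.fs, cfg.lowpass_hz)
    amp, phase, _ = resize_spectrum(amp_b, phase_b, freqs, cfg.n_freq_bins, cfg.lowpass_hz)
    tensor = SpectralTensor(
        values=np.stack([amp, phase]),
        segment_length=seg.segment_length,
        fs=seg.fs,
        lowpass_hz=cfg.lowpass_hz,
        n_bins_retained=amp_b.shape[-1],
        amp_b=amp_b,
        phase_b=phase_b,
        record_id=record.record_id,
    ).validate()
    return tensor, build_meta_vector(record)


def tensorize(
    records: Sequence[ECGRecord], cfg: Optional[PreprocessConfig] = None
) -> tuple[list[SpectralTensor], np.ndarray]:
    """Tensorize a cohort; returns the tensors and the (N, 2) meta matrix."""
    cfg = (cfg or PreprocessConfig()).validate()
    tensors, metas = [], []
    for rec in records:
        t, m = build_input_tensor(rec, cfg)
        tensors.append(t)
        metas.append(m)
    return tensors, np.asarray(metas)


def stack_tensors(tensors: Sequence[SpectralTensor]) -> np.ndarray:
    """Stack into the model's (N, 2, 12, 400) float32 input array."""
    return np.stack([t.values for t in tensors]).astype(np.float32)


class SpectralTensorizer:
    """Scikit-learn style transformer from ECG records to spectral tensors.

    ``transform`` accepts a sequence of :class:`~pediscreen.io.ECGRecord`
    and returns the stacked (N, 2, 12, 400) tensor array; ``transform_meta``
    returns the (N, 2) age/sex matrix. Stateless: ``fit`` only validates
    the configuration.
    """

    def __init__(self, fs: float = 500.0, lowpass_hz: float = 50.0,
                 n_freq_bins: int = 400, detector_lead: str = "II"):
        self.fs = fs
        self.lowpass_hz = lowpass_hz
        self.n_freq_bins = n_freq_bins
        self.detector_lead = detector_lead

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(fs=self.fs, lowpass_hz=self.lowpass_hz,
                                n_freq_bins=self.n_freq_bins,
                                detector_lead=self.detector_lead).validate()

    def get_params(self, deep: bool = True) -> dict:
        return {"fs": self.fs, "lowpass_hz": self.lowpass_hz,
                "n_freq_bins": self.n_freq_bins, "detector_lead": self.detector_lead}

    def set_params(self, **params) -> "SpectralTensorizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: Sequence[ECGRecord], y=None) -> "SpectralTensorizer":
        self._config()
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[ECGRecord]) -> np.ndarray:
        tensors, _ = tensorize(X, self._config())
        return stack_tensors(tensors)

    def transform_meta(self, X: Sequence[ECGRecord]) -> np.ndarray:
        return np.asarray([build_meta_vector(r) for r in X])

    def fit_transform(self, X: Sequence[ECGRecord], y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
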