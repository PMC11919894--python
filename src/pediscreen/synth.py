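"""Synthetic pediatric 12-lead ECG cohorts with injectable abnormalities.

The beat model is a sum of Gaussian wavelets (P, Q, R, S, T, plus optional
extras such as an rsR' secondary wave or a delta wave) riding on a rotating
cardiac dipole. Each wavelet carries a frontal-plane and a horizontal-plane
angle; the six limb leads are cosine projections of the dipole in the
frontal plane (with the augmented leads derived from Einthoven's triangle,
so II = I + III and aVR = -(I + II)/2 hold by construction) and the chest
leads V1..V6 are attenuated cosine projections in the horizontal plane.

Abnormalities are injected by deforming the wavelet parameters: axis
deviation rotates the QRS wavelets, complete/incomplete RBBB widens the QRS
and adds a rightward-anterior R', hypertrophies scale voltages toward V1 or
V5/V6, WPW shortens PR and adds a delta wave, Brugada adds a right-precordial
coved ST hump, ST-T abnormality shifts the ST segment and flattens/inverts
the T wave, SVT and third-degree AV block alter the rhythm (rate, P-wave
dissociation), and PVC replaces every k-th beat with a wide ectopic complex.
All deformations scale monotonically with a severity in [0, 1].

Records carry simulator ground truth (R-peak sample indices and QRS
onset/offset windows) so detectors and saliency maps can be scored against
a known answer.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ECGRecord, DatasetManifest, FINDING_VOCAB

FRONTAL_LEAD_ANGLES = {"I": 0.0, "II": 60.0, "III": 120.0}
CHEST_LEAD_ANGLES = {"V1": -60.0, "V2": -40.0, "V3": -20.0,
                     "V4": 0.0, "V5": 20.0, "V6": 40.0}
CHEST_GAIN = 0.8  # shared attenuation of the horizontal-plane projection

ABNORMAL_CODES = tuple(sorted(FINDING_VOCAB))


@dataclass
class Wave:
    """One Gaussian wavelet of the dipole trajectory.

    ``t_offset`` is relative to the R peak (s), ``width`` the Gaussian sigma
    (s), ``mag`` the dipole magnitude (mV), and the two angles locate the
    dipole direction in the frontal and horizontal planes (degrees).
    ``qrs`` marks wavelets belonging to the ventricular depolarization
    complex (these define QRS onset/offset and follow axis rotations).
    """

    t_offset: float
    width: float
    mag: float
    frontal_deg: float
    horizontal_deg: float
    qrs: bool = False


@dataclass
class DipoleParams:
    """Full parameter set of the beat simulator for one record."""

    heart_rate_bpm: float = 90.0
    rr_jitter_sd: float = 0.04          # fraction of the RR interval
    waves: dict[str, Wave] = field(default_factory=dict)
    extras: list[Wave] = field(default_factory=list)
    baseline_noise_sd: float = 0.02     # mV, white, per lead
    pr_interval_s: float = 0.16
    qrs_width_scale: float = 1.0
    st_shift_mv: float = 0.0
    t_scale: float = 1.0
    p_scale: float = 1.0
    p_dissociated_rate_bpm: Optional[float] = None  # AV dissociation
    pvc_every_k: Optional[int] = None               # ectopic interleave period

    def validate(self) -> "DipoleParams":
        if not (50.0 <= self.heart_rate_bpm <= 220.0):
            raise ValueError(f"heart_rate_bpm {self.heart_rate_bpm} outside [50, 220]")
        for name, w in self.waves.items():
            if w.width <= 0:
                raise ValueError(f"wave {name}: width must be positive")
            if not (-180.0 < w.frontal_deg <= 180.0 and -180.0 < w.horizontal_deg <= 180.0):
                raise ValueError(f"wave {name}: angles must lie in (-180, 180]")
        if self.qrs_width_scale <= 0:
            raise ValueError("qrs_width_scale must be positive")
        return self


def normal_template(heart_rate_bpm: float = 90.0) -> DipoleParams:
    """Normal pediatric beat: narrow QRS at ~60 deg frontal axis."""
    waves = {
        "P": Wave(-0.16, 0.022, 0.12, 60.0, 0.0),
        "Q": Wave(-0.016, 0.008, -0.08, 60.0, 15.0, qrs=True),
        "R": Wave(0.0, 0.010, 1.10, 60.0, 15.0, qrs=True),
        "S": Wave(0.020, 0.009, -0.22, 60.0, -70.0, qrs=True),
        "T": Wave(0.28, 0.055, 0.30, 45.0, 20.0),
    }
    return DipoleParams(heart_rate_bpm=heart_rate_bpm, waves=waves)


def age_to_heart_rate(age_years: float) -> float:
    """Linear pediatric schedule: resting HR falls ~4 bpm per year of age."""
    return 120.0 - 4.0 * (age_years - 6.0)


@dataclass(frozen=True)
class AbnormalitySpec:
    code: str
    severity: float = 1.0

    def __post_init__(self) -> None:
        if self.code != "normal" and self.code not in FINDING_VOCAB:
            raise ValueError(f"unknown finding code {self.code!r}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError("severity must lie in [0, 1]")


def _wrap_angle(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def inject_abnormality(params: DipoleParams, spec: AbnormalitySpec) -> DipoleParams:
    """Deform a normal beat template toward one guideline abnormality.

    Deformations are monotone in ``spec.severity``; severity 0 returns the
    parameters unchanged.
    """
    s = float(spec.severity)
    p = copy.deepcopy(params)
    if spec.code == "normal" or s == 0.0:
        return p
    if spec.code == "axis_dev":
        for w in list(p.waves.values()) + p.extras:
            if w.qrs:
                w.frontal_deg = _wrap_angle(w.frontal_deg + 90.0 * s)
    elif spec.code == "crbbb":
        p.qrs_width_scale *= 1.0 + 0.40 * s
        p.extras.append(Wave(0.050, 0.018, 0.90 * s, 150.0, -60.0, qrs=True))
    elif spec.code == "irbbb":
        p.qrs_width_scale *= 1.0 + 0.15 * s
        p.extras.append(Wave(0.035 + 0.010 * s, 0.012, 0.50 * s, 150.0, -60.0, qrs=True))
    elif spec.code == "rvh":
        p.extras.append(Wave(0.0, 0.010, 1.20 * s, 120.0, -60.0, qrs=True))
    elif spec.code == "lvh":
        p.waves["R"].mag *= 1.0 + 1.2 * s
        p.waves["S"].mag *= 1.0 + 1.2 * s
    elif spec.code == "st_t":
        p.st_shift_mv += -0.25 * s
        p.t_scale *= 1.0 - 1.6 * s
    elif spec.code == "brugada":
        p.extras.append(Wave(0.070, 0.035, 0.45 * s, 30.0, -55.0))
    elif spec.code == "wpw":
        p.pr_interval_s -= 0.06 * s
        p.qrs_width_scale *= 1.0 + 0.10 * s
        p.extras.append(Wave(-0.030, 0.016, 0.50 * s, 60.0, 0.0, qrs=True))
    elif spec.code == "svt":
        p.heart_rate_bpm = 185.0 + 35.0 * s
        p.rr_jitter_sd = 0.01
        p.p_scale *= 0.3
    elif spec.code == "avb3":
        p.heart_rate_bpm = 55.0 - 5.0 * s
        p.p_dissociated_rate_bpm = 95.0
    elif spec.code == "pvc":
        p.pvc_every_k = max(2, int(round(8.0 - 6.0 * s)))
    else:  # pragma: no cover - vocabulary is closed above
        raise ValueError(f"unknown finding code {spec.code!r}")
    return p


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

_ECTOPIC_WAVES = (
    Wave(0.0, 0.030, 1.60, -30.0, -40.0, qrs=True),
    Wave(0.055, 0.022, -0.50, -30.0, -40.0, qrs=True),
    Wave(0.30, 0.060, -0.40, -30.0, -20.0),
)


def _beat_waves(params: DipoleParams, ectopic: bool) -> list[Wave]:
    if ectopic:
        return list(_ECTOPIC_WAVES)
    waves = []
    for name, w in params.waves.items():
        w = replace(w)
        if name == "P":
            if params.p_dissociated_rate_bpm is not None:
                continue  # P train generated independently
            w.t_offset = -params.pr_interval_s
            w.mag *= params.p_scale
        if name == "T":
            w.mag *= params.t_scale
        if w.qrs:
            w.width *= params.qrs_width_scale
        waves.append(w)
    for w in params.extras:
        w = replace(w)
        if w.qrs:
            w.width *= params.qrs_width_scale
        waves.append(w)
    if params.st_shift_mv != 0.0:
        waves.append(Wave(0.10, 0.040, params.st_shift_mv, 55.0, 10.0))
    return waves


def _qrs_window(waves: Sequence[Wave]) -> tuple[float, float]:
    onset = min(w.t_offset - 2.5 * w.width for w in waves if w.qrs)
    offset = max(w.t_offset + 2.5 * w.width for w in waves if w.qrs)
    return onset, offset


def _add_wave(limb: dict, chest: dict, t: np.ndarray, center: float, w: Wave) -> None:
    lo = np.searchsorted(t, center + w.t_offset - 5.0 * w.width)
    hi = np.searchsorted(t, center + w.t_offset + 5.0 * w.width)
    if hi <= lo:
        return
    g = w.mag * np.exp(-((t[lo:hi] - center - w.t_offset) ** 2) / (2.0 * w.width ** 2))
    ch = math.cos(math.radians(w.horizontal_deg))
    for name, alpha in FRONTAL_LEAD_ANGLES.items():
        limb[name][lo:hi] += ch * math.cos(math.radians(w.frontal_deg - alpha)) * g
    for name, phi in CHEST_LEAD_ANGLES.items():
        chest[name][lo:hi] += CHEST_GAIN * math.cos(math.radians(w.horizontal_deg - phi)) * g


def generate_record(
    params: DipoleParams,
    age_years: int,
    sex: str,
    seed: int,
    record_id: str = "synth",
    patient_id: Optional[str] = None,
    fs: float = 500.0,
    duration_s: float = 10.0,
    findings: Optional[set[str]] = None,
) -> ECGRecord:
    """Synthesize one 12-lead record from dipole parameters.

    Deterministic given ``(params, seed)``. The returned record carries the
    true R-peak sample indices and QRS windows as simulator ground truth.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    limb = {name: np.zeros(n) for name in FRONTAL_LEAD_ANGLES}
    chest = {name: np.zeros(n) for name in CHEST_LEAD_ANGLES}

    rr0 = 60.0 / params.heart_rate_bpm
    beat_times: list[float] = []
    tb = 0.25 * rr0 + 0.1
    while tb < duration_s + 0.4:
        beat_times.append(tb)
        jit = np.clip(rng.normal(0.0, params.rr_jitter_sd), -0.3, 0.3)
        tb += rr0 * (1.0 + jit)

    r_true: list[int] = []
    qrs_windows: list[tuple[int, int]] = []
    for i, center in enumerate(beat_times):
        ectopic = params.pvc_every_k is not None and i >= 2 and (i % params.pvc_every_k) == 0
        waves = _beat_waves(params, ectopic)
        for w in waves:
            _add_wave(limb, chest, t, center, w)
        idx = int(round(center * fs))
        if 0 <= idx < n:
            r_true.append(idx)
            onset, offset = _qrs_window(waves)
            qrs_windows.append((
                max(0, int(round((center + onset) * fs))),
                min(n - 1, int(round((center + offset) * fs))),
            ))

    if params.p_dissociated_rate_bpm is not None:
        pw = params.waves["P"]
        rrp = 60.0 / params.p_dissociated_rate_bpm
        tp = 0.3 + rng.uniform(0, rrp)
        while tp < duration_s + 0.2:
            _add_wave(limb, chest, t, tp, replace(pw, t_offset=0.0, mag=pw.mag * params.p_scale))
            tp += rrp * (1.0 + np.clip(rng.normal(0.0, 0.03), -0.2, 0.2))

    leads = {
        "I": limb["I"],
        "II": limb["II"],
        "III": limb["III"],
        "aVR": -(limb["I"] + limb["II"]) / 2.0,
        "aVL": (limb["I"] - limb["III"]) / 2.0,
        "aVF": (limb["II"] + limb["III"]) / 2.0,
    }
    leads.update(chest)

    if params.baseline_noise_sd > 0:
        drift_amp = 2.0 * params.baseline_noise_sd
        for name in leads:
            noise = rng.normal(0.0, params.baseline_noise_sd, n)
            phase = rng.uniform(0, 2 * np.pi)
            freq = rng.uniform(0.15, 0.4)
            leads[name] = leads[name] + noise + drift_amp * np.sin(2 * np.pi * freq * t + phase)

    record = ECGRecord(
        record_id=record_id,
        patient_id=patient_id or record_id,
        leads=leads,
        age_years=int(age_years),
        sex=sex,
        findings=set(findings or set()),
        fs=fs,
        duration_s=duration_s,
        r_true=r_true,
        qrs_windows=qrs_windows,
    )
    return record.validate()


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

#: Abnormal-finding mixture, proportional to the test-group prevalence of
#: each finding in the screening cohort the simulator emulates.
DEFAULT_FINDING_WEIGHTS: dict[str, float] = {
    "st_t": 51, "crbbb": 17, "axis_dev": 16, "rvh": 11, "lvh": 5,
    "irbbb": 9, "pvc": 3, "wpw": 1, "svt": 8, "brugada": 1, "avb3": 4,
}


@dataclass
class CohortSpec:
    """Conditions of a simulated screening cohort."""

    n_records: int
    abnormal_fraction: float = 0.27
    finding_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FINDING_WEIGHTS))
    age_range: tuple[int, int] = (6, 18)
    severity_range: tuple[float, float] = (0.7, 1.0)
    noise_sd: float = 0.02
    repeat_prob: float = 0.35   # chance a patient contributes a second ECG
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_records < 2:
            raise ValueError("n_records must be at least 2")
        if not (0.0 <= self.abnormal_fraction <= 1.0):
            raise ValueError("abnormal_fraction must lie in [0, 1]")
        if any(w < 0 for w in self.finding_weights.values()) or \
                sum(self.finding_weights.values()) <= 0:
            raise ValueError("finding weights must be non-negative with positive sum")
        unknown = set(self.finding_weights) - FINDING_VOCAB
        if unknown:
            raise ValueError(f"unknown finding(s) in weights: {sorted(unknown)}")
        return self


def sample_cohort(spec: CohortSpec) -> tuple[list[ECGRecord], DatasetManifest]:
    """Draw a labeled cohort; deterministic given ``spec.seed``.

    The abnormal fraction is respected to within rounding; ages are uniform
    over the range with heart rate following the age schedule (with 10%
    jitter); a patient may contribute two ECGs of the same label class.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    n_ab = int(round(spec.abnormal_fraction * n))
    codes = sorted(spec.finding_weights)
    weights = np.array([spec.finding_weights[c] for c in codes], dtype=float)
    weights /= weights.sum()
    planned: list[Optional[str]] = list(rng.choice(codes, size=n_ab, p=weights))
    planned += [None] * (n - n_ab)
    rng.shuffle(planned)

    records: list[ECGRecord] = []
    rows: list[dict] = []
    i = 0
    pnum = 0
    while i < n:
        pnum += 1
        patient_id = f"P{pnum:05d}"
        age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
        sex = "male" if rng.random() < 0.55 else "female"
        # a repeat visit shares the patient's finding (same child, same heart)
        k = 2 if (spec.repeat_prob > 0 and i + 1 < n
                  and planned[i + 1] == planned[i]
                  and rng.random() < spec.repeat_prob) else 1
        for j in range(k):
            code = planned[i]
            hr = age_to_heart_rate(age) * (1.0 + rng.uniform(-0.1, 0.1))
            params = normal_template(heart_rate_bpm=float(np.clip(hr, 55.0, 180.0)))
            params.baseline_noise_sd = spec.noise_sd
            severity = 0.0
            if code is not None:
                severity = float(rng.uniform(*spec.severity_range))
                params = inject_abnormality(params, AbnormalitySpec(code, severity))
            rec_seed = int(rng.integers(0, 2**31 - 1))
            record = generate_record(
                params, age, sex, seed=rec_seed,
                record_id=f"R{i + 1:05d}", patient_id=patient_id,
                findings={code} if code else set(),
            )
            records.append(record)
            rows.append({
                "record_id": record.record_id,
                "patient_id": patient_id,
                "age_years": age,
                "sex": sex,
                "findings": record.findings,
                "comparator_flag": pd.NA,
                "path": "",
            })
            i += 1
    manifest = DatasetManifest.from_rows(rows)
    return records, manifest


# ---------------------------------------------------------------------------
# Waveform measurements and the toy rule-based comparator
# ---------------------------------------------------------------------------

def measure_features(record: ECGRecord) -> dict[str, float]:
    """Rule-oriented measurements: heart rate, QRS width, frontal axis,
    V1/V6 R amplitude, and ST deviation.

    Uses simulator ground-truth R indices when present, otherwise runs the
    QRS detector. These measurements feed the toy comparator and the
    separability checks; they are never ground truth.
    """
    fs = record.fs
    if record.r_true:
        r_idx = list(record.r_true)
    else:
        from .preprocess import detect_qrs
        r_idx = list(detect_qrs(record).r_sample_indices)
    n = record.n_samples
    leads = {name: np.asarray(record.leads[name], dtype=float) for name in record.leads}

    if len(r_idx) >= 2:
        rr = np.diff(r_idx) / fs
        hr = 60.0 / float(np.median(rr))
    else:
        hr = float("nan")

    env = np.maximum.reduce([np.abs(leads["II"]), np.abs(leads["V1"]), np.abs(leads["V6"])])
    widths, axes_x, axes_y, v1_rs, v6_rs, sts = [], [], [], [], [], []
    for r in r_idx:
        lo = max(0, r - int(0.10 * fs))
        hi = min(n, r + int(0.18 * fs))
        if hi - lo < int(0.1 * fs):
            continue
        win = env[lo:hi]
        thr = 0.15 * float(win.max())
        above = np.flatnonzero(win > thr)
        if len(above) == 0:
            continue
        widths.append((above[-1] - above[0]) / fs)
        qlo, qhi = lo + above[0], lo + above[-1] + 1
        a_i = float(np.sum(leads["I"][qlo:qhi]))
        a_avf = float(np.sum(leads["aVF"][qlo:qhi]))
        # hexaxial correction: aVF projections carry a sqrt(3)/2 factor
        ax = math.degrees(math.atan2(a_avf * 2.0 / math.sqrt(3.0), a_i))
        axes_x.append(math.cos(math.radians(ax)))
        axes_y.append(math.sin(math.radians(ax)))
        v1_rs.append(float(leads["V1"][qlo:qhi].max()))
        v6_rs.append(float(leads["V6"][qlo:qhi].max()))
        blo, bhi = max(0, r - int(0.07 * fs)), max(1, r - int(0.05 * fs))
        slo, shi = min(n - 2, r + int(0.09 * fs)), min(n - 1, r + int(0.13 * fs))
        st = max(
            abs(float(np.mean(leads[name][slo:shi]) - np.mean(leads[name][blo:bhi])))
            for name in ("II", "V1", "V2", "V5")
        )
        sts.append(st)
    axis = math.degrees(math.atan2(np.mean(axes_y), np.mean(axes_x))) if axes_x else float("nan")
    return {
        "heart_rate_bpm": hr,
        "qrs_width_s": float(np.median(widths)) if widths else float("nan"),
        "qrs_width_max_s": float(np.max(widths)) if widths else float("nan"),
        "frontal_axis_deg": axis,
        "v1_r_mv": float(np.median(v1_rs)) if v1_rs else float("nan"),
        "v6_r_mv": float(np.median(v6_rs)) if v6_rs else float("nan"),
        "st_dev_mv": float(np.median(sts)) if sts else float("nan"),
    }


def rule_based_comparator(records: Sequence[ECGRecord]) -> np.ndarray:
    """Toy conventional-algorithm stand-in: trips on any coarse rule.

    Thresholds sit close to normal variability, so the comparator is
    sensitive but unspecific, mimicking a conservative screening
    interpreter. Plumbing only — never a label source.
    """
    flags = []
    for rec in records:
        f = measure_features(rec)
        flag = (
            f["qrs_width_max_s"] > 0.0455
            or not (5.0 < f["frontal_axis_deg"] < 105.0)
            or f["v1_r_mv"] > 0.55
            or f["v6_r_mv"] > 1.25
            or f["st_dev_mv"] > 0.0215
            or f["heart_rate_bpm"] > 110.0
            or f["heart_rate_bpm"] < 57.0
        )
        flags.append(bool(flag))
    return np.asarray(flags, dtype=bool)
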