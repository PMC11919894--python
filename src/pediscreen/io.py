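"""Record and cohort I/O for 12-lead pediatric ECG screening.

An :class:`ECGRecord` holds a standard resting 10-s, 500 Hz, 12-lead ECG in
millivolts together with the demographics (age, sex) and the ground-truth
finding labels used for screening. Records are stored on disk either as a
CSV/JSON bundle (lossless, the native dialect) or as a minimal WFDB
format-16 ``.hea``/``.dat`` pair (signals quantized at 1 µV). Cohorts are
described by a TSV manifest, and the train/test split is performed at the
patient level so that repeat ECGs of one child never straddle the split.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Canonical lead names, in conventional (non-Cabrera) order.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Supported finding vocabulary (guideline-style screening abnormalities).
FINDING_VOCAB: frozenset[str] = frozenset({
    "st_t", "crbbb", "irbbb", "axis_dev", "rvh", "lvh",
    "wpw", "svt", "pvc", "brugada", "avb3",
})

SEXES = ("male", "female")

#: WFDB ADC gain used by the writer: 1000 ADC units per mV = 1 µV resolution.
WFDB_GAIN = 1000.0


class ECGFormatError(ValueError):
    """Raised when an on-disk record violates the 12-lead contract."""


@dataclass
class ECGRecord:
    """One 12-lead ECG with demographics and screening labels.

    ``leads`` maps each canonical lead name to a float vector in mV of
    length ``fs * duration_s``. ``findings`` is the (possibly empty) set of
    abnormal finding codes; a record is *abnormal* iff it is non-empty.
    ``r_true`` optionally carries simulator ground-truth R-peak sample
    indices, and ``qrs_windows`` the matching (onset, offset) sample pairs.
    """

    record_id: str
    patient_id: str
    leads: dict[str, np.ndarray]
    age_years: int
    sex: str
    findings: set[str] = field(default_factory=set)
    fs: float = 500.0
    duration_s: float = 10.0
    r_true: Optional[list[int]] = None
    qrs_windows: Optional[list[tuple[int, int]]] = None

    @property
    def abnormal(self) -> bool:
        return len(self.findings) > 0

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def lead_matrix(self, order: Sequence[str] = LEAD_NAMES) -> np.ndarray:
        """Stack leads into a (12, n_samples) array in the given order."""
        return np.stack([np.asarray(self.leads[name], dtype=float) for name in order])

    def validate(self) -> "ECGRecord":
        missing = [name for name in LEAD_NAMES if name not in self.leads]
        if missing:
            raise ECGFormatError(f"record {self.record_id!r}: missing lead(s) {missing}")
        n = self.n_samples
        for name in LEAD_NAMES:
            x = np.asarray(self.leads[name], dtype=float)
            if x.ndim != 1 or len(x) != n:
                raise ECGFormatError(
                    f"record {self.record_id!r}: lead {name} has length {len(x)}, expected {n}"
                )
            if not np.all(np.isfinite(x)):
                raise ECGFormatError(
                    f"record {self.record_id!r}: lead {name} contains non-finite samples"
                )
        if self.sex not in SEXES:
            raise ECGFormatError(f"record {self.record_id!r}: sex must be one of {SEXES}")
        if not (1 <= int(self.age_years) <= 120):
            raise ECGFormatError(f"record {self.record_id!r}: implausible age {self.age_years}")
        unknown = set(self.findings) - FINDING_VOCAB
        if unknown:
            raise ECGFormatError(f"record {self.record_id!r}: unknown finding(s) {sorted(unknown)}")
        return self


# ---------------------------------------------------------------------------
# CSV/JSON bundle dialect
# ---------------------------------------------------------------------------

def _bundle_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return base.with_suffix(".json"), base.with_suffix(".csv")


def _write_csvjson(record: ECGRecord, path: Path) -> Path:
    jpath, cpath = _bundle_paths(path)
    header = {
        "record_id": record.record_id,
        "patient_id": record.patient_id,
        "age_years": int(record.age_years),
        "sex": record.sex,
        "findings": sorted(record.findings),
        "fs": record.fs,
        "duration_s": record.duration_s,
    }
    if record.r_true is not None:
        header["r_true_samples"] = [int(i) for i in record.r_true]
    if record.qrs_windows is not None:
        header["qrs_windows"] = [[int(a), int(b)] for a, b in record.qrs_windows]
    jpath.write_text(json.dumps(header, indent=1))
    with open(cpath, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LEAD_NAMES)
        mat = record.lead_matrix().T  # samples x 12
        for row in mat:
            writer.writerow([repr(float(v)) for v in row])
    return jpath


def _read_csvjson(path: Path) -> ECGRecord:
    jpath, cpath = _bundle_paths(path)
    if not jpath.exists():
        raise ECGFormatError(f"missing JSON header {jpath}")
    if not cpath.exists():
        raise ECGFormatError(f"missing CSV signal file {cpath}")
    header = json.loads(jpath.read_text())
    with open(cpath, newline="") as fh:
        reader = csv.reader(fh)
        names = next(reader)
        rows = [[float(v) for v in row] for row in reader]
    mat = np.asarray(rows, dtype=float)
    missing = [name for name in LEAD_NAMES if name not in names]
    if missing:
        raise ECGFormatError(f"{cpath}: missing lead column(s) {missing}")
    leads = {name: np.ascontiguousarray(mat[:, names.index(name)]) for name in LEAD_NAMES}
    record = ECGRecord(
        record_id=header["record_id"],
        patient_id=header["patient_id"],
        leads=leads,
        age_years=int(header["age_years"]),
        sex=header["sex"],
        findings=set(header.get("findings", [])),
        fs=float(header.get("fs", 500.0)),
        duration_s=float(header.get("duration_s", 10.0)),
        r_true=header.get("r_true_samples"),
        qrs_windows=[tuple(w) for w in header["qrs_windows"]] if "qrs_windows" in header else None,
    )
    return record.validate()


# ---------------------------------------------------------------------------
# Minimal WFDB format-16 dialect
# ---------------------------------------------------------------------------
# Only the subset this package writes is supported: one .dat file, format 16
# (little-endian int16, sample-interleaved), a fixed gain, zero baseline.

def _write_wfdb(record: ECGRecord, path: Path) -> Path:
    base = path.with_suffix("")
    hea, dat = base.with_suffix(".hea"), base.with_suffix(".dat")
    mat = record.lead_matrix()
    adc = np.round(mat * WFDB_GAIN)
    if np.any(np.abs(adc) > 32767):
        raise ECGFormatError(f"record {record.record_id!r}: amplitude exceeds WFDB int16 range")
    adc = adc.astype("<i2")
    lines = [f"{base.name} {len(LEAD_NAMES)} {record.fs:g} {record.n_samples}"]
    for i, name in enumerate(LEAD_NAMES):
        first = int(adc[i, 0])
        cksum = int(np.sum(adc[i].astype(np.int64)) % 65536)
        lines.append(f"{dat.name} 16 {WFDB_GAIN:g}/mV 16 0 {first} {cksum} 0 {name}")
    lines.append(f"# record_id {record.record_id}")
    lines.append(f"# patient_id {record.patient_id}")
    lines.append(f"# age_years {int(record.age_years)}")
    lines.append(f"# sex {record.sex}")
    lines.append("# findings " + ",".join(sorted(record.findings)))
    hea.write_text("\n".join(lines) + "\n")
    dat.write_bytes(adc.T.tobytes())  # sample-major interleave
    return hea


def _read_wfdb(path: Path) -> ECGRecord:
    base = path.with_suffix("")
    hea, dat = base.with_suffix(".hea"), base.with_suffix(".dat")
    if not hea.exists():
        raise ECGFormatError(f"missing header {hea}")
    lines = hea.read_text().strip().splitlines()
    rec_line = lines[0].split()
    nsig, fs, nsamp = int(rec_line[1]), float(rec_line[2]), int(rec_line[3])
    sig_lines = lines[1 : 1 + nsig]
    names, gains = [], []
    for line in sig_lines:
        parts = line.split()
        gains.append(float(parts[2].split("/")[0]))
        names.append(parts[-1])
    meta = {"record_id": base.name, "patient_id": base.name, "age_years": 10,
            "sex": "male", "findings": ""}
    for line in lines[1 + nsig:]:
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition(" ")
            meta[key] = value
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if len(raw) != nsig * nsamp:
        raise ECGFormatError(f"{dat}: expected {nsig * nsamp} samples, found {len(raw)}")
    mat = raw.reshape(nsamp, nsig).T.astype(float)
    leads = {name: mat[i] / gains[i] for i, name in enumerate(names)}
    missing = [name for name in LEAD_NAMES if name not in leads]
    if missing:
        raise ECGFormatError(f"{hea}: missing lead(s) {missing}")
    findings = set(meta["findings"].split(",")) - {""}
    record = ECGRecord(
        record_id=meta["record_id"],
        patient_id=meta["patient_id"],
        leads={name: leads[name] for name in LEAD_NAMES},
        age_years=int(meta["age_years"]),
        sex=meta["sex"],
        findings=findings,
        fs=fs,
        duration_s=nsamp / fs,
    )
    return record.validate()


def write_record(record: ECGRecord, path, format: str = "csvjson") -> Path:
    """Write a validated record; ``csvjson`` is lossless, ``wfdb`` quantizes at 1 µV."""
    record.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csvjson":
        return _write_csvjson(record, path)
    if format == "wfdb":
        return _write_wfdb(record, path)
    raise ValueError(f"unknown format {format!r}")


def read_record(path, format: str = "csvjson") -> ECGRecord:
    """Read a record written by :func:`write_record` and validate it."""
    path = Path(path)
    if format == "csvjson":
        return _read_csvjson(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Manifest and split
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("record_id", "patient_id", "age_years", "sex",
                    "findings", "comparator_flag", "path")


@dataclass
class DatasetManifest:
    """Cohort bookkeeping: one row per ECG record.

    ``comparator_flag`` houses the verdict of a conventional rule-based
    interpreter, consumed as data (it is never ground truth).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing column(s) {sorted(missing)}")
        if self.table["record_id"].duplicated().any():
            dup = self.table.loc[self.table["record_id"].duplicated(), "record_id"].iloc[0]
            raise ValueError(f"duplicate record_id {dup!r}")
        bad = [f for fl in self.table["findings"] for f in _split_findings(fl)
               if f not in FINDING_VOCAB]
        if bad:
            raise ValueError(f"unknown finding(s) {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["patient_id"]))

    def findings_of(self, record_id: str) -> set[str]:
        row = self.table.loc[self.table["record_id"] == record_id]
        return set(_split_findings(row["findings"].iloc[0]))

    def abnormal_labels(self) -> np.ndarray:
        return np.array([len(_split_findings(f)) > 0 for f in self.table["findings"]], dtype=bool)

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "DatasetManifest":
        df = pd.DataFrame(rows)
        for col in MANIFEST_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col != "comparator_flag" else pd.NA
        df["findings"] = [
            ",".join(sorted(f)) if isinstance(f, (set, frozenset, list, tuple)) else str(f or "")
            for f in df["findings"]
        ]
        return cls(df[list(MANIFEST_COLUMNS)].copy())

    def write_tsv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read_tsv(cls, path) -> "DatasetManifest":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"manifest not found: {path}")
        df = pd.read_csv(path, sep="\t", dtype={"record_id": str, "patient_id": str})
        df["findings"] = df["findings"].fillna("")
        df["path"] = df["path"].fillna("")
        return cls(df[list(MANIFEST_COLUMNS)].copy())


def _split_findings(s) -> list[str]:
    if not isinstance(s, str) or not s:
        return []
    return [f for f in s.split(",") if f]


@dataclass(frozen=True)
class Split:
    """Patient-level partition of a cohort into training and test groups."""

    train_patient_ids: frozenset[str]
    test_patient_ids: frozenset[str]
    train_fraction: float
    seed: int

    def record_mask(self, manifest: DatasetManifest, group: str = "train") -> np.ndarray:
        ids = self.train_patient_ids if group == "train" else self.test_patient_ids
        return manifest.table["patient_id"].isin(ids).to_numpy()


def patient_level_split(manifest: DatasetManifest, train_fraction: float, seed: int) -> Split:
    """Randomly assign whole patients to train/test groups.

    The train patient count is ``round-half-up(train_fraction * n_patients)``;
    all ECGs of one patient land in the same group. Deterministic given seed.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    patients = sorted(set(manifest.table["patient_id"]))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    n_train = int(math.floor(train_fraction * len(patients) + 0.5))
    n_train = min(max(n_train, 1), len(patients) - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    train = frozenset(patients[i] for i in order[:n_train])
    test = frozenset(patients[i] for i in order[n_train:])
    return Split(train, test, train_fraction, seed)
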