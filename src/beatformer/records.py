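"""ECG record containers, synthetic two-class cohort generation, and I/O.

A cohort is a list of :class:`EcgRecord` objects, one continuous trace per
subject with expert-style R-peak annotations.  The synthetic generator
emulates the shape of the real study material — 18 normal-sinus-rhythm
subjects recorded at 128 Hz and 15 congestive-heart-failure (CHF) subjects
at 250 Hz — using a sum-of-Gaussians beat morphology (P, Q, R, S, T waves).

The class contrast is placed in the T-wave amplitude and QRS width, with
between-subject parameter spread wide enough that the two classes overlap:
generalizing to unseen subjects (the inter-patient protocol) is then
meaningfully harder than memorizing subjects seen in training.

Real PhysioNet records can be read through :func:`read_wfdb_record` when the
optional ``wfdb`` package is installed; nothing else in the package depends
on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

LABELS = ("normal", "chf")


@dataclass
class EcgRecord:
    """One subject's continuous ECG trace with R-peak annotations.

    ``samples`` is the voltage trace in mV; ``r_peaks`` holds 0-based sample
    indices of the annotated R points, strictly increasing.
    """

    subject_id: str
    label: str
    fs: int
    samples: np.ndarray
    r_peaks: np.ndarray

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if self.samples.size < 1:
            raise ValueError("record must contain at least one sample")
        if self.r_peaks.size:
            if self.r_peaks.min() < 0 or self.r_peaks.max() >= self.samples.size:
                raise ValueError("r_peaks must index into samples")
            if np.any(np.diff(self.r_peaks) <= 0):
                raise ValueError("r_peaks must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-class cohort.

    Defaults mirror the real study material: 18 normal and 15 CHF subjects,
    2000 annotated beats each.  ``morphology_spread`` scales between-subject
    parameter variation; ``class_separation`` scales the normal-vs-CHF
    morphology offset (1.0 = calibrated default, 0.0 = identical classes).
    """

    n_normal_subjects: int = 18
    n_chf_subjects: int = 15
    beats_per_subject: int = 2000
    fs: int = 250
    master_seed: int = 0
    morphology_spread: float = 1.0
    class_separation: float = 1.0

    def __post_init__(self):
        if min(self.n_normal_subjects, self.n_chf_subjects,
               self.beats_per_subject) < 1:
            raise ValueError("subject and beat counts must be >= 1")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.morphology_spread < 0 or self.class_separation < 0:
            raise ValueError("spread parameters must be >= 0")


# Base beat morphology: per wave (amplitude mV, center offset from R in s,
# width in s).  Values give a plausible lead-II-like beat at 250 Hz.
_BASE_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, -0.180, 0.025),
    "Q": (-0.10, -0.026, 0.010),
    "R": (1.00, 0.000, 0.012),
    "S": (-0.25, 0.028, 0.011),
    "T": (0.35, 0.230, 0.060),
}

# Class-conditional morphology offsets, scaled by ``class_separation``:
# CHF beats get a flattened T wave, a broadened QRS complex and a slightly
# faster resting heart rate.
_CHF_T_AMP_FACTOR = 0.65        # T amplitude multiplier at separation 1
_CHF_QRS_WIDTH_FACTOR = 1.25    # Q/R/S width multiplier at separation 1
_HEART_RATE_BPM = {"normal": 72.0, "chf": 82.0}

# Between-subject relative spreads at morphology_spread 1.
_SUBJECT_AMP_SD = 0.10
_SUBJECT_WIDTH_SD = 0.08
_SUBJECT_CENTER_SD_S = 0.008
_SUBJECT_HR_SD_BPM = 8.0

# Beat-to-beat jitter and additive disturbances (always on).
_BEAT_AMP_SD = 0.03
_BEAT_WIDTH_SD = 0.02
_RR_JITTER_SD = 0.04
_SENSOR_NOISE_MV = 0.02
_BASELINE_WANDER_MV = 0.04

_LEAD_IN_S = 0.5                # >= 0.4 s before the first R peak
_LEAD_OUT_S = 0.75              # >= 0.6 s after the last R peak


def sample_subject_params(label: str, rng: np.random.Generator,
                          spec: CohortSpec) -> dict:
    """Draw one subject's morphology parameters from the class-conditional
    distributions.  Returned dict maps wave name -> (amp, center, width),
    plus ``heart_rate_bpm``."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    sep = spec.class_separation
    spread = spec.morphology_spread
    waves = {}
    for name, (amp, center, width) in _BASE_WAVES.items():
        if label == "chf":
            if name == "T":
                amp = amp * (1.0 + (_CHF_T_AMP_FACTOR - 1.0) * sep)
            if name in ("Q", "R", "S"):
                width = width * (1.0 + (_CHF_QRS_WIDTH_FACTOR - 1.0) * sep)
        amp = amp * (1.0 + _SUBJECT_AMP_SD * spread * rng.standard_normal())
        width = width * float(np.exp(_SUBJECT_WIDTH_SD * spread
                                     * rng.standard_normal()))
        center = center + _SUBJECT_CENTER_SD_S * spread * rng.standard_normal()
        waves[name] = (amp, center, width)
    hr = rng.normal(_HEART_RATE_BPM[label], _SUBJECT_HR_SD_BPM * spread)
    hr = float(np.clip(hr, 40.0, 140.0))
    return {"waves": waves, "heart_rate_bpm": hr}


def generate_subject(label: str, subject_seed: int, n_beats: int, fs: int,
                     spec: CohortSpec, subject_id: str | None = None) -> EcgRecord:
    """Synthesize one subject's annotated ECG record.

    The record carries exactly ``n_beats`` R-peak annotations and enough
    lead-in/lead-out that a 0.4 s / 0.6 s window around every R peak stays
    inside the trace.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    rng = np.random.default_rng(subject_seed)
    params = sample_subject_params(label, rng, spec)
    waves = params["waves"]
    rr_mean = 60.0 / params["heart_rate_bpm"]

    rr = rr_mean * (1.0 + _RR_JITTER_SD * rng.standard_normal(n_beats))
    rr = np.clip(rr, 0.4, 2.0)
    r_times = _LEAD_IN_S + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    n_samples = int(round((r_times[-1] + _LEAD_OUT_S) * fs))
    t = np.arange(n_samples) / fs
    x = np.zeros(n_samples)

    amp_jit = 1.0 + _BEAT_AMP_SD * rng.standard_normal((n_beats, len(waves)))
    width_jit = np.exp(_BEAT_WIDTH_SD * rng.standard_normal((n_beats, len(waves))))
    for b in range(n_beats):
        for w, (name, (amp, center, width)) in enumerate(waves.items()):
            a = amp * amp_jit[b, w]
            s = width * width_jit[b, w]
            c = r_times[b] + center
            lo = max(0, int((c - 4 * s) * fs))
            hi = min(n_samples, int((c + 4 * s) * fs) + 1)
            if lo >= hi:
                continue
            seg = t[lo:hi] - c
            x[lo:hi] += a * np.exp(-0.5 * (seg / s) ** 2)

    # slow baseline wander + broadband sensor noise
    for _ in range(2):
        f_w = rng.uniform(0.15, 0.35)
        phase = rng.uniform(0, 2 * np.pi)
        x += _BASELINE_WANDER_MV * np.sin(2 * np.pi * f_w * t + phase)
    x += _SENSOR_NOISE_MV * rng.standard_normal(n_samples)

    r_peaks = np.round(r_times * fs).astype(np.int64)
    if subject_id is None:
        subject_id = f"{label}_{subject_seed}"
    return EcgRecord(subject_id=subject_id, label=label, fs=fs,
                     samples=x, r_peaks=r_peaks)


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic, order-independent per-subject seed derived from the
    cohort master seed via a splittable NumPy SeedSequence."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


def generate_cohort(spec: CohortSpec) -> list[EcgRecord]:
    """Generate the full two-class cohort described by ``spec``.

    Subject IDs are ``normal01..`` and ``chf01..``; per-subject seeds are
    derived from ``master_seed`` so the cohort is bit-reproducible.
    """
    records = []
    idx = 0
    for label, count in (("normal", spec.n_normal_subjects),
                         ("chf", spec.n_chf_subjects)):
        for j in range(count):
            sid = f"{label}{j + 1:02d}"
            records.append(generate_subject(
                label, subject_seed(spec.master_seed, idx),
                spec.beats_per_subject, spec.fs, spec, subject_id=sid))
            idx += 1
    return records


def save_cohort(records: list[EcgRecord], out_dir) -> None:
    """Write one CSV (sample_index, amplitude_mV) plus a JSON sidecar
    (subject_id, label, fs, r_peaks) per subject."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        pd.DataFrame({
            "sample_index": np.arange(rec.samples.size),
            "amplitude_mV": rec.samples,
        }).to_csv(out / f"{rec.subject_id}.csv", index=False)
        meta = {"subject_id": rec.subject_id, "label": rec.label,
                "fs": rec.fs, "r_peaks": rec.r_peaks.tolist()}
        (out / f"{rec.subject_id}.json").write_text(json.dumps(meta))


def load_cohort(in_dir) -> list[EcgRecord]:
    src = Path(in_dir)
    records = []
    for meta_path in sorted(src.glob("*.json")):
        meta = json.loads(meta_path.read_text())
        df = pd.read_csv(src / f"{meta['subject_id']}.csv")
        records.append(EcgRecord(
            subject_id=meta["subject_id"], label=meta["label"],
            fs=int(meta["fs"]), samples=df["amplitude_mV"].to_numpy(),
            r_peaks=np.asarray(meta["r_peaks"], dtype=np.int64)))
    return records


def read_wfdb_record(path, channel: int = 0, label: str = "normal") -> EcgRecord:
    """Read a PhysioNet WFDB record (.hea/.dat/.atr triplet) as an EcgRecord.

    Requires the optional ``wfdb`` package.  R peaks are taken from the beat
    annotations; the chosen signal channel is returned in mV.
    """
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - depends on extra
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install beatformer[wfdb])") from exc
    path = str(path)
    rec = wfdb.rdrecord(path)
    if channel < 0 or channel >= rec.n_sig:
        raise ValueError(f"channel {channel} out of range (record has "
                         f"{rec.n_sig} channels)")
    try:
        ann = wfdb.rdann(path, "atr")
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"missing annotation file {path}.atr") from exc
    beat_mask = np.isin(ann.symbol, ["N", "L", "R", "V", "A", "a", "J", "S",
                                     "F", "e", "j", "E", "/", "f", "Q"])
    r_peaks = np.asarray(ann.sample)[beat_mask]
    if r_peaks.size == 0:
        raise ValueError(f"no R-peak annotations in {path}.atr")
    return EcgRecord(subject_id=Path(path).name, label=label,
                     fs=int(rec.fs), samples=rec.p_signal[:, channel],
                     r_peaks=r_peaks.astype(np.int64))
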