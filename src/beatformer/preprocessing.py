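"""Heartbeat preprocessing: resampling, R-centered segmentation, min-max
normalization, and additive white Gaussian noise (AWGN) injection.

The pipeline turns continuous annotated records into fixed-length training
beats: (1) resample every record to a common rate (250 Hz), (2) cut a
window from 0.4 s before each annotated R peak to 0.6 s after it — a
half-open window of exactly 250 samples at 250 Hz — and (3) rescale each
window to the [0, 1] interval, which removes per-beat amplitude scaling.

Noise-robustness experiments inject AWGN into the *raw* trace, before
resampling and normalization, at a prescribed signal-to-noise ratio
measured against the actual signal power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .records import EcgRecord, LABELS

TARGET_FS = 250
PRE_S = 0.4
POST_S = 0.6


@dataclass
class BeatSegment:
    """One fixed-length, normalized heartbeat window."""

    values: np.ndarray
    label: str
    subject_id: str
    source_r_peak: int


@dataclass(frozen=True)
class NoiseSpec:
    """AWGN at a given SNR in dB; ``snr_db=inf`` means no noise.

    The noise variance is set against the *measured* power of the signal the
    noise is added to (mean of squared amplitudes), not an assumed unit
    power.
    """

    snr_db: float
    rng_seed: int = 0

    def __post_init__(self):
        if math.isnan(self.snr_db):
            raise ValueError("snr_db must be finite or +inf")


def resample_record(record: EcgRecord, target_fs: int,
                    snap_r_peaks: bool = True) -> EcgRecord:
    """Resample a record to ``target_fs`` with an anti-aliased polyphase
    filter, rescaling the R-peak indices.

    Plain index rescaling can land the fiducial a sample or two off the true
    peak after filtering, so by default each rescaled R index is re-snapped
    to the local maximum within +/-3 samples (``snap_r_peaks=False`` keeps
    the strictly rescaled indices).
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == record.fs:
        return record
    frac = Fraction(target_fs, record.fs)
    samples = resample_poly(record.samples, frac.numerator, frac.denominator)
    r_peaks = np.round(record.r_peaks * (target_fs / record.fs)).astype(np.int64)
    r_peaks = np.clip(r_peaks, 0, samples.size - 1)
    if snap_r_peaks:
        snapped = np.empty_like(r_peaks)
        for i, r in enumerate(r_peaks):
            lo = max(0, r - 3)
            hi = min(samples.size, r + 4)
            snapped[i] = lo + int(np.argmax(samples[lo:hi]))
        # snapping must not reorder the fiducials; fall back if it would
        if snapped.size < 2 or np.all(np.diff(snapped) > 0):
            r_peaks = snapped
    return EcgRecord(subject_id=record.subject_id, label=record.label,
                     fs=target_fs, samples=samples, r_peaks=r_peaks)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Affinely map ``values`` onto [0, 1]; constant input is rejected."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        raise ValueError("degenerate flat segment: max equals min")
    return (values - vmin) / (vmax - vmin)


def segment_heartbeats(record: EcgRecord, pre_s: float = PRE_S,
                       post_s: float = POST_S,
                       normalize: bool = True) -> tuple[list[BeatSegment], int]:
    """Cut one window per annotated R peak; returns (segments, skip tally).

    Each window is the half-open index range
    ``[r - round(pre_s*fs), r + round(post_s*fs))``.  R peaks whose window
    would cross a record boundary are skipped, not errors; the count of
    skipped peaks is returned so that ``len(segments) + skipped`` always
    equals the number of annotations.
    """
    n_pre = round(pre_s * record.fs)
    n_post = round(post_s * record.fs)
    segments: list[BeatSegment] = []
    skipped = 0
    for r in record.r_peaks:
        lo, hi = r - n_pre, r + n_post
        if lo < 0 or hi > record.samples.size:
            skipped += 1
            continue
        window = record.samples[lo:hi]
        if normalize:
            window = minmax_normalize(window)
        else:
            window = window.copy()
        segments.append(BeatSegment(values=window, label=record.label,
                                    subject_id=record.subject_id,
                                    source_r_peak=int(r)))
    return segments, skipped


def add_awgn(samples: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Add zero-mean white Gaussian noise at ``noise.snr_db`` relative to the
    measured signal power; an infinite SNR returns the input unchanged."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("samples must be non-empty")
    if math.isinf(noise.snr_db):
        return samples
    power = float(np.mean(samples ** 2))
    if power <= 0.0:
        raise ValueError("zero-power signal: cannot set a finite SNR")
    noise_var = power / (10.0 ** (noise.snr_db / 10.0))
    rng = np.random.default_rng(noise.rng_seed)
    return samples + rng.normal(0.0, np.sqrt(noise_var), samples.size)


def preprocess(records, noise: NoiseSpec | None = None,
               target_fs: int = TARGET_FS, pre_s: float = PRE_S,
               post_s: float = POST_S) -> list[BeatSegment]:
    """Full pipeline over a cohort: optional AWGN on the raw trace, then
    resample -> segment -> normalize.  Per-record noise streams are derived
    from ``noise.rng_seed`` so cohort order does not couple the noise."""
    segments: list[BeatSegment] = []
    for i, rec in enumerate(records):
        if noise is not None and not math.isinf(noise.snr_db):
            per_rec = NoiseSpec(
                snr_db=noise.snr_db,
                rng_seed=int(np.random.SeedSequence(
                    [noise.rng_seed, i]).generate_state(1)[0]))
            rec = EcgRecord(subject_id=rec.subject_id, label=rec.label,
                            fs=rec.fs, samples=add_awgn(rec.samples, per_rec),
                            r_peaks=rec.r_peaks)
        rec = resample_record(rec, target_fs)
        segs, _ = segment_heartbeats(rec, pre_s, post_s, normalize=True)
        segments.extend(segs)
    return segments


def stack_segments(segments) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segments -> (X beat matrix, y int labels [normal=0, chf=1], subject ids)."""
    X = np.stack([s.values for s in segments]).astype(np.float64)
    y = np.array([LABELS.index(s.label) for s in segments], dtype=np.int64)
    sid = np.array([s.subject_id for s in segments])
    return X, y, sid


def save_segments(segments, path) -> None:
    """Persist segments as one CSV row per beat: subject_id, label,
    source_r_peak, then the sample columns."""
    X, _, _ = stack_segments(segments)
    df = pd.DataFrame(X, columns=[f"s{i}" for i in range(X.shape[1])])
    df.insert(0, "source_r_peak", [s.source_r_peak for s in segments])
    df.insert(0, "label", [s.label for s in segments])
    df.insert(0, "subject_id", [s.subject_id for s in segments])
    df.to_csv(path, index=False)


def load_segments(path) -> list[BeatSegment]:
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns if c.startswith("s") and c != "subject_id"
                  and c != "source_r_peak"]
    X = df[value_cols].to_numpy(dtype=np.float64)
    return [BeatSegment(values=X[i], label=df["label"].iat[i],
                        subject_id=str(df["subject_id"].iat[i]),
                        source_r_peak=int(df["source_r_peak"].iat[i]))
            for i in range(len(df))]
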