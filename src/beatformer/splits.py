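"""Intra-patient and inter-patient experiment partitions.

Two evaluation protocols are supported:

* **inter-patient** — train and test sets contain disjoint subjects, so the
  classifier must generalize to unseen individuals;
* **intra-patient** — beats from all subjects are pooled, shuffled and split
  into k class-stratified cross-validation folds, so the same subjects
  appear on both sides.

The default subject rosters for the real PhysioNet material put the first
10 of 18 normal-sinus-rhythm records and CHF subjects 1-8 in training, the
remaining 8 and 7 in test.
"""

from __future__ import annotations

import json
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .records import LABELS

logger = logging.getLogger(__name__)

# Table rosters for the real databases (overridable in configs).
MITNSR_IDS = ["16265", "16272", "16273", "16420", "16483", "16539", "16773",
              "16786", "16795", "17052", "17453", "18177", "18184", "19088",
              "19090", "19093", "19140", "19830"]
BIDMC_IDS = [f"chf{i:02d}" for i in range(1, 16)]
REAL_TRAIN_IDS = MITNSR_IDS[:10] + BIDMC_IDS[:8]
REAL_TEST_IDS = MITNSR_IDS[10:] + BIDMC_IDS[8:]


@dataclass(frozen=True)
class SplitSpec:
    """Partition description for either protocol.

    ``scheme='inter'`` uses the subject rosters; ``scheme='intra'`` uses
    ``k_folds`` seeded, class-stratified folds over the pooled beats.
    """

    scheme: str
    train_subjects: tuple = ()
    test_subjects: tuple = ()
    k_folds: int = 10
    seed: int = 0
    beats_per_subject_cap: int = 2000

    def __post_init__(self):
        if self.scheme not in ("intra", "inter"):
            raise ValueError("scheme must be 'intra' or 'inter'")
        if self.scheme == "inter":
            train, test = set(self.train_subjects), set(self.test_subjects)
            if not train or not test:
                raise ValueError("inter scheme needs non-empty train and "
                                 "test subject lists")
            overlap = train & test
            if overlap:
                raise ValueError(f"subjects in both train and test: "
                                 f"{sorted(overlap)}")
        elif self.k_folds < 2:
            raise ValueError("intra scheme needs k_folds >= 2")


def cap_beats(segments, cap: int):
    """Keep only the first ``cap`` beats per subject, in record order.

    Mirrors the study's use of the first 2000 heartbeats of every record.
    Subjects with fewer beats keep all of them (logged, not an error).
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    kept = []
    counts: OrderedDict[str, int] = OrderedDict()
    for seg in segments:
        c = counts.get(seg.subject_id, 0)
        if c < cap:
            kept.append(seg)
        counts[seg.subject_id] = c + 1
    for sid, total in counts.items():
        if total < cap:
            logger.warning("subject %s has only %d beats (cap %d)",
                           sid, total, cap)
    return kept


def inter_patient_split(segments, spec: SplitSpec):
    """Partition beats by subject ID into (train, test); every subject must
    be on exactly one side."""
    train_ids = set(spec.train_subjects)
    test_ids = set(spec.test_subjects)
    train, test = [], []
    for seg in segments:
        if seg.subject_id in train_ids:
            train.append(seg)
        elif seg.subject_id in test_ids:
            test.append(seg)
        else:
            raise ValueError(f"subject {seg.subject_id!r} is in neither the "
                             "train nor the test roster")
    overlap = ({s.subject_id for s in train} & {s.subject_id for s in test})
    assert not overlap, f"subject leak across the split: {overlap}"
    return train, test


def intra_patient_folds(segments, spec: SplitSpec):
    """Pool all beats, shuffle with the split seed, and return ``k_folds``
    class-stratified (train, test) pairs of segment lists.

    Stratification keeps the per-class test-fold sizes within one beat of
    n_class / k, so a cohort with 36,000 normal and 30,000 CHF beats yields
    test folds of exactly 3600 + 3000.
    """
    y = np.array([LABELS.index(s.label) for s in segments])
    class_counts = np.bincount(y, minlength=2)
    if spec.k_folds > class_counts[class_counts > 0].min():
        raise ValueError(f"k_folds={spec.k_folds} exceeds the smallest "
                         "class count")
    skf = StratifiedKFold(n_splits=spec.k_folds, shuffle=True,
                          random_state=spec.seed)
    folds = []
    for train_idx, test_idx in skf.split(np.zeros(len(segments)), y):
        folds.append(([segments[i] for i in train_idx],
                      [segments[i] for i in test_idx]))
    return folds


def save_manifest(spec: SplitSpec, path, fold_test_indices=None) -> None:
    """Record the split for reproducibility: scheme, seed, rosters, and
    (for the intra scheme) the per-fold test indices."""
    payload = {
        "scheme": spec.scheme,
        "seed": spec.seed,
        "beats_per_subject_cap": spec.beats_per_subject_cap,
    }
    if spec.scheme == "inter":
        payload["train_subjects"] = list(spec.train_subjects)
        payload["test_subjects"] = list(spec.test_subjects)
    else:
        payload["k_folds"] = spec.k_folds
        if fold_test_indices is not None:
            payload["fold_test_indices"] = [
                [int(i) for i in fold] for fold in fold_test_indices]
    Path(path).write_text(json.dumps(payload, indent=2))
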