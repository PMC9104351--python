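"""Pre-wired end-to-end experiments on synthetic cohorts.

The *fixture experiment* is the package's reduced, CPU-friendly version of
the full protocol: an 8 normal + 8 CHF synthetic cohort with 200 beats per
subject, an inter-subject split (6+6 subjects train, 2+2 test), the
scaled-down model configuration, 10 training epochs at batch 64, and an
SNR robustness sweep over the held-out subjects' raw records.  The default
seeds make it bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evaluation import (ConfusionMatrix, MetricsReport, evaluate,
                         noise_robustness_sweep)
from .model import ModelConfig, build_variant
from .preprocessing import preprocess, stack_segments
from .records import CohortSpec, generate_cohort
from .splits import SplitSpec, inter_patient_split
from .training import TrainConfig, TrainHistory, train

FIXTURE_COHORT = CohortSpec(n_normal_subjects=8, n_chf_subjects=8,
                            beats_per_subject=200, fs=250, master_seed=0)
FIXTURE_TRAIN_IDS = tuple(f"normal{i:02d}" for i in range(1, 7)) + \
                    tuple(f"chf{i:02d}" for i in range(1, 7))
FIXTURE_TEST_IDS = tuple(f"normal{i:02d}" for i in range(7, 9)) + \
                   tuple(f"chf{i:02d}" for i in range(7, 9))
FIXTURE_SNR_LIST = (math.inf, 24.0, 12.0, 6.0)


@dataclass
class FixtureResult:
    history: TrainHistory
    confusion: ConfusionMatrix
    report: MetricsReport
    sweep: dict[float, tuple[ConfusionMatrix, MetricsReport]]
    n_train_beats: int
    n_test_beats: int

    @property
    def sweep_accuracy(self) -> dict[float, float]:
        return {snr: rep.accuracy for snr, (_, rep) in self.sweep.items()}


def run_fixture_experiment(cohort_seed: int = 0, model_seed: int = 7,
                           train_seed: int = 7, noise_seed: int = 7,
                           variant: str = "ecvt_net",
                           snr_list=FIXTURE_SNR_LIST,
                           run_sweep: bool = True) -> FixtureResult:
    """Generate the fixture cohort, train the reduced model on the training
    subjects, evaluate on the held-out subjects, and (optionally) run the
    SNR robustness sweep on the held-out raw records."""
    spec = CohortSpec(n_normal_subjects=FIXTURE_COHORT.n_normal_subjects,
                      n_chf_subjects=FIXTURE_COHORT.n_chf_subjects,
                      beats_per_subject=FIXTURE_COHORT.beats_per_subject,
                      fs=FIXTURE_COHORT.fs, master_seed=cohort_seed)
    records = generate_cohort(spec)
    segments = preprocess(records)
    split = SplitSpec(scheme="inter", train_subjects=FIXTURE_TRAIN_IDS,
                      test_subjects=FIXTURE_TEST_IDS)
    train_segs, test_segs = inter_patient_split(segments, split)
    X_train, y_train, _ = stack_segments(train_segs)

    model = build_variant(variant, ModelConfig.fixture(), seed=model_seed)
    history = train(model, X_train, y_train, TrainConfig.fixture(seed=train_seed))
    cm, report = evaluate(model, test_segs)

    sweep = {}
    if run_sweep:
        test_records = [r for r in records if r.subject_id in FIXTURE_TEST_IDS]
        sweep = noise_robustness_sweep(model, test_records, snr_list=snr_list,
                                       seed=noise_seed, target_fs=spec.fs)
    return FixtureResult(history=history, confusion=cm, report=report,
                         sweep=sweep, n_train_beats=len(train_segs),
                         n_test_beats=len(test_segs))
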