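"""End-to-end study workflows on phantom cohorts.

These compose the full pipeline — phantom synthesis, windowing, training
augmentation, classifier training, scale-search measurement and the
agreement battery — into reproducible experiments used by the examples
and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement import AgreementReport, MeasurementPair, compute_agreement
from .ctio import CTSlice, apply_window
from .framing import AugmentationPolicy, Frame, balance_frames, prepare_training_frames
from .phantom import PhantomCase, sample_dataset
from .scalesearch import LadderConfig, measure_lesion
from .sizeclassifier import SizeClassifier, TrainingProtocol, train_cascade

__all__ = [
    "slice_from_case",
    "training_frames_for_cases",
    "measure_cases",
    "EndToEndResult",
    "run_end_to_end",
]

# cohort conditions for the scaled-down phantom study: diameters and
# spacings inside the canonical measurable range, with margin so the
# ladder (1.0-5.5 cm) brackets every truth
STUDY_DIAMETER_RANGE_CM = (1.5, 5.0)
STUDY_SPACING_RANGE_CM = (0.06, 0.13)


def slice_from_case(case: PhantomCase) -> CTSlice:
    """View a phantom as the CT slice the measurement pipeline consumes."""
    return CTSlice(
        pixels=case.image.astype(float),
        spacing_cm=(case.spacing_cm, case.spacing_cm),
        source_id=case.case_id,
    )


def training_frames_for_cases(
    cases: list[PhantomCase],
    policy: AugmentationPolicy,
    rng_seed: int = 0,
) -> list[Frame]:
    """Windowed, labeled augmentation frames pooled over a phantom cohort."""
    frames: list[Frame] = []
    for i, case in enumerate(cases):
        img = apply_window(slice_from_case(case))
        frames.extend(
            prepare_training_frames(
                img,
                case.seed_point,
                case.true_diameter_px,
                policy,
                rng_seed=rng_seed + i,
                spacing_cm=case.spacing_cm,
            )
        )
    return frames


def measure_cases(
    cases: list[PhantomCase],
    clf: SizeClassifier,
    config: LadderConfig = LadderConfig(),
) -> tuple[list[MeasurementPair], int]:
    """Measure a cohort; ground truth plays the human reader.

    Returns the measurement pairs plus the count of out-of-range flags
    (those cases carry no usable size and are excluded from agreement).
    """
    pairs: list[MeasurementPair] = []
    n_out_of_range = 0
    for case in cases:
        result = measure_lesion(slice_from_case(case), case.seed_point, clf, config)
        if result.out_of_range is not None:
            n_out_of_range += 1
            continue
        pairs.append(
            MeasurementPair(
                case_id=case.case_id,
                m_human=case.true_diameter_cm,
                m_dl=result.size_cm,
                spacing_cm=case.spacing_cm,
                invasion_group=case.invasion_group.value,
            )
        )
    return pairs, n_out_of_range


@dataclass
class EndToEndResult:
    report: AgreementReport
    n_out_of_range: int
    best_val_accuracies: list[float]
    n_train_frames: int
    pairs: list[MeasurementPair]


def run_end_to_end(
    seed: int = 0,
    n_train: int = 120,
    n_val: int = 30,
    n_test: int = 100,
    iterations: int = 500,
    batch_size: int = 32,
    n_members: int = 3,
) -> EndToEndResult:
    """Scaled-down phantom analogue of a reader-agreement study.

    Trains the reference cascade on balanced frames from ``n_train``
    phantoms (validated on frames from ``n_val`` more), measures
    ``n_test`` held-out phantoms, and reports agreement between measured
    and true diameters. All randomness derives from ``seed``.
    """
    def sub(k: int) -> int:
        return (seed * 1000 + k) % (2**31)

    train_cases = sample_dataset(
        n_train, STUDY_DIAMETER_RANGE_CM, STUDY_SPACING_RANGE_CM, master_seed=sub(11)
    )
    val_cases = sample_dataset(
        n_val, STUDY_DIAMETER_RANGE_CM, STUDY_SPACING_RANGE_CM, master_seed=sub(12)
    )
    test_cases = sample_dataset(
        n_test, STUDY_DIAMETER_RANGE_CM, STUDY_SPACING_RANGE_CM, master_seed=sub(13)
    )

    train_policy = AugmentationPolicy(per_image_count=32, max_shift_px=24)
    val_policy = AugmentationPolicy(per_image_count=16, max_shift_px=24)
    train_frames = balance_frames(
        training_frames_for_cases(train_cases, train_policy, rng_seed=sub(100)),
        rng_seed=sub(5),
    )
    val_frames = training_frames_for_cases(val_cases, val_policy, rng_seed=sub(200))

    protocol = TrainingProtocol(iterations=iterations, batch_size=batch_size, rng_seed=seed)
    cascade = train_cascade(train_frames, val_frames, protocol, n_members=n_members)

    pairs, n_oor = measure_cases(test_cases, cascade)
    report = compute_agreement(pairs)
    return EndToEndResult(
        report=report,
        n_out_of_range=n_oor,
        best_val_accuracies=[m.best_val_accuracy for m in cascade.members],
        n_train_frames=len(train_frames),
        pairs=pairs,
    )
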