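"""Canonical label sets for the six-stage / eight-disorder sleep-scoring task.

Stages follow the Rechtschaffen–Kales six-class scheme (wake, four NREM
sub-stages, REM); disorders follow the eight recording-level diagnostic
groups of clinical polysomnography cohorts.
"""

from __future__ import annotations

STAGES: tuple[str, ...] = ("W", "S1", "S2", "S3", "S4", "R")
DISORDERS: tuple[str, ...] = ("N", "B", "I", "Na", "Nf", "P", "Rd", "S")
MODALITIES: tuple[str, ...] = ("EEG", "ECG", "EMG")
TASKS: tuple[str, ...] = ("stage", "disorder")

STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
DISORDER_INDEX: dict[str, int] = {d: i for i, d in enumerate(DISORDERS)}


def task_classes(task: str) -> tuple[str, ...]:
    """Return the ordered class labels for a task ('stage' or 'disorder')."""
    if task == "stage":
        return STAGES
    if task == "disorder":
        return DISORDERS
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def validate_stage(stage: str) -> str:
    if stage not in STAGE_INDEX:
        raise ValueError(f"unknown sleep stage {stage!r}; valid stages: {STAGES}")
    return stage


def validate_disorder(disorder: str) -> str:
    if disorder not in DISORDER_INDEX:
        raise ValueError(
            f"unknown sleep disorder {disorder!r}; valid disorders: {DISORDERS}"
        )
    return disorder


def validate_modality(modality: str) -> str:
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; valid: {MODALITIES}")
    return modality
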