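"""Reading, writing and validating study datasets, and the exclusion step.

Both tables are plain UTF-8 comma-separated files with a header row:

* trials long table — ``participant_id, trial, truth, advice, advice_correct,
  response_1, response_2`` (one row per participant × trial);
* participants wide table — ``participant_id, experience_years``, item columns
  per scale, and attention-check flags.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import TRIALS_COLUMNS, StudyDataset


class DatasetValidationError(ValueError):
    """Schema or value violations; message lists file, column and row context."""


def write_dataset(dataset: StudyDataset, out_dir: str) -> tuple[str, str]:
    """Write the two tables to ``out_dir``; returns (trials_path, participants_path)."""
    os.makedirs(out_dir, exist_ok=True)
    trials_path = os.path.join(out_dir, "trials.csv")
    participants_path = os.path.join(out_dir, "participants.csv")
    dataset.trials.to_csv(trials_path, index=False)
    dataset.participants.to_csv(participants_path, index=False)
    return trials_path, participants_path


def _validate_trials(trials: pd.DataFrame, source: str) -> list[str]:
    problems: list[str] = []
    missing = [c for c in TRIALS_COLUMNS if c not in trials.columns]
    if missing:
        problems.append(f"{source}: missing column(s) {missing}")
        return problems
    for col in ("advice", "response_1", "response_2"):
        vals = pd.to_numeric(trials[col], errors="coerce")
        bad = trials.index[vals.isna() | (vals < 0) | (vals > 100)]
        for row in bad[:10]:
            problems.append(f"{source}: row {row}: {col}={trials.loc[row, col]!r} outside [0, 100]")
    bad_truth = trials.index[~trials["truth"].isin(["benign", "malignant"])]
    for row in bad_truth[:10]:
        problems.append(f"{source}: row {row}: unknown truth {trials.loc[row, 'truth']!r}")
    dupes = trials.duplicated(subset=["participant_id", "trial"])
    if dupes.any():
        rows = list(trials.index[dupes][:10])
        problems.append(f"{source}: duplicate (participant_id, trial) key at row(s) {rows}")
    return problems


def read_dataset(trials_path: str, participants_path: str | None = None) -> StudyDataset:
    """Read and validate a study dataset; all violations are collected and
    reported together in a single :class:`DatasetValidationError`."""
    trials = pd.read_csv(trials_path)
    problems = _validate_trials(trials, trials_path)
    if participants_path is not None:
        participants = pd.read_csv(participants_path)
        if "participant_id" not in participants.columns:
            problems.append(f"{participants_path}: missing column(s) ['participant_id']")
        elif participants["participant_id"].duplicated().any():
            problems.append(f"{participants_path}: duplicate participant_id")
    else:
        # trials-only ingest: minimal participant frame so downstream stages
        # can report explicit skips for questionnaire-dependent analyses
        participants = pd.DataFrame(
            {"participant_id": np.sort(trials["participant_id"].unique())}
        )
    if problems:
        raise DatasetValidationError("; ".join(problems))
    trials = trials.copy()
    trials["advice_correct"] = trials["advice_correct"].astype(bool)
    return StudyDataset(trials=trials, participants=participants)


@dataclass
class ExclusionLog:
    """Record of the attention-check exclusion step."""

    rule: str
    n_total: int
    n_excluded: int
    n_retained: int
    excluded_ids: list

    @property
    def retention_percent(self) -> float:
        return 100.0 * self.n_retained / self.n_total if self.n_total else float("nan")

    def as_dict(self) -> dict:
        return {
            "rule": self.rule,
            "respondents_in": self.n_total,
            "attention_failures_excluded": self.n_excluded,
            "retained": self.n_retained,
            "retention_percent": round(self.retention_percent, 1),
            "excluded_ids": [int(i) for i in self.excluded_ids],
        }


def apply_exclusions(dataset: StudyDataset, rule: str = "either") -> tuple[StudyDataset, ExclusionLog]:
    """Drop participants failing the attention checks from both tables.

    ``rule='either'`` excludes on failing at least one check; ``rule='both'``
    only when both checks were failed.  Tables without check columns pass
    through unchanged (nothing to exclude on).
    """
    if rule not in ("either", "both"):
        raise ValueError("exclusion rule must be 'either' or 'both'")
    parts = dataset.participants
    n_total = len(parts)
    if {"attention_check_1", "attention_check_2"}.issubset(parts.columns):
        c1 = parts["attention_check_1"].astype(bool)
        c2 = parts["attention_check_2"].astype(bool)
        failed = ~(c1 & c2) if rule == "either" else ~(c1 | c2)
    elif "attention_pass" in parts.columns:
        failed = ~parts["attention_pass"].astype(bool)
    else:
        failed = pd.Series(False, index=parts.index)
    excluded_ids = list(parts.loc[failed, "participant_id"])
    kept = parts.loc[~failed].reset_index(drop=True)
    trials = dataset.trials[~dataset.trials["participant_id"].isin(excluded_ids)].reset_index(
        drop=True
    )
    log = ExclusionLog(
        rule=rule,
        n_total=n_total,
        n_excluded=len(excluded_ids),
        n_retained=len(kept),
        excluded_ids=excluded_ids,
    )
    return StudyDataset(trials=trials, participants=kept), log


def dataset_checksums(dataset: StudyDataset) -> dict[str, str]:
    """SHA-256 of the canonical CSV serialisation of each table (provenance)."""
    out = {}
    for name, frame in (("trials", dataset.trials), ("participants", dataset.participants)):
        payload = frame.to_csv(index=False).encode("utf-8")
        out[name] = hashlib.sha256(payload).hexdigest()
    return out
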