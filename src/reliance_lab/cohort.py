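"""Synthetic-cohort generator for the two-step advice-taking experiment.

Emulates a judge–advisor study: each participant classifies lesions on a
0–100 slider (benign … malignant), sees AI advice placed 15–25 units from a
scale extreme, and may revise.  Advice is deliberately wrong on a fixed number
of trials per participant, with the positions shuffled per participant.  The
behavioural model generates trust from propensity-to-trust and experience
(positive and negative paths respectively) and per-trial adherence from trust
and confidence, so downstream mediation analyses have a known ground truth.

Reproducibility: a single master seed; each participant draws from a
sub-stream derived deterministically from (seed, participant id), so a
participant's data can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .config import (
    DEFAULT_SCALES,
    SCALE_LATENT,
    BehaviorConfig,
    DesignConfig,
    ScaleDefinition,
)

TRAITS = ("propensity", "affinity", "control_beliefs", "need_for_cognition")

TRIALS_COLUMNS = [
    "participant_id",
    "trial",
    "truth",
    "advice",
    "advice_correct",
    "response_1",
    "response_2",
]


@dataclass
class StudyDataset:
    """A complete study dataset: one trials long table, one participants wide table."""

    trials: pd.DataFrame
    participants: pd.DataFrame

    def copy(self) -> "StudyDataset":
        return StudyDataset(self.trials.copy(), self.participants.copy())


def _participant_rng(seed: int, participant_id: int, stream: int = 0) -> np.random.Generator:
    # Deterministic sub-stream per (participant, stage): regenerating one
    # participant's profile or trials never depends on any other draw.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(participant_id), int(stream)])
    )


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float,
    high: float,
    size: int,
) -> np.ndarray:
    """Inverse-CDF truncated normal draw (exact, no rejection loop)."""
    if sd == 0:
        return np.full(size, np.clip(mean, low, high))
    a = special.ndtr((low - mean) / sd)
    b = special.ndtr((high - mean) / sd)
    u = rng.uniform(a, b, size=size)
    return mean + sd * special.ndtri(u)


def _truncnorm_mean(mu: float, sd: float, low: float, high: float) -> float:
    a = (low - mu) / sd
    b = (high - mu) / sd
    z = special.ndtr(b) - special.ndtr(a)
    phi = lambda t: np.exp(-0.5 * t * t) / np.sqrt(2 * np.pi)
    return mu + sd * (phi(a) - phi(b)) / z


def _match_truncnorm_location(
    target_mean: float, sd: float, low: float, high: float
) -> float:
    """Location parameter whose truncated-normal mean equals ``target_mean``.

    The experience config states the cohort mean; truncation at the range
    bounds shifts the mean away from the location parameter, so the location
    is solved for by bisection (the truncated mean is increasing in it).
    """
    if sd == 0:
        return target_mean
    lo, hi = low - 10 * sd, high + 10 * sd
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _truncnorm_mean(mid, sd, low, high) < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _discretize_items(values: np.ndarray, scale: ScaleDefinition) -> np.ndarray:
    lo, hi = scale.response_range
    return np.clip(np.rint(values), lo, hi).astype(int)


def _generate_items(
    rng: np.random.Generator,
    latent: np.ndarray,
    scale: ScaleDefinition,
    loading: float,
    noise_sd: float,
) -> np.ndarray:
    """Item responses: center + loading*latent + item noise, discretized.

    ``latent`` is on the standardised scale; the scale midpoint anchors the
    items so a zero latent scores at the middle of the response range.
    """
    lo, hi = scale.response_range
    center = (lo + hi) / 2.0
    n = latent.shape[0]
    noise = rng.normal(0.0, noise_sd, size=(n, scale.n_items)) if noise_sd > 0 else 0.0
    raw = center + loading * latent[:, None] + np.zeros((n, scale.n_items)) + noise
    return _discretize_items(raw, scale)


def generate_participants(
    design: DesignConfig,
    behavior: BehaviorConfig,
    scales: dict[str, ScaleDefinition] | None = None,
) -> pd.DataFrame:
    """Generate the participants wide table.

    Columns: participant_id, experience_years, the four latent traits, the
    latent trust value, per-scale item columns, two attention-check flags and
    the combined ``attention_pass`` convenience flag.
    """
    design.validate()
    behavior.validate()
    scales = scales or DEFAULT_SCALES

    lo_exp, hi_exp = behavior.experience_range
    exp_location = _match_truncnorm_location(
        behavior.experience_mean, behavior.experience_sd, lo_exp, hi_exp
    )

    rows = []
    for pid in range(design.n_participants):
        rng = _participant_rng(design.seed, pid)
        row: dict = {"participant_id": pid}

        latents = {}
        for trait in TRAITS:
            latents[trait] = rng.normal(behavior.trait_means[trait], behavior.trait_sds[trait])
            row[trait] = latents[trait]

        row["experience_years"] = float(
            _truncated_normal(
                rng, exp_location, behavior.experience_sd, lo_exp, hi_exp, 1
            )[0]
        )

        trust = (
            behavior.trust_intercept
            + behavior.trust_propensity_slope * latents["propensity"]
            + behavior.trust_experience_slope * row["experience_years"]
            + rng.normal(0.0, behavior.trust_sd)
        )
        trust = float(np.clip(trust, 1.0, 5.0))
        row["trust_latent"] = trust

        for name, scale in scales.items():
            if name == "trust":
                # trust is already on the 1–5 response metric; items scatter around it
                items = _discretize_items(
                    trust + rng.normal(0.0, behavior.item_noise_sd, size=scale.n_items),
                    scale,
                )
            else:
                latent = np.array([latents[SCALE_LATENT[name]]])
                items = _generate_items(
                    rng, latent, scale, behavior.item_loading, behavior.item_noise_sd
                )[0]
            for col, val in zip(scale.item_columns, items):
                row[col] = int(val)

        check_1 = rng.random() >= behavior.attention_fail_rate
        check_2 = rng.random() >= behavior.attention_fail_rate
        row["attention_check_1"] = bool(check_1)
        row["attention_check_2"] = bool(check_2)
        row["attention_pass"] = bool(check_1 and check_2)
        rows.append(row)

    return pd.DataFrame(rows)


def generate_trials(
    profile: pd.Series,
    design: DesignConfig,
    behavior: BehaviorConfig,
) -> pd.DataFrame:
    """Generate one participant's trial sequence.

    Advice placement: the offset from the extreme is uniform on
    ``design.advice_offset_range``, so benign-pointing advice lies in [15, 25]
    and malignant-pointing advice in [75, 85] at defaults.  The final response
    is ``response_1 + w * (advice - response_1)`` with the adherence weight
    *w* from the behavioural equation, clipped to [0, 1] by default.
    """
    design.validate()
    behavior.validate()
    pid = int(profile["participant_id"])
    rng = _participant_rng(design.seed, pid, stream=1)
    n = design.n_trials

    # balanced truth composition, order shuffled per participant
    n_mal = n // 2
    truth_mal = np.zeros(n, dtype=bool)
    truth_mal[:n_mal] = True
    rng.shuffle(truth_mal)

    advice_correct = np.ones(n, dtype=bool)
    wrong_pos = rng.choice(n, size=design.n_incorrect_advice, replace=False)
    advice_correct[wrong_pos] = False

    off_lo, off_hi = design.advice_offset_range
    offsets = rng.uniform(off_lo, off_hi, size=n)
    # advice points at the truth when correct, at the opposite class when not
    points_malignant = truth_mal == advice_correct
    advice = np.where(points_malignant, 100.0 - offsets, offsets)

    # initial response: in the correct region with probability `skill`
    in_correct = rng.random(n) < behavior.skill
    response_1 = np.empty(n)
    for i in range(n):
        if truth_mal[i] == in_correct[i]:
            lo, hi = 61.0, 100.0  # malignant-side region
        else:
            lo, hi = 0.0, 40.0  # benign-side region
        response_1[i] = _truncated_normal(
            rng, (lo + hi) / 2.0, behavior.response_sd, lo, hi, 1
        )[0]

    confident = (response_1 <= 20.0) | (response_1 >= 80.0)
    w = (
        behavior.adherence_intercept
        + behavior.adherence_trust_slope * float(profile["trust_latent"])
        + behavior.adherence_confidence_slope * confident.astype(float)
        + rng.normal(0.0, behavior.adherence_sd, size=n)
    )
    w_lo = -1.0 if behavior.allow_negative_adherence else 0.0
    w = np.clip(w, w_lo, 1.0)

    response_2 = np.clip(response_1 + w * (advice - response_1), 0.0, 100.0)
    if design.round_responses:
        response_1 = np.rint(response_1)
        response_2 = np.rint(response_2)

    return pd.DataFrame(
        {
            "participant_id": pid,
            "trial": np.arange(n),
            "truth": np.where(truth_mal, "malignant", "benign"),
            "advice": advice,
            "advice_correct": advice_correct,
            "response_1": response_1,
            "response_2": response_2,
        }
    )


def simulate_study(
    design: DesignConfig,
    behavior: BehaviorConfig | None = None,
    scales: dict[str, ScaleDefinition] | None = None,
) -> StudyDataset:
    """Generate a complete synthetic study dataset (participants + trials).

    The design seed fully determines the output.
    """
    behavior = behavior or BehaviorConfig()
    participants = generate_participants(design, behavior, scales)
    trial_frames = [
        generate_trials(row, design, behavior) for _, row in participants.iterrows()
    ]
    trials = pd.concat(trial_frames, ignore_index=True)
    return StudyDataset(trials=trials, participants=participants)
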