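"""Measurement layer: weight of advice, correctness scoring, confidence proxy,
the eight-pattern reliance taxonomy, and pooled / per-participant reliance metrics.

Weight of advice (WoA) quantifies the fractional shift of a judgment toward
advice::

    WoA = (response_2 - response_1) / (advice - response_1)

clipped to [-1, 1] and undefined (missing) when the advice coincides with the
initial response.  Relative AI reliance (RAIR) is the proportion of
initially-wrong / advice-right cases that ended correct; relative
self-reliance (RSR) is the proportion of initially-right / advice-wrong cases
that stayed correct.  Jointly high RAIR and RSR indicate appropriate reliance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CutoffRule


class ReliancePattern(str, enum.Enum):
    """The eight reliance patterns indexed by (initial correct, advice correct,
    final correct); 'detrimental' marks an incorrect final decision."""

    DETRIMENTAL_RELIANCE = "detrimental reliance"            # (0, 0, 0)
    BENEFICIAL_UNDERRELIANCE = "beneficial underreliance"    # (0, 0, 1)
    DETRIMENTAL_SELF_RELIANCE = "detrimental self-reliance"  # (0, 1, 0)
    BENEFICIAL_OVERRELIANCE = "beneficial overreliance"      # (0, 1, 1)
    DETRIMENTAL_OVERRELIANCE = "detrimental overreliance"    # (1, 0, 0)
    BENEFICIAL_SELF_RELIANCE = "beneficial self-reliance"    # (1, 0, 1)
    DETRIMENTAL_UNDERRELIANCE = "detrimental underreliance"  # (1, 1, 0)
    BENEFICIAL_RELIANCE = "beneficial reliance"              # (1, 1, 1)


PATTERN_BY_TRIPLE: dict[tuple[int, int, int], ReliancePattern] = {
    (0, 0, 0): ReliancePattern.DETRIMENTAL_RELIANCE,
    (0, 0, 1): ReliancePattern.BENEFICIAL_UNDERRELIANCE,
    (0, 1, 0): ReliancePattern.DETRIMENTAL_SELF_RELIANCE,
    (0, 1, 1): ReliancePattern.BENEFICIAL_OVERRELIANCE,
    (1, 0, 0): ReliancePattern.DETRIMENTAL_OVERRELIANCE,
    (1, 0, 1): ReliancePattern.BENEFICIAL_SELF_RELIANCE,
    (1, 1, 0): ReliancePattern.DETRIMENTAL_UNDERRELIANCE,
    (1, 1, 1): ReliancePattern.BENEFICIAL_RELIANCE,
}

TRIPLE_BY_PATTERN = {v: k for k, v in PATTERN_BY_TRIPLE.items()}

#: Table ordering used in reports.
PATTERN_ORDER = [PATTERN_BY_TRIPLE[t] for t in sorted(PATTERN_BY_TRIPLE)]


def _check_slider(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(np.isnan(arr)) or np.any(arr < 0.0) or np.any(arr > 100.0):
        raise ValueError(f"{name} must lie in [0, 100]")


def weight_of_advice(response_1, advice, response_2):
    """Weight of advice, clipped to [-1, 1]; NaN when ``advice == response_1``.

    Accepts scalars or array-likes; returns a float or float ndarray.
    """
    _check_slider("response_1", response_1)
    _check_slider("advice", advice)
    _check_slider("response_2", response_2)
    r1 = np.asarray(response_1, dtype=float)
    a = np.asarray(advice, dtype=float)
    r2 = np.asarray(response_2, dtype=float)
    denom = a - r1
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(denom == 0.0, np.nan, (r2 - r1) / denom)
    out = np.clip(raw, -1.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def is_correct(response, truth, rule: CutoffRule | None = None):
    """True when the response falls in the truth's correct interval (inclusive)."""
    rule = rule or CutoffRule()
    _check_slider("response", response)
    r = np.asarray(response, dtype=float)
    t = np.asarray(truth)
    known = np.isin(t, ("benign", "malignant"))
    if not np.all(known):
        bad = np.unique(t[~known])
        raise ValueError(f"unknown truth label(s): {list(bad)}")
    m_lo, m_hi = rule.malignant_correct
    b_lo, b_hi = rule.benign_correct
    mal = (t == "malignant") & (r >= m_lo) & (r <= m_hi)
    ben = (t == "benign") & (r >= b_lo) & (r <= b_hi)
    out = mal | ben
    if out.ndim == 0:
        return bool(out)
    return out


def confidence_proxy(response_1, rule: CutoffRule | None = None):
    """Binary confidence proxy from the initial slider placement.

    1 (high) when the initial response lies in either extreme band
    ([0, 20] or [80, 100] by default), else 0 (low).
    """
    rule = rule or CutoffRule()
    _check_slider("response_1", response_1)
    r = np.asarray(response_1, dtype=float)
    (lo1, hi1), (lo2, hi2) = rule.confidence_high
    out = (((r >= lo1) & (r <= hi1)) | ((r >= lo2) & (r <= hi2))).astype(int)
    if out.ndim == 0:
        return int(out)
    return out


def classify_pattern(correct_1, advice_correct, correct_2) -> ReliancePattern:
    """Map one (initial, advice, final) correctness triple to its pattern."""
    return PATTERN_BY_TRIPLE[(int(bool(correct_1)), int(bool(advice_correct)), int(bool(correct_2)))]


def derive_trials(trials: pd.DataFrame, rule: CutoffRule | None = None) -> pd.DataFrame:
    """Augment a trials long table with WoA, correctness flags, confidence and pattern.

    Input columns: participant_id, trial, truth, advice, advice_correct,
    response_1, response_2.
    """
    rule = (rule or CutoffRule()).validate()
    out = trials.copy()
    out["woa"] = weight_of_advice(
        out["response_1"].to_numpy(), out["advice"].to_numpy(), out["response_2"].to_numpy()
    )
    truth = out["truth"].to_numpy()
    out["correct_1"] = is_correct(out["response_1"].to_numpy(), truth, rule)
    out["correct_2"] = is_correct(out["response_2"].to_numpy(), truth, rule)
    out["confidence"] = confidence_proxy(out["response_1"].to_numpy(), rule)
    c1 = out["correct_1"].to_numpy().astype(int)
    adv = out["advice_correct"].to_numpy().astype(int)
    c2 = out["correct_2"].to_numpy().astype(int)
    lookup = np.empty(8, dtype=object)
    for (a, b, c), pat in PATTERN_BY_TRIPLE.items():
        lookup[a * 4 + b * 2 + c] = pat.value
    out["pattern"] = lookup[c1 * 4 + adv * 2 + c2]
    return out


@dataclass
class RelianceSummary:
    """Pooled reliance summary: pattern counts/percentages, RAIR, RSR, accuracy.

    RAIR and RSR are case-pooled across participants (numerators and
    denominators summed over all trials), matching how the study pooled its
    5352 cases; ``rair``/``rsr`` are NaN when the denominator is zero.
    """

    counts: dict[str, int]
    n_cases: int
    n_woa_defined: int
    rair: float
    rsr: float
    rair_numerator: int
    rair_denominator: int
    rsr_numerator: int
    rsr_denominator: int
    accuracy_first: float
    accuracy_final: float
    percentages: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.percentages = {
            k: 100.0 * v / self.n_cases for k, v in self.counts.items()
        }

    def rounded_percentages(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.percentages.items()}

    def as_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_woa_defined": self.n_woa_defined,
            "pattern_counts": dict(self.counts),
            "pattern_percentages": self.rounded_percentages(2),
            "rair": None if np.isnan(self.rair) else self.rair,
            "rsr": None if np.isnan(self.rsr) else self.rsr,
            "rair_percent": None if np.isnan(self.rair) else round(100 * self.rair, 2),
            "rsr_percent": None if np.isnan(self.rsr) else round(100 * self.rsr, 1),
            "rair_cases": [self.rair_numerator, self.rair_denominator],
            "rsr_cases": [self.rsr_numerator, self.rsr_denominator],
            "accuracy_first": self.accuracy_first,
            "accuracy_final": self.accuracy_final,
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def summarize_reliance(derived: pd.DataFrame) -> RelianceSummary:
    """Pool a derived-trials table into pattern counts, RAIR, RSR and accuracy."""
    if len(derived) == 0:
        raise ValueError("cannot summarize an empty trial collection")
    counts = {p.value: 0 for p in PATTERN_ORDER}
    observed = derived["pattern"].value_counts()
    for pat, n in observed.items():
        counts[str(pat)] += int(n)
    n_cases = len(derived)

    n_bo = counts[ReliancePattern.BENEFICIAL_OVERRELIANCE.value]
    n_dsr = counts[ReliancePattern.DETRIMENTAL_SELF_RELIANCE.value]
    n_bsr = counts[ReliancePattern.BENEFICIAL_SELF_RELIANCE.value]
    n_do = counts[ReliancePattern.DETRIMENTAL_OVERRELIANCE.value]

    return RelianceSummary(
        counts=counts,
        n_cases=n_cases,
        n_woa_defined=int(derived["woa"].notna().sum()),
        rair=_ratio(n_bo, n_bo + n_dsr),
        rsr=_ratio(n_bsr, n_bsr + n_do),
        rair_numerator=n_bo,
        rair_denominator=n_bo + n_dsr,
        rsr_numerator=n_bsr,
        rsr_denominator=n_bsr + n_do,
        accuracy_first=float(derived["correct_1"].mean()),
        accuracy_final=float(derived["correct_2"].mean()),
    )


def per_participant_metrics(derived: pd.DataFrame) -> pd.DataFrame:
    """Collapse a derived-trials table to one row per participant.

    Columns: mean WoA over defined-WoA trials (overall and split by advice
    correctness), participant RAIR/RSR (NaN when no opportunity existed),
    accuracy before and after advice, mean confidence, trial counts.
    A participant with zero defined-WoA trials gets a missing mean WoA.
    """
    rows = []
    for pid, grp in derived.groupby("participant_id", sort=True):
        woa = grp["woa"]
        adv = grp["advice_correct"].astype(bool)
        c1 = grp["correct_1"].astype(bool)
        c2 = grp["correct_2"].astype(bool)
        rair_den = int((~c1 & adv).sum())
        rair_num = int((~c1 & adv & c2).sum())
        rsr_den = int((c1 & ~adv).sum())
        rsr_num = int((c1 & ~adv & c2).sum())
        rows.append(
            {
                "participant_id": pid,
                "n_trials": len(grp),
                "n_woa_defined": int(woa.notna().sum()),
                "mean_woa": float(woa.mean()) if woa.notna().any() else float("nan"),
                "mean_woa_correct_advice": float(woa[adv].mean())
                if woa[adv].notna().any()
                else float("nan"),
                "mean_woa_incorrect_advice": float(woa[~adv].mean())
                if woa[~adv].notna().any()
                else float("nan"),
                "rair": _ratio(rair_num, rair_den),
                "rsr": _ratio(rsr_num, rsr_den),
                "accuracy_first": float(c1.mean()),
                "accuracy_final": float(c2.mean()),
                "mean_confidence": float(grp["confidence"].mean()),
            }
        )
    return pd.DataFrame(rows)
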