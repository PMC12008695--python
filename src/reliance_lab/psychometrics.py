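"""Questionnaire scoring (mean scoring with reverse-keying) and Cronbach's alpha."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import DEFAULT_SCALES, ScaleDefinition

logger = logging.getLogger(__name__)


class ReliabilityError(ValueError):
    """Cronbach's alpha is undefined (too few rows/items or zero variance)."""


def score_scale(
    items: pd.DataFrame,
    definition: ScaleDefinition,
    max_missing_frac: float = 0.2,
) -> pd.Series:
    """Score one scale: reflect reverse-keyed items (min+max−x), then row-mean.

    Respondents missing more than ``max_missing_frac`` of the items receive a
    missing score; otherwise the mean is taken over the answered items.
    """
    definition.validate()
    cols = definition.item_columns
    missing = [c for c in cols if c not in items.columns]
    if missing:
        raise KeyError(f"scale '{definition.name}': missing item column(s) {missing}")
    mat = items[cols].astype(float).copy()
    lo, hi = definition.response_range
    in_range = mat.isna() | ((mat >= lo) & (mat <= hi))
    if not in_range.all().all():
        bad = mat[~in_range].stack().index[0]
        raise ValueError(
            f"scale '{definition.name}': item response out of range at row {bad[0]}, {bad[1]}"
        )
    for i in definition.reverse_items:
        mat[cols[i]] = lo + hi - mat[cols[i]]
    frac_missing = mat.isna().mean(axis=1)
    scores = mat.mean(axis=1, skipna=True)
    dropped = frac_missing > max_missing_frac
    if dropped.any():
        logger.warning(
            "scale '%s': %d respondent(s) above the %.0f%% missing-item limit scored as missing",
            definition.name,
            int(dropped.sum()),
            100 * max_missing_frac,
        )
    scores[dropped] = np.nan
    return scores.rename(f"{definition.name}_score")


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(item variances)/var(row totals))``.

    Sample variances use the n−1 denominator.  Requires at least 3 complete
    respondents, at least 2 items and a nonzero total-score variance.
    """
    mat = np.asarray(pd.DataFrame(items).dropna(), dtype=float)
    n, k = mat.shape
    if k < 2:
        raise ReliabilityError("alpha needs at least 2 items")
    if n < 3:
        raise ReliabilityError("alpha needs at least 3 complete respondents")
    item_vars = mat.var(axis=0, ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ReliabilityError("total-score variance is zero; reliability undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def score_participants(
    participants: pd.DataFrame,
    scales: dict[str, ScaleDefinition] | None = None,
    max_missing_frac: float = 0.2,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Score every scale present in the participants wide table.

    Returns (scores frame indexed like ``participants`` with one
    ``<scale>_score`` column per scale, alpha per scale).  Scales whose item
    columns are absent are skipped silently — callers report them as skipped.
    """
    scales = scales or DEFAULT_SCALES
    scores = pd.DataFrame({"participant_id": participants["participant_id"]})
    alphas: dict[str, float] = {}
    for name, definition in scales.items():
        if not all(c in participants.columns for c in definition.item_columns):
            continue
        scores[f"{name}_score"] = score_scale(participants, definition, max_missing_frac)
        try:
            alphas[name] = cronbach_alpha(participants[definition.item_columns])
        except ReliabilityError as exc:
            logger.warning("scale '%s': %s", name, exc)
            alphas[name] = float("nan")
    return scores, alphas
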