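"""Configuration objects for the study design, behavioural generator and scoring rules.

Defaults reproduce the design of a web-based judge–advisor experiment with
dermatologists: 223 participants, 24 lesion-classification trials on a 0–100
slider, AI advice correct on 19/24 trials and placed 15–25 slider units from
the scale extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Any

import yaml


class ConfigError(ValueError):
    """A configuration field violates its invariant; the message names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class DesignConfig:
    """Experimental design: trial counts and advice placement.

    ``advice_offset_range`` is the distance of the advice from the scale
    extreme, in slider units: advice lands in ``[lo, hi]`` when pointing
    benign and ``[100-hi, 100-lo]`` when pointing malignant.
    """

    n_participants: int = 223
    n_trials: int = 24
    n_incorrect_advice: int = 5
    advice_offset_range: tuple[float, float] = (15.0, 25.0)
    slider_range: tuple[float, float] = (0.0, 100.0)
    round_responses: bool = False
    seed: int = 0

    def validate(self) -> "DesignConfig":
        _require(self.n_participants >= 1, "n_participants", "must be >= 1")
        _require(self.n_trials >= 1, "n_trials", "must be >= 1")
        _require(
            0 <= self.n_incorrect_advice <= self.n_trials,
            "n_incorrect_advice",
            "must lie in [0, n_trials]",
        )
        lo, hi = self.advice_offset_range
        _require(0 < lo < hi < 50, "advice_offset_range", "needs 0 < lower < upper < 50")
        _require(
            tuple(self.slider_range) == (0.0, 100.0),
            "slider_range",
            "the response scale is fixed at [0, 100]",
        )
        return self


@dataclass(frozen=True)
class BehaviorConfig:
    """Generative behavioural model for the synthetic cohort.

    Latent traits (propensity to trust technology, affinity for technology
    interaction, control beliefs, need for cognition) are standardised
    normals.  Subjective trust in the system follows a linear equation in
    propensity and years of experience; the per-trial adherence weight *w*
    (the generated weight of advice) follows a linear equation in trust and
    decision confidence, clipped to [0, 1] unless ``allow_negative_adherence``.
    """

    # latent trait moments (standardised scores)
    trait_means: dict[str, float] = field(
        default_factory=lambda: {
            "propensity": 0.0,
            "affinity": 0.0,
            "control_beliefs": 0.0,
            "need_for_cognition": 0.0,
        }
    )
    trait_sds: dict[str, float] = field(
        default_factory=lambda: {
            "propensity": 1.0,
            "affinity": 1.0,
            "control_beliefs": 1.0,
            "need_for_cognition": 1.0,
        }
    )
    # years of clinical experience: truncated normal
    experience_mean: float = 15.5
    experience_sd: float = 11.2
    experience_range: tuple[float, float] = (0.0, 50.0)
    # trust equation: trust = b0 + b_prop*propensity + b_exp*experience + N(0, sd)
    trust_intercept: float = 3.0
    trust_propensity_slope: float = 0.30
    trust_experience_slope: float = -0.02
    trust_sd: float = 0.40
    # adherence equation: w = a0 + a_trust*trust + a_conf*confidence + N(0, sd)
    adherence_intercept: float = -0.30
    adherence_trust_slope: float = 0.15
    adherence_confidence_slope: float = -0.05
    adherence_sd: float = 0.20
    allow_negative_adherence: bool = False
    # probability the initial response lands in the truth's correct region
    skill: float = 0.63
    # SD of the truncated-normal initial response within its region
    response_sd: float = 12.0
    # questionnaire item generation: item = center + loading*latent + N(0, noise)
    item_loading: float = 0.8
    item_noise_sd: float = 0.6
    # per-check probability of failing an attention check
    attention_fail_rate: float = 0.0

    def validate(self) -> "BehaviorConfig":
        _require(0.0 <= self.skill <= 1.0, "skill", "must lie in [0, 1]")
        for name, sd in [
            ("experience_sd", self.experience_sd),
            ("trust_sd", self.trust_sd),
            ("adherence_sd", self.adherence_sd),
            ("response_sd", self.response_sd),
            ("item_noise_sd", self.item_noise_sd),
        ]:
            _require(sd >= 0.0, name, "must be >= 0")
        for name, sd in self.trait_sds.items():
            _require(sd >= 0.0, f"trait_sds[{name}]", "must be >= 0")
        lo, hi = self.experience_range
        _require(lo < hi, "experience_range", "needs lower < upper")
        _require(
            0.0 <= self.attention_fail_rate <= 1.0,
            "attention_fail_rate",
            "must lie in [0, 1]",
        )
        _require(
            set(self.trait_means) == set(self.trait_sds),
            "trait_means",
            "trait_means and trait_sds must name the same traits",
        )
        return self


@dataclass(frozen=True)
class CutoffRule:
    """Correctness and confidence cut-offs on the 0–100 slider.

    Responses are scored correct when they fall inside the truth's interval
    (inclusive at both ends); everything else — including the 41–60
    uncertainty band — is incorrect.  The confidence proxy is high (1) when
    the *initial* response lies in either extreme band.
    """

    malignant_correct: tuple[float, float] = (61.0, 100.0)
    benign_correct: tuple[float, float] = (1.0, 40.0)
    confidence_high: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 20.0),
        (80.0, 100.0),
    )

    def validate(self) -> "CutoffRule":
        for name, (lo, hi) in [
            ("malignant_correct", self.malignant_correct),
            ("benign_correct", self.benign_correct),
            ("confidence_high[0]", self.confidence_high[0]),
            ("confidence_high[1]", self.confidence_high[1]),
        ]:
            _require(0 <= lo <= hi <= 100, name, "must be an interval within [0, 100]")
        m_lo, m_hi = self.malignant_correct
        b_lo, b_hi = self.benign_correct
        _require(
            m_lo > b_hi or b_lo > m_hi,
            "malignant_correct",
            "malignant and benign correct intervals must be disjoint",
        )
        return self


@dataclass(frozen=True)
class ScaleDefinition:
    """One questionnaire scale: item count, response range, reverse-keyed items."""

    name: str
    n_items: int
    response_range: tuple[int, int] = (1, 5)
    reverse_items: tuple[int, ...] = ()  # zero-based item indices

    def validate(self) -> "ScaleDefinition":
        _require(self.n_items > 1, f"{self.name}.n_items", "must be > 1")
        lo, hi = self.response_range
        _require(lo < hi, f"{self.name}.response_range", "needs lower < upper")
        for i in self.reverse_items:
            _require(0 <= i < self.n_items, f"{self.name}.reverse_items", "index out of range")
        return self

    @property
    def item_columns(self) -> list[str]:
        return [f"{self.name}_{i + 1}" for i in range(self.n_items)]


#: The five questionnaires of the study design.  Trust in the system (5 items,
#: 5-point), propensity to trust technology (6 items, 5-point), affinity for
#: technology interaction (9 items, 6-point), control beliefs in dealing with
#: technology (8 items, 5-point), need for cognition (6 items, 5-point).
#: Reverse-key lists default to empty and are config-editable.
DEFAULT_SCALES: dict[str, ScaleDefinition] = {
    s.name: s.validate()
    for s in (
        ScaleDefinition("trust", 5, (1, 5)),
        ScaleDefinition("propensity", 6, (1, 5)),
        ScaleDefinition("affinity", 9, (1, 6)),
        ScaleDefinition("control_beliefs", 8, (1, 5)),
        ScaleDefinition("need_for_cognition", 6, (1, 5)),
    )
}

#: Latent trait feeding each non-trust scale's items.
SCALE_LATENT = {
    "propensity": "propensity",
    "affinity": "affinity",
    "control_beliefs": "control_beliefs",
    "need_for_cognition": "need_for_cognition",
}


@dataclass(frozen=True)
class InferenceConfig:
    """Settings for the hypothesis-testing layer."""

    n_boot: int = 5000
    alpha: float = 0.05
    experience_threshold: float = 5.0
    seed: int = 0

    def validate(self) -> "InferenceConfig":
        _require(self.n_boot >= 1, "n_boot", "must be >= 1")
        _require(0 < self.alpha < 1, "alpha", "must lie in (0, 1)")
        return self


@dataclass
class RunConfig:
    """Top-level pipeline configuration: simulate a cohort or ingest tables."""

    mode: str = "simulate"  # "simulate" | "ingest"
    trials_path: str | None = None
    participants_path: str | None = None
    design: DesignConfig = field(default_factory=DesignConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    cutoffs: CutoffRule = field(default_factory=CutoffRule)
    scales: dict[str, ScaleDefinition] = field(default_factory=lambda: dict(DEFAULT_SCALES))
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    exclusion_rule: str = "either"  # exclude on failing "either" or "both" checks
    out_dir: str = "results"

    def validate(self) -> "RunConfig":
        _require(self.mode in ("simulate", "ingest"), "mode", "must be 'simulate' or 'ingest'")
        if self.mode == "ingest":
            _require(self.trials_path is not None, "trials_path", "required in ingest mode")
        _require(
            self.exclusion_rule in ("either", "both"),
            "exclusion_rule",
            "must be 'either' or 'both'",
        )
        self.design.validate()
        self.behavior.validate()
        self.cutoffs.validate()
        self.inference.validate()
        for scale in self.scales.values():
            scale.validate()
        return self


def _coerce(cls: type, data: dict[str, Any]):
    """Build a dataclass from a plain dict, converting lists to tuples."""
    kwargs = {}
    names = {f.name for f in fields(cls)}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"{cls.__name__}.{key}: unknown field")
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def _parse_scales(raw: dict[str, Any] | None) -> dict[str, ScaleDefinition]:
    if not raw:
        return dict(DEFAULT_SCALES)
    scales = {}
    for name, spec_ in raw.items():
        scales[name] = _coerce(ScaleDefinition, {"name": name, **(spec_ or {})})
    return scales


def load_config(path: str) -> RunConfig:
    """Read a YAML run configuration; unknown fields raise :class:`ConfigError`."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(
        mode=raw.get("mode", "simulate"),
        trials_path=raw.get("trials_path"),
        participants_path=raw.get("participants_path"),
        design=_coerce(DesignConfig, raw.get("design", {})),
        behavior=_coerce(BehaviorConfig, raw.get("behavior", {})),
        cutoffs=_coerce(CutoffRule, raw.get("cutoffs", {})),
        scales=_parse_scales(raw.get("scales")),
        inference=_coerce(InferenceConfig, raw.get("inference", {})),
        exclusion_rule=raw.get("exclusion_rule", "either"),
        out_dir=raw.get("out_dir", "results"),
    )
    return cfg.validate()


def dump_config(cfg: RunConfig, path: str) -> None:
    """Write a run configuration to YAML, field-for-field."""
    payload = {
        "mode": cfg.mode,
        "trials_path": cfg.trials_path,
        "participants_path": cfg.participants_path,
        "design": asdict(cfg.design),
        "behavior": asdict(cfg.behavior),
        "cutoffs": asdict(cfg.cutoffs),
        "scales": {
            name: {k: v for k, v in asdict(s).items() if k != "name"}
            for name, s in cfg.scales.items()
        },
        "inference": asdict(cfg.inference),
        "exclusion_rule": cfg.exclusion_rule,
        "out_dir": cfg.out_dir,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
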