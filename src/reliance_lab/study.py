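"""Top-level study model: build from a dataset, ``fit()`` to get results.

``RelianceStudy`` ties the analysis chain together in the fixed stage order
exclude → derive → summarize → psychometrics → inference.  ``fit()`` returns a
:class:`StudyResults` object carrying the reliance summary, scale
reliabilities, and every hypothesis-level analysis (advice-correctness
contrast, trust→reliance regressions, confidence moderation, the five
trait/experience mediations through trust, and the experience subgroup
contrast), each either as a results block or an explicit skip reason.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .cohort import StudyDataset, simulate_study
from .config import (
    DEFAULT_SCALES,
    BehaviorConfig,
    CutoffRule,
    DesignConfig,
    InferenceConfig,
    ScaleDefinition,
)
from .dataset import ExclusionLog, apply_exclusions, dataset_checksums, read_dataset
from .inference import (
    DegenerateDataError,
    Mediation,
    Moderation,
    experience_split_contrast,
    ols,
    paired_t,
)
from .metrics import (
    RelianceSummary,
    derive_trials,
    per_participant_metrics,
    summarize_reliance,
)
from .psychometrics import score_participants

#: Mediation exposures: column in the analysis table → report label.
MEDIATION_FACTORS = {
    "propensity_score": "propensity_to_trust",
    "experience_years": "medical_experience",
    "affinity_score": "technology_affinity",
    "control_beliefs_score": "control_beliefs",
    "need_for_cognition_score": "need_for_cognition",
}

#: Reliance outcomes analysed in parallel (mean WoA is the primary one).
RELIANCE_DVS = ("mean_woa", "rair", "rsr")


def _sub_seed(master: int | None, index: int) -> int | None:
    """Deterministic per-analysis seed derived from the master seed."""
    if master is None:
        return None
    return int((int(master) * 10007 + index) % (2**31 - 1))


@dataclass
class StudyResults:
    """Fitted results of a :class:`RelianceStudy`.

    Attributes hold plain module outputs; :meth:`as_dict` renders the full
    JSON-ready report and :meth:`summary` a human-readable table.
    """

    provenance: dict[str, Any]
    exclusions: ExclusionLog
    reliance: RelianceSummary
    participant_metrics: pd.DataFrame
    scores: pd.DataFrame
    alphas: dict[str, float]
    hypotheses: dict[str, Any]
    analysis_table: pd.DataFrame

    def as_dict(self) -> dict:
        def render(block: Any) -> Any:
            if hasattr(block, "as_dict"):
                return render(block.as_dict())
            if isinstance(block, dict):
                return {k: render(v) for k, v in block.items()}
            if isinstance(block, (list, tuple)):
                return [render(v) for v in block]
            if isinstance(block, (float, np.floating)):
                # degenerate fits can surface NaN statistics; render as null
                return float(block) if np.isfinite(block) else None
            if isinstance(block, (np.integer, np.bool_)):
                return block.item()
            return block

        return render({
            "provenance": self.provenance,
            "exclusions": self.exclusions.as_dict(),
            "reliance_summary": self.reliance.as_dict(),
            "scale_reliability": {
                k: (None if np.isnan(v) else round(float(v), 4))
                for k, v in self.alphas.items()
            },
            "hypotheses": {k: render(v) for k, v in self.hypotheses.items()},
        })

    def summary(self) -> str:
        rel = self.reliance
        lines = [
            "Appropriate-reliance study report",
            "=" * 34,
            f"Cases: {rel.n_cases} ({self.exclusions.n_retained} participants retained "
            f"of {self.exclusions.n_total}, {self.exclusions.retention_percent:.1f}%)",
            "",
            "Reliance patterns (count, %):",
        ]
        for name, count in rel.counts.items():
            lines.append(f"  {name:<28} {count:>6}  {rel.percentages[name]:6.2f}%")
        rair_pct = "n/a" if np.isnan(rel.rair) else f"{100 * rel.rair:.2f}%"
        rsr_pct = "n/a" if np.isnan(rel.rsr) else f"{100 * rel.rsr:.1f}%"
        lines += [
            f"  RAIR = {rair_pct} ({rel.rair_numerator}/{rel.rair_denominator})"
            f"   RSR = {rsr_pct} ({rel.rsr_numerator}/{rel.rsr_denominator})",
            f"  accuracy: first {100 * rel.accuracy_first:.1f}% -> final "
            f"{100 * rel.accuracy_final:.1f}%",
            "",
        ]
        if self.alphas:
            lines.append("Scale reliability (Cronbach alpha):")
            for name, a in self.alphas.items():
                lines.append(f"  {name:<22} {a:.2f}" if np.isfinite(a) else f"  {name:<22} n/a")
            lines.append("")
        lines.append("Hypothesis-level analyses:")
        for key, block in self.hypotheses.items():
            if isinstance(block, dict) and "skipped" in block:
                lines.append(f"  {key}: skipped ({block['skipped']})")
            elif hasattr(block, "summary"):
                first = block.summary().splitlines()[0]
                lines.append(f"  {key}: {first}")
            elif hasattr(block, "as_dict"):
                d = block.as_dict()
                if "t" in d:
                    lines.append(
                        f"  {key}: t({d['df']:.0f}) = {d['t']:.2f}, p = {d['p']:.4g}, "
                        f"effect size = {d['effect_size']:.2f}"
                    )
                else:
                    lines.append(f"  {key}: {d}")
            elif isinstance(block, dict):
                for sub, res in block.items():
                    if isinstance(res, dict) and "skipped" in res:
                        lines.append(f"  {key}[{sub}]: skipped ({res['skipped']})")
                    elif hasattr(res, "as_dict"):
                        d = res.as_dict()
                        if "indirect" in d:
                            sig = "sig" if d["significant"] else "ns"
                            lines.append(
                                f"  {key}[{sub}]: indirect = {d['indirect']:.4f} "
                                f"CI [{d['indirect_ci'][0]:.4f}, {d['indirect_ci'][1]:.4f}] ({sig})"
                            )
                        elif "interaction" in d:
                            sig = "sig" if d["significant"] else "ns"
                            lines.append(
                                f"  {key}[{sub}]: interaction = {d['interaction']:.4f} "
                                f"CI [{d['interaction_ci'][0]:.4f}, "
                                f"{d['interaction_ci'][1]:.4f}] ({sig}), "
                                f"dR2 = {d['delta_r2']:.4f}"
                            )
                        elif "coef" in d:
                            slope = [v for k, v in d["coef"].items() if k != "const"]
                            pv = [v for k, v in d["p"].items() if k != "const"]
                            lines.append(
                                f"  {key}[{sub}]: beta = {slope[0]:.4f}, p = {pv[0]:.4g}, "
                                f"R2 = {d['r_squared']:.3f}"
                            )
        return "\n".join(lines)

    def save(self, out_dir: str) -> dict[str, str]:
        """Write report.json, summary.txt and the derived tables; returns paths."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        paths["report"] = os.path.join(out_dir, "report.json")
        with open(paths["report"], "w", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True, allow_nan=False)
            fh.write("\n")
        paths["summary"] = os.path.join(out_dir, "summary.txt")
        with open(paths["summary"], "w", encoding="utf-8") as fh:
            fh.write(self.summary() + "\n")
        paths["participant_metrics"] = os.path.join(out_dir, "participant_metrics.csv")
        self.participant_metrics.to_csv(paths["participant_metrics"], index=False)
        paths["scored_scales"] = os.path.join(out_dir, "scored_scales.csv")
        self.scores.to_csv(paths["scored_scales"], index=False)
        return paths

    def plot_reliance_patterns(self, ax=None):
        """Bar chart of the pattern percentages (diagnostic plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        names = list(self.reliance.percentages)
        vals = [self.reliance.percentages[n] for n in names]
        ax.bar(range(len(names)), vals)
        ax.set_xticks(range(len(names)))
        ax.set_xticklabels(names, rotation=45, ha="right", fontsize=8)
        ax.set_ylabel("% of cases")
        ax.set_title("Reliance patterns")
        return ax


class RelianceStudy:
    """Analysis model for a two-step advice-taking study dataset.

    Parameters
    ----------
    dataset : StudyDataset
        Trials long table plus participants wide table.
    cutoffs : CutoffRule, optional
        Correctness/confidence cut-offs.
    scales : dict of ScaleDefinition, optional
        Questionnaire definitions (defaults to the five study scales).
    exclusion_rule : {'either', 'both'}
        Attention-check exclusion policy.
    """

    def __init__(
        self,
        dataset: StudyDataset,
        cutoffs: CutoffRule | None = None,
        scales: dict[str, ScaleDefinition] | None = None,
        exclusion_rule: str = "either",
        provenance: dict[str, Any] | None = None,
    ):
        self.dataset = dataset
        self.cutoffs = (cutoffs or CutoffRule()).validate()
        self.scales = scales or DEFAULT_SCALES
        self.exclusion_rule = exclusion_rule
        self.provenance = provenance or {"source": "in-memory dataset"}
        self.provenance.setdefault("checksums", dataset_checksums(dataset))

    @classmethod
    def from_csv(
        cls,
        trials_path: str,
        participants_path: str | None = None,
        **kwargs,
    ) -> "RelianceStudy":
        dataset = read_dataset(trials_path, participants_path)
        prov = {
            "source": "ingest",
            "trials_path": trials_path,
            "participants_path": participants_path,
        }
        return cls(dataset, provenance=prov, **kwargs)

    @classmethod
    def simulate(
        cls,
        design: DesignConfig | None = None,
        behavior: BehaviorConfig | None = None,
        seed: int | None = None,
        **kwargs,
    ) -> "RelianceStudy":
        design = design or DesignConfig()
        if seed is not None:
            design = DesignConfig(**{**design.__dict__, "seed": int(seed)})
        dataset = simulate_study(design, behavior)
        prov = {"source": "simulate", "seed": design.seed}
        return cls(dataset, provenance=prov, **kwargs)

    # -- helpers ------------------------------------------------------------

    def _analysis_table(
        self, metrics: pd.DataFrame, scores: pd.DataFrame, participants: pd.DataFrame
    ) -> pd.DataFrame:
        table = metrics.merge(scores, on="participant_id", how="left")
        if "experience_years" in participants.columns:
            table = table.merge(
                participants[["participant_id", "experience_years"]],
                on="participant_id",
                how="left",
            )
        return table

    # -- fitting ------------------------------------------------------------

    def fit(self, inference: InferenceConfig | None = None) -> StudyResults:
        """Run the full analysis chain and return a :class:`StudyResults`."""
        cfg = (inference or InferenceConfig()).validate()
        data, exclusions = apply_exclusions(self.dataset, self.exclusion_rule)
        if len(data.trials) == 0:
            raise DegenerateDataError("no trials remain after exclusions")

        derived = derive_trials(data.trials, self.cutoffs)
        reliance = summarize_reliance(derived)
        metrics = per_participant_metrics(derived)
        scores, alphas = score_participants(data.participants, self.scales)
        table = self._analysis_table(metrics, scores, data.participants)

        hypotheses: dict[str, Any] = {}
        seed_ix = 0

        # advice-correctness contrast (paired within participant)
        try:
            hypotheses["advice_correctness_contrast"] = paired_t(
                table["mean_woa_correct_advice"], table["mean_woa_incorrect_advice"]
            )
        except DegenerateDataError as exc:
            hypotheses["advice_correctness_contrast"] = {"skipped": str(exc)}

        has_trust = "trust_score" in table.columns and table["trust_score"].notna().any()

        # trust → reliance regressions, one per DV
        block: dict[str, Any] = {}
        for dv in RELIANCE_DVS:
            if not has_trust:
                block[dv] = {"skipped": "no trust scale scores available"}
                continue
            try:
                block[dv] = ols(table[dv], table[["trust_score"]])
            except DegenerateDataError as exc:
                block[dv] = {"skipped": str(exc)}
        hypotheses["trust_reliance_regression"] = block

        # confidence moderation of trust → reliance
        block = {}
        for dv in RELIANCE_DVS:
            if not has_trust:
                block[dv] = {"skipped": "no trust scale scores available"}
                continue
            try:
                model = Moderation(table[dv], table["trust_score"], table["mean_confidence"])
                block[dv] = model.fit(
                    n_boot=cfg.n_boot, seed=_sub_seed(cfg.seed, seed_ix)
                )
            except DegenerateDataError as exc:
                block[dv] = {"skipped": str(exc)}
            seed_ix += 1
        hypotheses["confidence_moderation"] = block

        # trait/experience → trust → reliance mediations
        for col, label in MEDIATION_FACTORS.items():
            block = {}
            for dv in RELIANCE_DVS:
                if not has_trust:
                    block[dv] = {"skipped": "no trust scale scores available"}
                elif col not in table.columns or table[col].isna().all():
                    block[dv] = {"skipped": f"no {label} measurements available"}
                else:
                    try:
                        model = Mediation.from_dataframe(
                            table.rename(columns={col: label}),
                            exposure=label,
                            mediator="trust_score",
                            outcome=dv,
                        )
                        block[dv] = model.fit(
                            n_boot=cfg.n_boot, seed=_sub_seed(cfg.seed, seed_ix)
                        )
                    except DegenerateDataError as exc:
                        block[dv] = {"skipped": str(exc)}
                seed_ix += 1
            hypotheses[f"mediation_{label}"] = block

        # experience subgroup contrast on accuracy improvement
        if "experience_years" in table.columns and table["experience_years"].notna().any():
            try:
                contrast, sizes = experience_split_contrast(
                    table, threshold_years=cfg.experience_threshold
                )
                hypotheses["experience_subgroup_contrast"] = {
                    "test": contrast,
                    "groups": sizes,
                }
            except DegenerateDataError as exc:
                hypotheses["experience_subgroup_contrast"] = {"skipped": str(exc)}
        else:
            hypotheses["experience_subgroup_contrast"] = {
                "skipped": "no experience measurements available"
            }

        provenance = dict(self.provenance)
        provenance["inference"] = {
            "n_boot": cfg.n_boot,
            "alpha": cfg.alpha,
            "seed": cfg.seed,
            "experience_threshold": cfg.experience_threshold,
        }
        return StudyResults(
            provenance=provenance,
            exclusions=exclusions,
            reliance=reliance,
            participant_metrics=metrics,
            scores=scores,
            alphas=alphas,
            hypotheses=hypotheses,
            analysis_table=table,
        )
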