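"""Measurement layer: weight of advice, cut-off scoring, confidence proxy,
pattern taxonomy and pooled/per-participant reliance metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import reliance_lab as rl
from reliance_lab.metrics import PATTERN_BY_TRIPLE, ReliancePattern

sliders = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)


class TestWeightOfAdvice:
    @pytest.mark.parametrize(
        "r1, advice, r2, expected",
        [
            (70.0, 83.0, 83.0, 1.0),   # moved exactly onto the advice
            (70.0, 83.0, 70.0, 0.0),   # no change
            (50.0, 60.0, 90.0, 1.0),   # raw ratio 4.0 clipped to 1
            (50.0, 60.0, 40.0, -1.0),  # moved away, clipped at -1
            (80.0, 60.0, 70.0, 0.5),   # halfway toward the advice
        ],
    )
    def test_worked_examples(self, r1, advice, r2, expected):
        assert rl.weight_of_advice(r1, advice, r2) == pytest.approx(expected)

    def test_undefined_when_advice_equals_initial(self):
        assert np.isnan(rl.weight_of_advice(70.0, 70.0, 60.0))

    @pytest.mark.parametrize("bad", [(-1, 50, 50), (50, 101, 50), (50, 50, 120)])
    def test_domain_error_outside_slider(self, bad):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            rl.weight_of_advice(*bad)

    def test_vectorized_matches_scalar(self, rng):
        r1 = rng.uniform(0, 100, 50)
        adv = rng.uniform(0, 100, 50)
        r2 = rng.uniform(0, 100, 50)
        vec = rl.weight_of_advice(r1, adv, r2)
        for i in range(50):
            scalar = rl.weight_of_advice(r1[i], adv[i], r2[i])
            assert (np.isnan(vec[i]) and np.isnan(scalar)) or vec[i] == pytest.approx(scalar)

    @given(r1=sliders, advice=sliders, r2=sliders,
           scale=st.floats(min_value=0.1, max_value=0.9),
           shift=st.floats(min_value=0.0, max_value=10.0))
    @settings(max_examples=200, derandomize=True)
    def test_affine_invariance(self, r1, advice, r2, scale, shift):
        """Rescaling all three inputs by one positive affine map preserves WoA."""
        assume(abs(advice - r1) > 1e-6)  # far from the undefined diagonal
        base = rl.weight_of_advice(r1, advice, r2)
        mapped = rl.weight_of_advice(
            scale * r1 + shift, scale * advice + shift, scale * r2 + shift
        )
        assert mapped == pytest.approx(base, abs=1e-6)

    @given(r1=sliders, advice=sliders)
    @settings(max_examples=200, derandomize=True)
    def test_unit_weight_iff_final_equals_advice(self, r1, advice):
        """Unclipped WoA is exactly 1 iff the final response equals the advice."""
        if advice == r1:
            return
        assert rl.weight_of_advice(r1, advice, advice) == pytest.approx(1.0)
        # raw ratio of 1 forces r2 == advice algebraically
        r2 = r1 + 1.0 * (advice - r1)
        assert r2 == pytest.approx(advice)

    @given(r1=sliders, advice=sliders)
    @settings(max_examples=200, derandomize=True)
    def test_zero_weight_iff_no_change(self, r1, advice):
        if advice == r1:
            return
        assert rl.weight_of_advice(r1, advice, r1) == 0.0


class TestCutoffScoring:
    @pytest.mark.parametrize(
        "response, truth, expected",
        [
            (70.0, "malignant", True),
            (61.0, "malignant", True),   # inclusive lower bound
            (60.9, "malignant", False),
            (100.0, "malignant", True),
            (40.0, "benign", True),      # inclusive upper bound
            (45.0, "benign", False),
            (1.0, "benign", True),
            (0.0, "benign", False),      # literal printed interval starts at 1
            (50.0, "benign", False),     # midzone incorrect for both truths
            (50.0, "malignant", False),
        ],
    )
    def test_default_rule(self, response, truth, expected):
        assert rl.is_correct(response, truth) is expected

    def test_widened_benign_interval_is_a_config_choice(self):
        widened = rl.CutoffRule(benign_correct=(0.0, 40.0))
        assert rl.is_correct(0.0, "benign", widened) is True

    def test_unknown_truth_label(self):
        with pytest.raises(ValueError, match="unknown truth"):
            rl.is_correct(50.0, "equivocal")

    @pytest.mark.parametrize(
        "r1, expected", [(85.0, 1), (50.0, 0), (20.0, 1), (21.0, 0), (80.0, 1), (79.0, 0), (0.0, 1)]
    )
    def test_confidence_proxy(self, r1, expected):
        assert rl.confidence_proxy(r1) == expected


class TestPatternTaxonomy:
    @pytest.mark.parametrize(
        "triple, label",
        [
            ((0, 0, 0), "detrimental reliance"),
            ((0, 0, 1), "beneficial underreliance"),
            ((0, 1, 0), "detrimental self-reliance"),
            ((0, 1, 1), "beneficial overreliance"),
            ((1, 0, 0), "detrimental overreliance"),
            ((1, 0, 1), "beneficial self-reliance"),
            ((1, 1, 0), "detrimental underreliance"),
            ((1, 1, 1), "beneficial reliance"),
        ],
    )
    def test_bijection_with_triples(self, triple, label):
        assert rl.classify_pattern(*triple).value == label

    def test_eight_distinct_labels(self):
        labels = {rl.classify_pattern(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)}
        assert len(labels) == 8

    def test_exhaustive_over_integer_grid(self):
        """Every (response_1, advice, response_2) x truth combination gets a
        pattern, and the per-pattern counts sum to the grid size."""
        grid = np.arange(0, 101, 5.0)  # coarse grid; correctness only depends on region
        r1, adv, r2 = (g.ravel() for g in np.meshgrid(grid, grid, grid))
        for truth in ("benign", "malignant"):
            truths = np.full(r1.shape, truth)
            c1 = rl.is_correct(r1, truths).astype(int)
            c2 = rl.is_correct(r2, truths).astype(int)
            for adv_ok in (0, 1):
                keys = list(zip(c1, np.full_like(c1, adv_ok), c2))
                patterns = [PATTERN_BY_TRIPLE[k] for k in keys]
                assert len(patterns) == r1.size


class TestSummarizeReliance:
    def test_reference_counts_reproduce_published_rates(self, reference_fixture):
        summary = rl.summarize_reliance(rl.derive_trials(reference_fixture))
        assert summary.n_cases == 5352
        assert round(100 * summary.rair, 2) == 10.04
        assert round(100 * summary.rsr, 1) == 85.6
        assert summary.rair_numerator == 139 and summary.rair_denominator == 1384
        assert summary.rsr_numerator == 487 and summary.rsr_denominator == 569

    def test_percentages_match_published_table(self, reference_fixture):
        summary = rl.summarize_reliance(rl.derive_trials(reference_fixture))
        expected = {
            "detrimental reliance": 10.15,
            "beneficial underreliance": 0.06,
            "detrimental self-reliance": 23.26,
            "beneficial overreliance": 2.60,
            "detrimental overreliance": 1.53,
            "beneficial self-reliance": 9.10,
            "detrimental underreliance": 0.11,
            "beneficial reliance": 53.20,
        }
        assert summary.rounded_percentages(2) == pytest.approx(expected)
        assert sum(summary.counts.values()) == summary.n_cases
        assert sum(summary.percentages.values()) == pytest.approx(100.0)

    def test_all_correct_trials_leave_rair_rsr_undefined(self):
        trials = rl.pattern_fixture_trials({(1, 1, 1): 24}, n_participants=1)
        summary = rl.summarize_reliance(rl.derive_trials(trials))
        assert np.isnan(summary.rair) and np.isnan(summary.rsr)
        assert summary.accuracy_final == 1.0

    def test_one_case_per_pattern(self):
        counts = {t: 1 for t in PATTERN_BY_TRIPLE}
        summary = rl.summarize_reliance(rl.derive_trials(rl.pattern_fixture_trials(counts, 1)))
        assert all(p == pytest.approx(12.5) for p in summary.percentages.values())
        assert summary.rair == pytest.approx(0.5)
        assert summary.rsr == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rl.summarize_reliance(rl.derive_trials(rl.pattern_fixture_trials()).iloc[:0])

    def test_accuracy_identity_from_counts(self, rng):
        """accuracy_final - accuracy_first equals the net beneficial-vs-detrimental
        switch balance over n_cases."""
        counts = {t: int(k) for t, k in zip(sorted(PATTERN_BY_TRIPLE),
                                            rng.integers(1, 50, size=8))}
        summary = rl.summarize_reliance(rl.derive_trials(rl.pattern_fixture_trials(counts, 1)))
        gains = counts[(0, 0, 1)] + counts[(0, 1, 1)]
        losses = counts[(1, 0, 0)] + counts[(1, 1, 0)]
        expected = (gains - losses) / summary.n_cases
        assert summary.accuracy_final - summary.accuracy_first == pytest.approx(expected)


class TestPerParticipantMetrics:
    def test_never_moving_participant(self):
        # advice always differs from the initial response; final == initial
        trials = pd.DataFrame(
            {
                "participant_id": 0,
                "trial": range(4),
                "truth": ["malignant", "malignant", "benign", "benign"],
                "advice": [80.0, 20.0, 20.0, 80.0],
                "advice_correct": [True, False, True, False],
                "response_1": [30.0, 70.0, 30.0, 30.0],
                "response_2": [30.0, 70.0, 30.0, 30.0],
            }
        )
        row = rl.per_participant_metrics(rl.derive_trials(trials)).iloc[0]
        assert row["mean_woa"] == 0.0
        assert row["rair"] == 0.0   # had a convertible case, never converted
        assert row["rsr"] == 1.0    # kept the initially-correct decision

    def test_full_adherence_participant(self):
        trials = pd.DataFrame(
            {
                "participant_id": 1,
                "trial": range(3),
                "truth": "malignant",
                "advice": [80.0, 76.0, 84.0],
                "advice_correct": True,
                "response_1": [30.0, 50.0, 90.0],
                "response_2": [80.0, 76.0, 84.0],
            }
        )
        row = rl.per_participant_metrics(rl.derive_trials(trials)).iloc[0]
        assert row["mean_woa"] == pytest.approx(1.0)

    def test_zero_defined_woa_yields_missing_mean(self):
        trials = pd.DataFrame(
            {
                "participant_id": 2,
                "trial": [0],
                "truth": ["malignant"],
                "advice": [80.0],
                "advice_correct": [True],
                "response_1": [80.0],  # advice == response_1: WoA undefined
                "response_2": [90.0],
            }
        )
        row = rl.per_participant_metrics(rl.derive_trials(trials)).iloc[0]
        assert np.isnan(row["mean_woa"])
        assert row["n_woa_defined"] == 0

    def test_pooled_equals_recombined_participant_counts(self, default_dataset):
        """Case-pooled RAIR/RSR equal the recombination of per-participant
        numerators and denominators on a full synthetic cohort."""
        derived = rl.derive_trials(default_dataset.trials)
        pooled = rl.summarize_reliance(derived)
        per = rl.per_participant_metrics(derived)
        num = den = 0
        for _, grp in derived.groupby("participant_id"):
            c1 = grp["correct_1"].astype(bool)
            adv = grp["advice_correct"].astype(bool)
            c2 = grp["correct_2"].astype(bool)
            num += int((~c1 & adv & c2).sum())
            den += int((~c1 & adv).sum())
        assert pooled.rair == pytest.approx(num / den)
        assert len(per) == default_dataset.participants.shape[0]
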