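"""Training and naive Bayes scoring."""

import math

import pytest

from msirepeat.classifier import (
    classify_cohort,
    marker_factor,
    score_sample,
    train,
)
from msirepeat.datamodel import (
    MSI_H,
    MSS,
    NOT_ASSESSABLE,
    MarkerParameters,
    SampleRecord,
    TrainedModel,
    ValidationError,
)

from conftest import frac_observation, make_observation, make_sample

LOG_PRIOR = math.log10(0.15 / 0.85)


def tiny_cohort(marker_id="LRT8"):
    """Hand-countable cohort: 3 MSS and 3 MSI-H samples at one marker."""
    cohort = []
    for i, f in enumerate((0.01, 0.02, 0.03)):
        cohort.append(
            make_sample(f"mss{i}", MSS, [frac_observation(marker_id, f)])
        )
    for i, f in enumerate((0.5, 0.6, 0.7)):
        cohort.append(
            make_sample(f"msi{i}", MSI_H, [frac_observation(marker_id, f)])
        )
    return cohort


class TestTrain:
    def test_hand_countable_threshold_and_exceedance(self, marker_8a):
        model = train(tiny_cohort(marker_8a.marker_id), [marker_8a])
        params = model.markers[marker_8a.marker_id]
        assert params.threshold == pytest.approx(0.03)
        assert params.counts["d_msi"] == (3, 3)
        assert params.counts["d_mss"] == (0, 3)
        assert params.p_d_msi == pytest.approx(4 / 5)  # Laplace smoothed
        assert params.p_d_mss == pytest.approx(1 / 5)
        # no heterozygous SNP anywhere: bias parameters unavailable
        assert not params.bias_available

    def test_single_class_cohort_rejected(self, marker_8a):
        cohort = [
            make_sample("s", MSS, [frac_observation(marker_8a.marker_id, 0.01)])
        ]
        with pytest.raises(ValidationError, match="both classes"):
            train(cohort, [marker_8a])

    def test_marker_without_usable_mss_dropped(self, marker_8a, marker_12a):
        cohort = tiny_cohort(marker_8a.marker_id)
        # marker_12a observed only in MSI-H samples
        for sample in cohort:
            if sample.label == MSI_H:
                sample.observations[marker_12a.marker_id] = frac_observation(
                    marker_12a.marker_id, 0.5
                )
        model = train(cohort, [marker_8a, marker_12a])
        assert marker_12a.marker_id not in model.markers
        assert model.provenance["dropped_markers"] == [marker_12a.marker_id]

    def test_smoothed_probabilities_from_exceedance_counts(self):
        # 58 of 66 MSI-H samples above threshold -> smoothed 59/68
        assert (58 + 1) / (66 + 2) == pytest.approx(0.8676, abs=5e-5)
        cohort = []
        for i in range(66):
            f = 0.5 if i < 58 else 0.0
            cohort.append(make_sample(f"m{i}", MSI_H, [frac_observation("x", f, depth=1000)]))
        for i in range(72):
            # distinct low MSS fractions: nearest-rank 95% threshold is the
            # 69th order statistic, leaving exactly 3 of 72 above it
            cohort.append(
                make_sample(f"s{i}", MSS, [frac_observation("x", (i + 1) / 1000, depth=1000)])
            )
        from msirepeat.datamodel import MarkerDefinition

        marker = MarkerDefinition("x", "c", 101, 12, "A", (61, 180))
        model = train(cohort, [marker])
        params = model.markers["x"]
        assert params.threshold == pytest.approx(0.069)
        assert params.counts["d_msi"] == (58, 66)
        assert params.counts["d_mss"] == (3, 72)
        assert params.p_d_msi == pytest.approx(59 / 68)
        assert params.p_d_mss == pytest.approx(4 / 74)


def params_59_68() -> MarkerParameters:
    return MarkerParameters(
        "x", threshold=0.24, p_d_msi=59 / 68, p_d_mss=5 / 74,
        p_b_msi=None, p_b_mss=None,
    )


class TestMarkerFactor:
    def test_deletion_factor_above_threshold(self):
        obs = frac_observation("x", 0.5)
        contribution = marker_factor(obs, params_59_68(), 0.05)
        assert contribution.d is True
        expected = math.log10((59 / 68) / (5 / 74))
        assert contribution.log10_factor == pytest.approx(expected)
        assert contribution.log10_factor == pytest.approx(1.108, abs=1e-3)

    def test_equal_probabilities_contribute_zero(self):
        params = MarkerParameters("x", 0.1, 0.4, 0.4, None, None)
        for f in (0.05, 0.5):
            c = marker_factor(frac_observation("x", f), params, 0.05)
            assert c.log10_factor == pytest.approx(0.0)

    def test_bias_ignored_below_threshold(self):
        params = MarkerParameters(
            "x", 0.24, 59 / 68, 5 / 74, p_b_msi=0.9, p_b_mss=0.1
        )
        # heavily biased allele table, but deletion fraction below threshold
        obs = make_observation(
            "x", {-1: 10, 0: 90},
            {"rs1": {"G": {-1: 10, 0: 40}, "A": {0: 50}}},
        )
        c = marker_factor(obs, params, 0.05)
        assert c.d is False and c.b is None
        expected = math.log10((1 - 59 / 68) / (1 - 5 / 74))
        assert c.log10_factor == pytest.approx(expected)

    def test_bias_term_added_when_significant(self):
        params = MarkerParameters(
            "x", 0.1, 0.8, 0.1, p_b_msi=0.9, p_b_mss=0.2
        )
        obs = make_observation(
            "x", {-1: 40, 0: 60},
            {"rs1": {"G": {-1: 38, 0: 12}, "A": {-1: 2, 0: 48}}},
        )
        c = marker_factor(obs, params, 0.05)
        assert c.d is True and c.b is True and c.snp_id == "rs1"
        assert c.bias_p < 0.05
        expected = math.log10(0.8 / 0.1) + math.log10(0.9 / 0.2)
        assert c.log10_factor == pytest.approx(expected)

    def test_lowest_p_snp_selected(self):
        params = MarkerParameters("x", 0.1, 0.8, 0.1, p_b_msi=0.9, p_b_mss=0.2)
        obs = make_observation(
            "x", {-1: 40, 0: 60},
            {
                "rs_weak": {"G": {-1: 22, 0: 28}, "A": {-1: 18, 0: 32}},
                "rs_strong": {"C": {-1: 38, 0: 12}, "T": {-1: 2, 0: 48}},
            },
        )
        c = marker_factor(obs, params, 0.05)
        assert c.snp_id == "rs_strong"

    def test_unusable_observation_skipped(self):
        c = marker_factor(frac_observation("x", 0.5, depth=10), params_59_68(), 0.05)
        assert not c.used and c.log10_factor is None

    def test_bias_unavailable_parameters_skip_term(self):
        obs = make_observation(
            "x", {-1: 40, 0: 60},
            {"rs1": {"G": {-1: 38, 0: 12}, "A": {-1: 2, 0: 48}}},
        )
        c = marker_factor(obs, params_59_68(), 0.05)
        assert c.b is None
        assert c.log10_factor == pytest.approx(
            math.log10((59 / 68) / (5 / 74))
        )


class TestScoreSample:
    def test_prior_only_baseline(self):
        model = TrainedModel(markers={"x": params_59_68()})
        sample = SampleRecord("empty")
        result = score_sample(sample, model, min_markers=0)
        assert result.score == model.log10_prior_odds
        assert result.score == pytest.approx(LOG_PRIOR)
        assert result.score == pytest.approx(-0.7533, abs=1e-4)
        assert result.call == MSS

    def test_prior_plus_single_factor(self):
        model = TrainedModel(markers={"x": params_59_68()})
        sample = make_sample("s", "unknown", [frac_observation("x", 0.5)])
        result = score_sample(sample, model)
        expected = LOG_PRIOR + math.log10((59 / 68) / (5 / 74))
        assert result.score == pytest.approx(expected)
        assert result.score == pytest.approx(0.355, abs=1e-3)
        assert result.call == MSI_H

    def test_score_zero_called_mss(self):
        params = MarkerParameters("x", 0.1, 0.4, 0.4, None, None)
        model = TrainedModel(
            markers={"x": params}, prior_msi=0.5, prior_mss=0.5
        )
        result = score_sample(
            make_sample("s", "unknown", [frac_observation("x", 0.5)]), model
        )
        assert result.score == 0.0
        assert result.call == MSS

    def test_below_min_markers_not_assessable(self):
        model = TrainedModel(markers={"x": params_59_68()})
        result = score_sample(SampleRecord("empty"), model, min_markers=1)
        assert result.call == NOT_ASSESSABLE
        assert result.score is None
        assert "0 usable markers" in result.reason

    def test_score_additivity_and_marker_removal(self):
        p1 = params_59_68()
        p2 = MarkerParameters("y", 0.05, 0.7, 0.2, None, None)
        model = TrainedModel(markers={"x": p1, "y": p2})
        sample = make_sample(
            "s", "unknown",
            [frac_observation("x", 0.5), frac_observation("y", 0.01)],
        )
        result = score_sample(sample, model)
        factors = [
            c.log10_factor for c in result.contributions if c.used
        ]
        assert result.score == pytest.approx(
            model.log10_prior_odds + sum(factors), abs=1e-9
        )
        removed = make_sample("s", "unknown", [frac_observation("x", 0.5)])
        result_removed = score_sample(removed, model)
        y_factor = next(
            c.log10_factor for c in result.contributions if c.marker_id == "y"
        )
        assert result.score - result_removed.score == pytest.approx(
            y_factor, abs=1e-9
        )


class TestClassifyCohort:
    def test_self_classification_summary_and_determinism(
        self, marker_8a, marker_12a
    ):
        # two concordant markers: their summed evidence (2 * log10 4) beats
        # the 0.15/0.85 prior penalty, one alone would not
        cohort = tiny_cohort(marker_8a.marker_id)
        for sample in cohort:
            frac = next(iter(sample.observations.values()))
            sample.observations[marker_12a.marker_id] = frac_observation(
                marker_12a.marker_id, frac.histogram.deletion_fraction
            )
        model = train(cohort, [marker_8a, marker_12a])
        results_a, summary = classify_cohort(cohort, model)
        results_b, _ = classify_cohort(cohort, model)
        assert [r.score for r in results_a] == [r.score for r in results_b]
        assert summary["n"] == 6
        assert summary["sensitivity"] == 1.0
        assert summary["specificity"] == 1.0
        lo, hi = summary["sensitivity_ci"]
        assert 0.0 <= lo <= 1.0 == hi

    def test_empty_cohort(self, marker_8a):
        model = train(tiny_cohort(marker_8a.marker_id), [marker_8a])
        results, summary = classify_cohort([], model)
        assert results == [] and summary is None
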