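"""Synthetic cohort generation, aggregation and satisfaction summaries."""

import dataclasses

import numpy as np
import pytest

from neocea import (
    CohortConfig,
    HORIZON_1MO,
    HORIZON_2MO,
    PatientRecord,
    aggregate_outcomes,
    effectiveness,
    fit_likert_distribution,
    generate_cohort,
    read_cohort_csv,
    summarize_satisfaction,
    write_cohort_csv,
)


def _record(i, arm="intervention", **overrides):
    fields = dict(
        patient_id=f"{arm[0].upper()}{i:04d}",
        arm=arm,
        ed_visit_1mo=False,
        ed_visit_2mo=False,
        hospital_visit=arm == "control",
        questionnaires_answered=0,
        emails_sent=0,
        satisfaction=None,
    )
    fields.update(overrides)
    return PatientRecord(**fields)


class TestGeneration:
    def test_same_seed_reproduces_cohort_exactly(self):
        config = CohortConfig(seed=42)
        assert generate_cohort(config) == generate_cohort(config)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(seed=1))
        b = generate_cohort(CohortConfig(seed=2))
        assert a != b

    def test_zero_probabilities_give_no_events(self):
        config = CohortConfig(
            p_ed_1mo_control=0.0, p_ed_1mo_intervention=0.0,
            p_ed_2mo_control=0.0, p_ed_2mo_intervention=0.0, seed=7,
        )
        cohort = generate_cohort(config)
        assert not any(r.ed_visit_1mo or r.ed_visit_2mo for r in cohort)

    def test_horizons_are_nested_in_every_record(self):
        for seed in (0, 1, 2):
            for record in generate_cohort(CohortConfig(seed=seed)):
                assert record.ed_visit_2mo or not record.ed_visit_1mo

    def test_control_arm_structural_invariants(self):
        cohort = generate_cohort(CohortConfig(seed=3))
        for record in cohort:
            if record.arm == "control":
                assert record.hospital_visit
                assert record.questionnaires_answered == 0
                assert record.emails_sent == 0
                assert record.satisfaction is None

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            generate_cohort(CohortConfig(), mode="bootstrap")

    def test_parameter_recovery_at_large_n(self):
        """With 10,000 patients per arm every configured probability is
        recovered by its empirical rate to within 2 percentage points."""
        config = CohortConfig(
            n_control=10_000, n_intervention=10_000,
            n_enrolled_intervention=10_000, seed=12345,
        )
        cohort = generate_cohort(config)
        control = [r for r in cohort if r.arm == "control"]
        intervention = [r for r in cohort if r.arm == "intervention"]
        checks = [
            (np.mean([r.ed_visit_1mo for r in control]), config.p_ed_1mo_control),
            (np.mean([r.ed_visit_2mo for r in control]), config.p_ed_2mo_control),
            (np.mean([r.ed_visit_1mo for r in intervention]), config.p_ed_1mo_intervention),
            (np.mean([r.ed_visit_2mo for r in intervention]), config.p_ed_2mo_intervention),
            (np.mean([r.hospital_visit for r in intervention]),
             config.p_hospital_visit_intervention),
            (np.mean([r.satisfaction is not None for r in intervention]),
             config.response_rate),
        ]
        for observed, expected in checks:
            assert abs(observed - expected) < 0.02

    def test_scaled_cohort_concentrates_on_configured_rate(self):
        """Binomial concentration: at 11,400 control patients the 1-month
        rate lands within one percentage point of 18/114."""
        config = CohortConfig(n_control=11_400, seed=2024)
        control = [r for r in generate_cohort(config) if r.arm == "control"]
        rate = np.mean([r.ed_visit_1mo for r in control])
        assert abs(rate - 18 / 114) < 0.01

    @pytest.mark.parametrize(
        "overrides",
        [
            dict(p_ed_1mo_control=1.2),
            dict(p_ed_2mo_control=0.05),  # below the 1-month default
            dict(n_control=0),
            dict(likert_sd=-1.0),
        ],
    )
    def test_invalid_configs_rejected_before_any_draw(self, overrides):
        with pytest.raises(ValueError):
            CohortConfig(**overrides)


class TestFixtureMode:
    def test_reference_counts_are_exact(self):
        cohort = generate_cohort(CohortConfig(), mode="fixture")
        t1 = aggregate_outcomes(cohort, HORIZON_1MO)
        t2 = aggregate_outcomes(cohort, HORIZON_2MO)
        assert (t1.a, t1.b, t1.c, t1.d) == (18, 96, 5, 85)
        assert (t2.a, t2.b, t2.c, t2.d) == (29, 85, 7, 83)
        assert sum(r.hospital_visit for r in cohort if r.arm == "intervention") == 32
        assert sum(r.questionnaires_answered for r in cohort) == 382
        assert sum(r.emails_sent for r in cohort) == 90
        assert sum(r.satisfaction is not None for r in cohort) == 43

    def test_reference_effectiveness_column(self):
        cohort = generate_cohort(CohortConfig(), mode="fixture")
        table = aggregate_outcomes(cohort, HORIZON_1MO)
        assert round(effectiveness(table.c, table.n_intervention), 3) == 0.944
        assert round(effectiveness(table.a, table.n_control), 3) == 0.842

    def test_fixture_mode_is_deterministic(self):
        assert generate_cohort(CohortConfig(seed=1), "fixture") == generate_cohort(
            CohortConfig(seed=99), "fixture"
        )


class TestAggregation:
    def test_manual_tally(self):
        cohort = [
            _record(1, "control", ed_visit_1mo=True, ed_visit_2mo=True),
            _record(2, "control", ed_visit_2mo=True),
            _record(3, "control"),
            _record(4),
            _record(5, ed_visit_1mo=True, ed_visit_2mo=True),
            _record(6),
        ]
        t1 = aggregate_outcomes(cohort, HORIZON_1MO)
        assert (t1.a, t1.b, t1.c, t1.d) == (1, 2, 1, 2)
        t2 = aggregate_outcomes(cohort, HORIZON_2MO)
        assert (t2.a, t2.b, t2.c, t2.d) == (2, 1, 1, 2)

    def test_margins_equal_arm_sizes(self):
        config = CohortConfig(seed=5)
        table = aggregate_outcomes(generate_cohort(config), HORIZON_1MO)
        assert table.n_control == config.n_control
        assert table.n_intervention == config.n_intervention

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            aggregate_outcomes([_record(1, "control")], HORIZON_1MO)

    def test_unknown_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            aggregate_outcomes([_record(1), _record(2, "control")], "6 weeks")


class TestSatisfaction:
    def test_constant_scores(self):
        cohort = [_record(i, satisfaction=5) for i in range(4)]
        assert summarize_satisfaction(cohort) == (5.0, 0.0, 4)

    def test_hand_computed_summary(self):
        cohort = [_record(i, satisfaction=s) for i, s in enumerate([4, 5, 3])]
        mean, sd, n = summarize_satisfaction(cohort)
        assert (mean, sd, n) == (4.0, 1.0, 3)

    def test_no_responders_rejected(self):
        with pytest.raises(ValueError, match="responders"):
            summarize_satisfaction([_record(1)])

    def test_large_n_mean_matches_configured_target(self):
        config = CohortConfig(
            n_intervention=20_000, n_enrolled_intervention=20_000, seed=777
        )
        mean, sd, n = summarize_satisfaction(generate_cohort(config))
        assert abs(mean - 4.3) < 0.1
        assert abs(sd - 0.9) < 0.1

    def test_moment_matched_distribution_hits_targets(self):
        probs = np.array(fit_likert_distribution(4.3, 0.9))
        scores = np.arange(6)
        mean = probs @ scores
        sd = np.sqrt(probs @ (scores - mean) ** 2)
        assert probs.sum() == pytest.approx(1.0)
        assert mean == pytest.approx(4.3, abs=1e-6)
        assert sd == pytest.approx(0.9, abs=1e-6)


class TestCohortCsv:
    def test_round_trip(self, tmp_path):
        cohort = generate_cohort(CohortConfig(seed=11))
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        assert read_cohort_csv(path) == cohort
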