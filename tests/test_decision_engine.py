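"""Matrix lookup, MoE verdicts, recommendations and full assessment."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from namtier.decision_engine import (
    Colour,
    DEFAULT_MATRIX,
    MatrixConfig,
    Recommendation,
    TierConfidence,
    Verdict,
    assess,
    matrix_lookup,
    moe_verdict,
    recommend_next,
)
from namtier.dossier_io import (
    DossierPoD,
    Scenario,
    ScenarioExposure,
    ScenarioSet,
    AssessmentStep,
    SubstanceDossier,
)
from namtier.exposure_categories import DurationClass, ExposureCategory
from namtier.hazard_bands import Endpoint, NOT_CLASSIFIED, PodType, Tier
from namtier.intervals import DoseInterval
from namtier.ttc_screen import CramerClass, TTCFlags


class TestMatrixLookup:
    @pytest.mark.parametrize(
        "hazard, exposure, colour",
        [
            (1, "B", "red"),
            (1, "D", "amber"),
            (1, "E", "green"),
            (2, "A", "red"),
            (2, "C", "amber"),
            (3, "C", "green"),
            (4, "B", "green"),
            (NOT_CLASSIFIED, "B", "green"),
        ],
    )
    def test_default_cells(self, hazard, exposure, colour):
        got = matrix_lookup(hazard, ExposureCategory(exposure))
        assert got == Colour(colour)

    def test_category_a_needs_limit_dose_clearance_for_green(self):
        amber = matrix_lookup(4, ExposureCategory.A)
        green = matrix_lookup(4, ExposureCategory.A, limit_dose_cleared=True)
        assert (amber, green) == (Colour.amber, Colour.green)

    def test_default_matrix_is_monotone(self):
        rank = {Colour.green: 0, Colour.amber: 1, Colour.red: 2}
        cats = list(ExposureCategory)
        for row in (1, 2, 3, 4):
            colours = [rank[matrix_lookup(row, c)] for c in cats]
            assert colours == sorted(colours, reverse=True)
        for cat in cats:
            colours = [rank[matrix_lookup(row, cat)] for row in (1, 2, 3, 4)]
            assert colours == sorted(colours, reverse=True)

    def test_non_monotone_config_rejected_at_load(self):
        cells = {k: dict(v) for k, v in DEFAULT_MATRIX.cells.items()}
        cells[1] = dict(cells[1])
        cells[1][ExposureCategory.E] = Colour.red  # worsens toward E
        with pytest.raises(ValueError, match="monotone"):
            MatrixConfig(cells=cells)


class TestMoEVerdict:
    def test_tier3_margin_acceptable(self):
        # targeted in vivo DNEL 0.04 against refined exposures
        for exposure in (0.004, 0.002):
            result = moe_verdict(
                DoseInterval.point(0.04), DoseInterval.point(exposure), 1
            )
            assert result.verdict == Verdict.acceptable

    def test_overlapping_intervals_borderline(self):
        result = moe_verdict(
            DoseInterval(lo=0.36, hi=3.6), DoseInterval(lo=0.5, hi=1.45), 1
        )
        assert result.verdict == Verdict.borderline
        assert result.moe == pytest.approx(0.36 / 1.45)

    def test_tier2_multiplier_flips_acceptable_to_insufficient_confidence(self):
        result = moe_verdict(
            DoseInterval.point(0.006), DoseInterval.point(0.004), 10
        )
        assert result.verdict == Verdict.insufficient_confidence
        assert result.moe == pytest.approx(1.5)

    def test_exposure_above_dnel_unacceptable(self):
        result = moe_verdict(DoseInterval.point(0.01), DoseInterval.point(5), 1)
        assert result.verdict == Verdict.unacceptable

    def test_zero_exposure_acceptable_with_infinite_moe(self):
        result = moe_verdict(DoseInterval.point(0.01), DoseInterval.point(0), 10)
        assert result.verdict == Verdict.acceptable

    @given(
        d_lo=st.floats(min_value=1e-4, max_value=1e2),
        d_span=st.floats(min_value=1, max_value=100),
        e_lo=st.floats(min_value=1e-4, max_value=1e2),
        e_span=st.floats(min_value=1, max_value=100),
        k=st.floats(min_value=1e-3, max_value=1e3),
        multiplier=st.sampled_from([1.0, 10.0, 100.0]),
    )
    def test_trichotomy_and_scale_invariance(
        self, d_lo, d_span, e_lo, e_span, k, multiplier
    ):
        dnel = DoseInterval(lo=d_lo, hi=d_lo * d_span)
        exposure = DoseInterval(lo=e_lo, hi=e_lo * e_span)
        verdict = moe_verdict(dnel, exposure, multiplier).verdict
        assert verdict in {
            Verdict.acceptable,
            Verdict.borderline,
            Verdict.unacceptable,
            Verdict.insufficient_confidence,
        }
        rescaled = moe_verdict(dnel.scale(k), exposure.scale(k), multiplier).verdict
        assert rescaled == verdict

    @given(
        d_lo=st.floats(min_value=1e-4, max_value=1e2),
        e_lo=st.floats(min_value=1e-4, max_value=1e2),
    )
    def test_raising_multiplier_never_moves_toward_acceptable(self, d_lo, e_lo):
        toward_acceptable = {
            Verdict.unacceptable: 0,
            Verdict.borderline: 1,
            Verdict.insufficient_confidence: 2,
            Verdict.acceptable: 3,
        }
        dnel, exposure = DoseInterval.point(d_lo), DoseInterval.point(e_lo)
        levels = [
            toward_acceptable[moe_verdict(dnel, exposure, m).verdict]
            for m in (1, 10, 100, 1000)
        ]
        assert levels == sorted(levels, reverse=True)


class TestRecommendNext:
    @pytest.mark.parametrize(
        "colour, verdict, exp_ref, haz_esc, expected",
        [
            ("green", "acceptable", False, False, "accept"),
            ("amber", "acceptable", False, False, "accept"),
            ("red", "unacceptable", True, True, "refine_exposure"),
            ("red", "unacceptable", False, True, "escalate_hazard_tier"),
            ("red", "unacceptable", False, False, "reject"),
            ("amber", "insufficient_confidence", True, True, "escalate_hazard_tier"),
            ("amber", "insufficient_confidence", True, False, "reject"),
            ("amber", "borderline", True, False, "refine_exposure"),
            ("amber", "borderline", False, True, "escalate_hazard_tier"),
            ("amber", "borderline", False, False, "compare_moe"),
        ],
    )
    def test_rules(self, colour, verdict, exp_ref, haz_esc, expected):
        got = recommend_next(Colour(colour), Verdict(verdict), exp_ref, haz_esc)
        assert got == Recommendation(expected)


def _dossier(records, **kw):
    return SubstanceDossier(
        substance_id="X",
        ttc_flags=TTCFlags(cramer_class=CramerClass.III),
        pod_records=tuple(records),
        **kw,
    )


def _scenario(dose, duration=DurationClass.long_term, tier=Tier.tier2_invitro):
    return ScenarioSet(
        scenarios=(
            Scenario(
                scenario_id="s1",
                duration=duration,
                steps=(
                    AssessmentStep(
                        exposure=ScenarioExposure(
                            external_dose=DoseInterval.model_validate(dose)
                        ),
                        hazard_tier=tier,
                    ),
                ),
            ),
        )
    )


class TestAssess:
    def test_empty_scenario_list_is_an_error(self):
        dossier = _dossier([])
        with pytest.raises(ValueError, match="scenario"):
            assess(dossier, ScenarioSet(scenarios=()))

    def test_tier0_pass_terminates_green(self):
        dossier = _dossier([])
        trajectory = assess(dossier, _scenario(1e-6))
        scenario = trajectory.scenarios[0]
        assert scenario.tier0.passes
        assert scenario.terminal_state == "accept"
        record = scenario.records[0]
        assert record.exposure_category == ExposureCategory.E
        assert record.colour == Colour.green

    def test_duration_without_relevant_data_is_a_data_gap(self):
        record = DossierPoD(
            endpoint=Endpoint.carcinogenicity,
            pod_type=PodType.T25,
            value=DoseInterval.point(50),
            tier=Tier.tier2_invitro,
        )
        trajectory = assess(
            _dossier([record]), _scenario(0.5, duration=DurationClass.one_day)
        )
        step = trajectory.scenarios[0].records[0]
        assert step.verdict == Verdict.not_evaluated
        assert any("data gap" in note for note in step.notes)

    def test_hazard_category_is_most_severe_relevant_endpoint(self):
        records = [
            DossierPoD(
                endpoint=Endpoint.stot_re,
                pod_type=PodType.NOAEL,
                value=DoseInterval.point(500),  # category 3
                tier=Tier.tier2_invitro,
            ),
            DossierPoD(
                endpoint=Endpoint.reproductive,
                pod_type=PodType.ED10,
                value=DoseInterval.point(2),  # category 1
                tier=Tier.tier2_invitro,
            ),
        ]
        trajectory = assess(_dossier(records), _scenario(0.5))
        assert trajectory.scenarios[0].records[0].hazard_category == 1

    def test_limit_dose_clearance_turns_category_a_green(self):
        record = DossierPoD(
            endpoint=Endpoint.stot_re,
            pod_type=PodType.NOAEL,
            value=DoseInterval.point(5000),  # category 4
            tier=Tier.conventional,
        )
        cleared = _dossier(
            [record], limit_dose_clearance={DurationClass.long_term: True}
        )
        uncleared = _dossier([record])
        scenario = _scenario(50, tier=Tier.conventional)
        assert (
            assess(cleared, scenario).scenarios[0].records[0].colour == Colour.green
        )
        assert (
            assess(uncleared, scenario).scenarios[0].records[0].colour == Colour.amber
        )

    def test_confidence_multiplier_config_is_honoured(self):
        record = DossierPoD(
            endpoint=Endpoint.stot_re,
            pod_type=PodType.NOAEL,
            value=DoseInterval.point(0.6),
            tier=Tier.tier2_invitro,
        )
        scenario = _scenario(0.004)
        strict = assess(_dossier([record]), scenario)
        relaxed = assess(
            _dossier([record]),
            scenario,
            confidence=TierConfidence(multipliers={Tier.tier2_invitro: 1.0}),
        )
        assert (
            strict.scenarios[0].records[0].verdict
            == Verdict.insufficient_confidence
        )
        assert relaxed.scenarios[0].records[0].verdict == Verdict.acceptable
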