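"""Deterministic dose/HQ/LTCR arithmetic and classification rules."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paerisk.errors import (
    ConfigurationError,
    InvalidFactorsError,
    InvalidInputError,
    InvalidToxicityError,
    MissingSlopeFactorError,
)
from paerisk.exposure import (
    ExposureFactors,
    ToxicityProfile,
    average_daily_dose,
    classify_cancer_risk,
    classify_noncancer,
    compound_risk,
    derive_rfc,
    hazard_quotient,
    lifetime_cancer_risk,
    risk_table,
)

finite_c = st.floats(min_value=0, max_value=1e5, allow_nan=False)


class TestDeriveRfc:
    def test_dmp_male_value(self, cfg, male):
        rfc = derive_rfc(cfg.toxicity["DMP"], male)
        assert rfc == pytest.approx(0.05 * 19.02 / 62.7, rel=1e-12)
        assert round(rfc, 3) == 0.015  # printed two-figure value

    def test_dehp_female_printed(self, cfg, female):
        assert round(derive_rfc(cfg.toxicity["DEHP"], female), 3) == 0.019

    def test_identity_scaling(self):
        ef = ExposureFactors("x", ir=5.0, bw=5.0, ef=1, ed=1, at_noncancer=1, at_cancer=1)
        tox = ToxicityProfile("X", rfc_air=1.0)
        assert derive_rfc(tox, ef) == 1.0

    def test_invalid_rfc_air_rejected(self):
        with pytest.raises(InvalidToxicityError):
            ToxicityProfile("X", rfc_air=0.0)


class TestAverageDailyDose:
    def test_cancer_horizon_frozen_value(self, male):
        # 1268.08 × 19.02 × 261 × 24 × 1e-3 / (62.7 × 25550), by hand
        assert average_daily_dose(1268.08, male, "cancer") == pytest.approx(
            0.09430842008033782, rel=1e-12
        )

    def test_noncancer_horizon_frozen_value(self, male):
        assert average_daily_dose(485.79, male, "noncancer") == pytest.approx(
            0.10537538763846103, rel=1e-12
        )

    def test_zero_concentration(self, male):
        assert average_daily_dose(0.0, male, "cancer") == 0.0

    def test_negative_concentration_rejected(self, male):
        with pytest.raises(InvalidInputError):
            average_daily_dose(-1.0, male, "noncancer")

    def test_zero_bw_rejected(self):
        with pytest.raises(InvalidFactorsError):
            ExposureFactors("x", ir=1, bw=0, ef=1, ed=1, at_noncancer=1, at_cancer=1)

    @given(c=finite_c, k=st.floats(min_value=0, max_value=100, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_linearity_in_concentration(self, male, c, k):
        lhs = average_daily_dose(k * c, male, "noncancer")
        rhs = k * average_daily_dose(c, male, "noncancer")
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-30)


class TestHazardQuotient:
    def test_dmp_industrial_mean_male(self, cfg, male):
        add = average_daily_dose(485.79, male, "noncancer")
        hq = hazard_quotient(add, derive_rfc(cfg.toxicity["DMP"], male))
        assert round(hq, 2) == 6.95

    def test_dbp_pooled_maximum(self, cfg, male):
        add = average_daily_dose(2514.0, male, "noncancer")
        hq = hazard_quotient(add, derive_rfc(cfg.toxicity["DBP"], male))
        assert round(hq, 1) == 89.9

    def test_threshold_case(self):
        assert hazard_quotient(0.5, 0.5) == 1.0

    def test_nonpositive_rfc_rejected(self):
        with pytest.raises(InvalidToxicityError):
            hazard_quotient(1.0, 0.0)

    @given(c=st.floats(min_value=1e-6, max_value=1e5))
    @settings(max_examples=200, deadline=None)
    def test_gender_invariance(self, cfg, male, female, c):
        """IR and BW cancel between the dose and the RfC derivation."""
        tox = cfg.toxicity["DBP"]
        hq_m = hazard_quotient(average_daily_dose(c, male, "noncancer"), derive_rfc(tox, male))
        hq_f = hazard_quotient(average_daily_dose(c, female, "noncancer"), derive_rfc(tox, female))
        assert hq_m == pytest.approx(hq_f, rel=1e-12)

    @given(c=st.floats(min_value=1e-6, max_value=1e5))
    @settings(max_examples=100, deadline=None)
    def test_closed_form_collapse(self, cfg, male, c):
        """HQ = c·EF·ED·CF / (AT_nc·rfc_air) equals the two-step route."""
        tox = cfg.toxicity["DEHP"]
        two_step = hazard_quotient(
            average_daily_dose(c, male, "noncancer"), derive_rfc(tox, male)
        )
        closed = c * male.ef * male.ed * male.cf / (male.at_noncancer * tox.rfc_air)
        assert two_step == pytest.approx(closed, rel=1e-12)


class TestLifetimeCancerRisk:
    def test_dehp_industrial_male(self, cfg, male):
        ladd = average_daily_dose(1268.08, male, "cancer")
        assert lifetime_cancer_risk(ladd, 0.014) == pytest.approx(1.3e-3, rel=0.02)

    def test_dehp_administrative_female(self, cfg, female):
        ladd = average_daily_dose(45.50, female, "cancer")
        assert lifetime_cancer_risk(ladd, 0.014) == pytest.approx(4.2e-5, rel=0.02)

    def test_zero_slope_factor(self):
        assert lifetime_cancer_risk(1.0, 0.0) == 0.0

    def test_missing_slope_factor_fails_loudly(self):
        with pytest.raises(MissingSlopeFactorError):
            lifetime_cancer_risk(1.0, None)

    def test_male_female_ratio_is_factor_ratio(self, male, female):
        """LTCR(m)/LTCR(f) = (IR_m/BW_m)/(IR_f/BW_f) for any fixed c."""
        for c in (1.0, 45.5, 1268.08):
            m = lifetime_cancer_risk(average_daily_dose(c, male, "cancer"), 0.014)
            f = lifetime_cancer_risk(average_daily_dose(c, female, "cancer"), 0.014)
            assert m / f == pytest.approx((19.02 / 62.7) / (14.7 / 54.4), rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "ltcr,label",
        [
            (0.0, "acceptable"),
            (9.999e-7, "acceptable"),
            (1e-6, "potential"),
            (4.7e-5, "potential"),
            (1e-4, "potential"),  # 'beyond 1e-4' is strict
            (1.0000001e-4, "severe"),
            (1.3e-3, "severe"),
        ],
    )
    def test_cancer_bands(self, ltcr, label):
        assert classify_cancer_risk(ltcr) == label

    @pytest.mark.parametrize(
        "hq,label",
        [(0.0, "acceptable"), (0.008, "acceptable"), (1.0, "acceptable"), (1.01, "at_risk"), (30.38, "at_risk")],
    )
    def test_noncancer_bands(self, hq, label):
        assert classify_noncancer(hq) == label

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_cancer_risk(-1e-9)
        with pytest.raises(InvalidInputError):
            classify_noncancer(-0.1)

    @given(x=st.floats(min_value=0, max_value=1.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_cancer_bands_total_and_exclusive(self, x):
        assert classify_cancer_risk(x) in {"acceptable", "potential", "severe"}


class TestRiskTable:
    def test_dehp_industrial_male_hq_cell(self, cfg, male):
        means = {("DEHP", "industrial"): 1268.08}
        rows = risk_table(means, [male], cfg.toxicity)
        hq = next(r for r in rows if r.metric == "HQ")
        assert round(hq.value, 2) == 12.95
        assert hq.classification == "at_risk"

    def test_empty_input_gives_empty_table(self, cfg):
        assert risk_table({}, cfg.exposure_factors.values(), cfg.toxicity) == []

    def test_cell_enumeration(self, cfg):
        """Carcinogen gets HQ+LTCR per gender; non-carcinogen HQ only."""
        means = {("DEHP", "industrial"): 100.0, ("DMP", "industrial"): 100.0}
        rows = risk_table(means, cfg.exposure_factors.values(), cfg.toxicity)
        by = {(r.compound, r.gender, r.metric) for r in rows}
        assert len(rows) == 6  # 2 genders × (2 metrics + 1 metric)
        assert ("DEHP", "male", "LTCR") in by and ("DMP", "male", "LTCR") not in by

    def test_missing_toxicity_entry(self, cfg, male):
        with pytest.raises(ConfigurationError):
            risk_table({("BBP", "industrial"): 1.0}, [male], cfg.toxicity)


def test_compound_risk_chain_consistency(cfg, male):
    """One-call chain equals the explicit dose→metric→classify steps."""
    r = compound_risk(1268.08, male, cfg.toxicity["DEHP"], "LTCR")
    assert r.value == pytest.approx(
        lifetime_cancer_risk(average_daily_dose(1268.08, male, "cancer"), 0.014)
    )
    assert r.classification == "severe"


def test_slope_factor_consistency_enforced():
    with pytest.raises(InvalidToxicityError):
        ToxicityProfile("DEHP", rfc_air=0.07, carcinogenic=True, slope_factor=None)
    with pytest.raises(InvalidToxicityError):
        ToxicityProfile("DMP", rfc_air=0.05, carcinogenic=False, slope_factor=0.01)
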