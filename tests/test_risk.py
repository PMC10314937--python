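"""USEPA dose equations (EC, CDI) and risk indices (HQ, LCR) with their
categorical classifiers."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from btexrisk import (
    ExposureFactors,
    assess,
    chronic_daily_intake,
    classify_hq,
    classify_lcr,
    exposure_concentration,
    hazard_quotient,
    lifetime_cancer_risk,
)


def factors(**kw):
    base = dict(c=1.0, et=10.0, ed=30.0, ef=252.0, bw=80.0)
    base.update(kw)
    return ExposureFactors(**base)


class TestExposureConcentration:
    def test_continuous_exposure_equals_concentration(self):
        f = factors(c=1.0, et=24.0, ef=365.0)
        assert exposure_concentration(f, "usepa") == pytest.approx(1.0)

    def test_usepa_time_fraction(self):
        f = factors(c=7.193, et=12.0, ef=270.0)
        assert exposure_concentration(f, "usepa") == pytest.approx(
            7.193 * (12 / 24) * (270 / 365), rel=1e-12
        )

    def test_paper_mode_literal_quotient(self):
        f = factors(c=1.0, et=10.0, ed=30.0, ef=252.0, at_noncancer=9000.0)
        assert exposure_concentration(f, "paper") == pytest.approx(8.40)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            exposure_concentration(factors(), "crystal")

    @given(st.floats(1, 40), st.floats(1, 40))
    def test_ed_cancels_in_usepa_mode(self, ed1, ed2):
        assert exposure_concentration(factors(ed=ed1), "usepa") == pytest.approx(
            exposure_concentration(factors(ed=ed2), "usepa")
        )

    @given(st.floats(0, 100), st.floats(0, 24), st.floats(1, 365))
    def test_ec_never_exceeds_concentration_in_usepa_mode(self, c, et, ef):
        f = factors(c=c, et=et, ef=ef)
        assert exposure_concentration(f, "usepa") <= c + 1e-12


class TestChronicDailyIntake:
    def test_zero_concentration(self):
        assert chronic_daily_intake(factors(c=0.0)) == 0.0

    def test_closed_form_example(self):
        f = ExposureFactors(c=1.0, et=10.0, ed=25.0, ef=250.0, bw=80.0, ir=16.0, at_cancer=25550.0)
        assert chronic_daily_intake(f) == pytest.approx(100000 / 2044000, rel=1e-12)

    def test_linearity_in_concentration(self):
        assert chronic_daily_intake(factors(c=2.0)) == pytest.approx(
            2 * chronic_daily_intake(factors(c=1.0))
        )

    @given(
        st.integers(0, 50),
        st.integers(1, 40),
        st.integers(1, 365),
        st.integers(50, 120),
        st.integers(1, 30),
    )
    def test_agrees_with_rational_arithmetic_oracle(self, c, ed, ef, bw, ir):
        """Brute-force evaluation on exact rationals to 1e-12 relative."""
        f = ExposureFactors(c=float(c), et=8.0, ed=float(ed), ef=float(ef), bw=float(bw), ir=float(ir))
        exact = Fraction(c) * Fraction(ir) * Fraction(ed) * Fraction(ef) / (
            Fraction(bw) * Fraction(25550)
        )
        assert chronic_daily_intake(f) == pytest.approx(float(exact), rel=1e-12)


class TestHazardQuotient:
    def test_ratio_of_one(self):
        assert hazard_quotient(0.03, 0.03) == pytest.approx(1.0)

    def test_zero_exposure(self):
        assert hazard_quotient(0.0, 5.0) == 0.0

    def test_derived_quotient(self):
        ec = 7.193 * (12 / 24) * (270 / 365)
        assert hazard_quotient(ec, 0.03) == pytest.approx(88.68, abs=0.01)

    def test_missing_rfc_yields_absent_not_zero(self):
        assert hazard_quotient(1.0, None) is None


class TestLifetimeCancerRisk:
    def test_benzene_slope(self):
        cdi = 100000 / 2044000
        assert lifetime_cancer_risk(cdi, 0.029) == pytest.approx(1.419e-3, rel=1e-3)

    def test_ethylbenzene_slope(self):
        cdi = 100000 / 2044000
        assert lifetime_cancer_risk(cdi, 0.0087) == pytest.approx(4.256e-4, rel=1e-3)

    def test_zero_intake(self):
        assert lifetime_cancer_risk(0.0, 0.029) == 0.0

    def test_missing_sf_yields_absent(self):
        assert lifetime_cancer_risk(1.0, None) is None

    def test_values_above_one_clip_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert lifetime_cancer_risk(100.0, 0.029) == 1.0


class TestClassifiers:
    @pytest.mark.parametrize(
        "hq,expected",
        [(0.914, "acceptable"), (1.0, "adverse"), (162.0, "adverse"), (0.0, "acceptable")],
    )
    def test_hq_bands(self, hq, expected):
        assert classify_hq(hq) == expected

    @pytest.mark.parametrize(
        "lcr,expected",
        [
            (5.42e-2, "definite"),
            (1e-7, "negligible"),
            (5e-6, "possible"),
            # boundaries belong to the lower band
            (1e-4, "probable"),
            (1e-5, "possible"),
            (1e-6, "negligible"),
            (2e-4, "definite"),
        ],
    )
    def test_lcr_bands(self, lcr, expected):
        assert classify_lcr(lcr) == expected

    def test_lcr_classification_is_monotone(self):
        order = {"negligible": 0, "possible": 1, "probable": 2, "definite": 3}
        rng = np.random.default_rng(0)
        grid = np.sort(10.0 ** rng.uniform(-9, 0, 500))
        cats = [order[classify_lcr(v)] for v in grid]
        assert all(a <= b for a, b in zip(cats, cats[1:]))


class TestAssess:
    def test_full_chain_benzene(self, analytes):
        f = factors(c=7.193, et=12.0, ef=270.0)
        res = assess(analytes["benzene"], f)
        assert res.hq == pytest.approx(88.68, abs=0.01)
        assert res.hq_category == "adverse"
        assert res.lcr_category == "definite"

    def test_homogeneity_in_concentration(self, analytes):
        r1 = assess(analytes["benzene"], factors(c=1.0))
        r2 = assess(analytes["benzene"], factors(c=3.0))
        assert r2.hq == pytest.approx(3 * r1.hq)
        assert r2.lcr == pytest.approx(3 * r1.lcr)

    def test_no_slope_factor_drops_lcr_only(self, analytes):
        res = assess(analytes["toluene"], factors())
        assert res.lcr is None and res.lcr_category is None
        assert res.hq is not None
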