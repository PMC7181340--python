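import math

import pytest
from hypothesis import given, settings, strategies as st

from antioxkit.druglikeness import (
    BioactivityClass,
    MolecularProperties,
    ToxicityRisk,
    bioactivity_class,
    drug_score,
    lipinski_violations,
    sigmoid_contribution,
    veber_check,
)


def _props(**overrides):
    base = dict(mw=317.27, milogp=1.980, logs=-2.338, druglikeness=1.310,
                tpsa=121.54, nhba=7, nhbd=5, nrotb=2)
    base.update(overrides)
    return MolecularProperties(**base)


class TestLipinski:
    def test_petunidin_has_no_violations(self):
        report = lipinski_violations(_props(milogp=-0.73))
        assert report.violations == 0
        assert report.passed

    def test_all_rules_broken(self):
        report = lipinski_violations(_props(mw=600.0, milogp=6.0, nhbd=6, nhba=11))
        assert report.violations == 4

    def test_boundaries_are_inclusive(self):
        report = lipinski_violations(_props(mw=500.0, milogp=5.0, nhbd=5, nhba=10))
        assert report.violations == 0

    def test_missing_property_named(self):
        with pytest.raises(ValueError, match="milogp"):
            lipinski_violations(MolecularProperties(mw=300.0, nhba=2, nhbd=1))

    @given(
        dmw=st.floats(0, 400, allow_nan=False),
        dlogp=st.floats(0, 6, allow_nan=False),
        dhbd=st.integers(0, 8),
        dhba=st.integers(0, 8),
    )
    @settings(deadline=None)
    def test_monotone_in_every_property(self, dmw, dlogp, dhbd, dhba):
        base = lipinski_violations(_props(milogp=-0.73)).violations
        worse = lipinski_violations(
            _props(mw=317.27 + dmw, milogp=-0.73 + dlogp, nhbd=5 + dhbd, nhba=7 + dhba)
        ).violations
        assert worse >= base


class TestVeber:
    def test_petunidin_passes(self):
        assert veber_check(_props()).passed

    def test_both_criteria_fail(self):
        report = veber_check(_props(tpsa=150.0, nrotb=11))
        assert report.violations == 2

    def test_boundary_passes(self):
        assert veber_check(_props(tpsa=139.99, nrotb=10)).passed


class TestBioactivityClass:
    @pytest.mark.parametrize("score, expected", [
        (0.03, BioactivityClass.CONSIDERABLE),
        (0.01, BioactivityClass.CONSIDERABLE),
        (-0.15, BioactivityClass.MODERATE),
        (0.0, BioactivityClass.MODERATE),
        (-0.5, BioactivityClass.MODERATE),
        (-0.51, BioactivityClass.INACTIVE),
    ])
    def test_classification(self, score, expected):
        assert bioactivity_class(score) is expected

    @given(score=st.floats(-5, 5, allow_nan=False))
    def test_partitions_the_line(self, score):
        assert bioactivity_class(score) in BioactivityClass


class TestSigmoid:
    def test_logistic_midpoint(self):
        assert sigmoid_contribution(5.0, 1.0, -5.0) == 0.5

    @pytest.mark.parametrize("p, a, b, expected", [
        (1.98, 1.0, -5.0, 0.9535),    # 1/(1+e^(-3.02))
        (317.27, 0.012, -6.0, 0.8996),
    ])
    def test_direct_evaluation(self, p, a, b, expected):
        assert sigmoid_contribution(p, a, b) == pytest.approx(expected, abs=5e-5)

    def test_overflow_saturates(self):
        assert sigmoid_contribution(1e6, 1.0, 0.0) == 0.0
        assert sigmoid_contribution(-1e6, 1.0, 0.0) == 1.0


class TestDrugScore:
    def test_petunidin_score(self):
        assert drug_score(_props()) == pytest.approx(0.804, abs=0.005)

    def test_literal_parameter_signs_deviate_grossly(self):
        literal = drug_score(_props(), literal_params=True)
        assert abs(literal - 0.804) > 0.3

    def test_toxicity_multiplier_law(self):
        all_high = {c: ToxicityRisk.HIGH for c in
                    ("mutagenic", "tumorigenic", "irritant", "reproductive")}
        assert drug_score(_props(toxicity=all_high)) == pytest.approx(
            0.6**4 * drug_score(_props()), rel=1e-12
        )

    def test_neutral_point(self):
        # every property at its logistic midpoint: each term 1/2 + 1/2·1/2
        props = _props(milogp=5.0, logs=-5.0, mw=500.0, druglikeness=0.0)
        assert drug_score(props) == pytest.approx(0.75**4, rel=1e-12)

    def test_missing_term_rejected(self):
        with pytest.raises(ValueError, match="logs"):
            drug_score(_props(logs=None))

    @given(
        mw=st.floats(100, 800, allow_nan=False),
        milogp=st.floats(-2, 8, allow_nan=False),
        logs=st.floats(-8, 1, allow_nan=False),
        dl=st.floats(-6, 6, allow_nan=False),
    )
    @settings(deadline=None)
    def test_bounds_and_monotonicity(self, mw, milogp, logs, dl):
        props = _props(mw=mw, milogp=milogp, logs=logs, druglikeness=dl)
        ds = drug_score(props)
        assert 0.0 < ds < 1.0
        assert drug_score(_props(mw=mw + 50, milogp=milogp, logs=logs,
                                 druglikeness=dl)) <= ds
        assert drug_score(_props(mw=mw, milogp=milogp + 1, logs=logs,
                                 druglikeness=dl)) <= ds
        assert drug_score(_props(mw=mw, milogp=milogp, logs=logs + 1,
                                 druglikeness=dl)) >= ds
        assert drug_score(_props(mw=mw, milogp=milogp, logs=logs,
                                 druglikeness=dl + 1)) >= ds

    def test_worsening_any_toxicity_flag_strictly_decreases(self):
        base = drug_score(_props())
        for cat in ("mutagenic", "tumorigenic", "irritant", "reproductive"):
            medium = drug_score(_props(toxicity={**_props().toxicity, cat: "medium"}))
            high = drug_score(_props(toxicity={**_props().toxicity, cat: "high"}))
            assert high < medium < base


class TestPropertiesValidation:
    def test_counts_must_be_nonnegative_integers(self):
        with pytest.raises(ValueError, match="nhbd"):
            MolecularProperties(mw=100.0, nhbd=-1)

    def test_toxicity_map_must_be_complete(self):
        with pytest.raises(ValueError, match="missing"):
            MolecularProperties(mw=100.0, toxicity={"mutagenic": "none"})

    def test_nonfinite_sigmoid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_contribution(math.nan, 1.0, 0.0)
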