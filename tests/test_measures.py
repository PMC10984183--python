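"""Unit and property tests for the pure interaction-measure computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from addint.measures import (
    CoefficientVector,
    RelativeRiskTriple,
    compute_ap,
    compute_reri,
    compute_s,
    interaction_measures,
    measures_from_coefficients,
    measures_from_draws,
    recode_lowest_reference,
)

rr_values = st.floats(min_value=0.05, max_value=50.0, allow_nan=False)


@st.composite
def triples(draw):
    return RelativeRiskTriple(
        rr10=draw(rr_values), rr01=draw(rr_values), rr11=draw(rr_values)
    )


@pytest.mark.parametrize(
    "rr10, rr01, rr11, reri, ap",
    [
        (5.0, 4.0, 20.0, 12.0, 0.60),
        (1.0, 1.0, 1.0, 0.0, 0.0),
        (160 / 54, 120 / 36, 4500 / 498, 3.74, None),  # sparse-cell example ORs
        (2.5, 2.0, 1.75, None, -1.0),
        (1.0, 1.0, 2.0, 1.0, 0.5),
    ],
)
def test_reri_and_ap_match_hand_computed_values(rr10, rr01, rr11, reri, ap):
    rr = RelativeRiskTriple(rr10=rr10, rr01=rr01, rr11=rr11)
    if reri is not None:
        assert compute_reri(rr) == pytest.approx(reri, abs=5e-3)
    if ap is not None:
        assert compute_ap(rr) == pytest.approx(ap, abs=5e-3)


@pytest.mark.parametrize(
    "rr10, rr01, rr11, s",
    [
        (5.0, 4.0, 20.0, 19 / 7),
        (5.0, 4.0, 8.0, 1.0),  # exact additivity forces S = 1
        (1.0, 1.0, 3.0, None),  # zero denominator
        (1.2, 1.1, 0.9, None),  # numerator non-positive
    ],
)
def test_synergy_index_values_and_domain(rr10, rr01, rr11, s):
    rr = RelativeRiskTriple(rr10=rr10, rr01=rr01, rr11=rr11)
    got = compute_s(rr)
    if s is None:
        assert got is None
        assert interaction_measures(rr).s_undefined_reason
    else:
        assert got == pytest.approx(s, rel=1e-12)


def test_non_positive_relative_risks_rejected():
    with pytest.raises(ValueError):
        RelativeRiskTriple(rr10=0.0, rr01=1.0, rr11=1.0)
    with pytest.raises(ValueError):
        RelativeRiskTriple(rr10=1.0, rr01=-2.0, rr11=1.0)


@settings(max_examples=200, deadline=None)
@given(triples())
def test_measure_identities(rr):
    """RERI == AP * RR11 always; RERI == (S-1)(RR10+RR01-2) when S defined."""
    m = interaction_measures(rr)
    assert m.reri == pytest.approx(m.ap * rr.rr11, rel=1e-9, abs=1e-9)
    if m.s is not None:
        assert m.reri == pytest.approx(
            (m.s - 1.0) * (rr.rr10 + rr.rr01 - 2.0), rel=1e-9, abs=1e-9
        )
        if abs(m.reri) < 1e-12:
            assert m.s == pytest.approx(1.0)
            assert m.ap == pytest.approx(0.0, abs=1e-12)


def test_s_monotone_in_rr11_on_domain():
    lo = compute_s(RelativeRiskTriple(2.0, 2.0, 3.0))
    hi = compute_s(RelativeRiskTriple(2.0, 2.0, 5.0))
    assert hi > lo


@pytest.mark.parametrize(
    "theta, expected",
    [
        (CoefficientVector(0, math.log(5), math.log(4), math.log(20)),
         (12.0, 0.60, 19 / 7)),
        # product coding of the same saturated cell means
        (CoefficientVector(0, math.log(5), math.log(4), 0.0, tag="product"),
         (12.0, 0.60, 19 / 7)),
    ],
)
def test_measures_from_coefficients_both_codings(theta, expected):
    m = measures_from_coefficients(theta)
    assert m.reri == pytest.approx(expected[0], rel=1e-12)
    assert m.ap == pytest.approx(expected[1], rel=1e-12)
    assert m.s == pytest.approx(expected[2], rel=1e-12)


def test_null_model_measures():
    m = measures_from_coefficients(CoefficientVector(0, 0, 0, 0))
    assert m.reri == 0 and m.ap == 0 and m.s is None


class TestRecode:
    def test_subtracts_minimal_coefficient(self):
        theta = CoefficientVector(0.0, -0.5, 0.3, 0.7)
        recoded, rmap = recode_lowest_reference(theta)
        assert rmap.reference == "A1B0"
        assert rmap.flip_a and not rmap.flip_b
        assert recoded.beta0 == pytest.approx(-0.5)  # intercept absorbs shift
        # recoded category coefficients (0.5, 0, 0.8, 1.2) re-referenced:
        # A1B0* is old A0B0 (0.5), A0B1* is old A1B1 (1.2), A1B1* is old A0B1 (0.8)
        assert recoded.beta1 == pytest.approx(0.5)
        assert recoded.beta2 == pytest.approx(1.2)
        assert recoded.beta3 == pytest.approx(0.8)

    def test_identity_when_reference_already_lowest(self):
        theta = CoefficientVector(-1.0, 0.2, 0.4, 0.9)
        recoded, rmap = recode_lowest_reference(theta)
        assert rmap.identity
        assert recoded == theta

    def test_idempotent(self):
        theta = CoefficientVector(0.1, -0.5, 0.3, -0.7)
        once, _ = recode_lowest_reference(theta)
        twice, rmap = recode_lowest_reference(once)
        assert rmap.identity
        assert twice == once

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-3, 3, allow_nan=False), min_size=3, max_size=3))
    def test_recoded_odds_ratios_at_least_one(self, betas):
        theta = CoefficientVector(0.0, *betas)
        recoded, _ = recode_lowest_reference(theta)
        rr = recoded.odds_ratios()
        assert min(rr.rr10, rr.rr01, rr.rr11) >= 1.0 - 1e-12

    def test_tie_prefers_original_reference_then_category_order(self):
        recoded, rmap = recode_lowest_reference(CoefficientVector(0, 0.0, 0.5, 1.0))
        assert rmap.reference == "A0B0"
        _, rmap = recode_lowest_reference(CoefficientVector(0, -1.0, -1.0, 0.0))
        assert rmap.reference == "A1B0"

    def test_matches_refit_on_physically_recoded_data(self):
        """Coefficient-space recoding equals refitting with recoded factors."""
        from addint.model_fit import SubjectData, fit_logistic_mle

        rng = np.random.default_rng(7)
        n = 800
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        beta = {(0, 0): 0.0, (1, 0): -0.9, (0, 1): 0.4, (1, 1): 0.1}
        eta = -0.3 + np.array([beta[(ai, bi)] for ai, bi in zip(a, b)])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic_mle(SubjectData(outcome=y, factor_a=a, factor_b=b))
        recoded, rmap = recode_lowest_reference(fit.coefficients)
        assert not rmap.identity
        a2 = 1 - a if rmap.flip_a else a
        b2 = 1 - b if rmap.flip_b else b
        refit = fit_logistic_mle(SubjectData(outcome=y, factor_a=a2, factor_b=b2))
        m1 = measures_from_coefficients(recoded)
        m2 = measures_from_coefficients(refit.coefficients)
        assert m1.reri == pytest.approx(m2.reri, abs=1e-6)
        assert m1.ap == pytest.approx(m2.ap, abs=1e-8)
        if m1.s is None:
            assert m2.s is None
        else:
            assert m1.s == pytest.approx(m2.s, abs=1e-8)


def test_vectorised_draws_agree_with_scalar_path(rng):
    beta = rng.normal(0, 1, size=(50, 3))
    for recode in (False, True):
        mapped = measures_from_draws(beta, recode=recode)
        for i in range(len(beta)):
            theta = CoefficientVector(0.0, *beta[i])
            if recode:
                theta, _ = recode_lowest_reference(theta)
            m = measures_from_coefficients(theta)
            assert mapped["RERI"][i] == pytest.approx(m.reri, rel=1e-12)
            assert mapped["AP"][i] == pytest.approx(m.ap, rel=1e-12)
            if m.s is None:
                assert np.isnan(mapped["S"][i])
            else:
                assert mapped["S"][i] == pytest.approx(m.s, rel=1e-12)
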