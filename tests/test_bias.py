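"""Egger regression, Begg rank correlation and funnel coordinates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mmtsa import begg_test, egger_test, funnel_coordinates
from mmtsa.effects import EffectEstimate


def eff(log_or, se, sid):
    return EffectEstimate(study_id=sid, log_or=log_or, se=se)


def test_egger_on_fixture_recessive_model(recessive_effects):
    res = egger_test(recessive_effects)
    assert res.df == 7
    assert res.t == pytest.approx(1.53, abs=0.02)
    assert 0.16 <= res.p <= 0.18


def test_egger_symmetric_funnel_has_zero_intercept():
    # effects mirrored about a common mean, pairwise at each precision level:
    # the conditional means lie exactly on y = mu * x, so the intercept vanishes
    effects = [
        eff(0.5 - 0.3, 0.1, "a"), eff(0.5 + 0.3, 0.1, "b"),
        eff(0.5 - 0.1, 0.3, "c"), eff(0.5 + 0.1, 0.3, "d"),
    ]
    res = egger_test(effects)
    assert res.intercept == pytest.approx(0.0, abs=1e-10)


def test_egger_common_effect_different_precisions_zero_intercept():
    # one shared log OR puts every point on the origin line y = theta * x
    effects = [eff(0.4, se, s) for se, s in [(0.1, "a"), (0.2, "b"), (0.4, "c")]]
    assert egger_test(effects).intercept == pytest.approx(0.0, abs=1e-10)


def test_egger_equal_standard_errors_is_degenerate():
    effects = [eff(0.1, 0.2, "a"), eff(0.3, 0.2, "b"), eff(0.5, 0.2, "c")]
    with pytest.raises(ValueError, match="undefined"):
        egger_test(effects)


def test_egger_matches_closed_form_simple_regression():
    """Oracle: hand-coded OLS with explicit mean/covariance formulas, k=3."""
    effects = [eff(0.2, 0.10, "a"), eff(0.5, 0.25, "b"), eff(-0.1, 0.40, "c")]
    x = np.array([1 / e.se for e in effects])
    y = np.array([e.log_or / e.se for e in effects])
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid**2).sum() / (len(x) - 2)
    se_int = np.sqrt(s2 * (1 / len(x) + x.mean() ** 2 / ((x - x.mean()) ** 2).sum()))
    res = egger_test(effects)
    assert res.intercept == pytest.approx(intercept, rel=1e-9)
    assert res.t == pytest.approx(intercept / se_int, rel=1e-9)


def test_egger_needs_three_studies():
    with pytest.raises(ValueError):
        egger_test([eff(0.1, 0.1, "a"), eff(0.2, 0.2, "b")])


def test_begg_perfect_concordance_gives_tau_one():
    # standardized deviates strictly increasing with variance
    effects = [eff(lo, se, f"s{i}") for i, (lo, se) in enumerate(
        [(0.0, 0.10), (0.3, 0.20), (0.8, 0.30), (1.6, 0.40)]
    )]
    res = begg_test(effects)
    assert res.kendall_tau == pytest.approx(1.0)


def test_begg_on_fixture_recessive_model_not_significant(recessive_effects):
    assert begg_test(recessive_effects).p > 0.05


def test_begg_needs_three_studies(recessive_effects):
    with pytest.raises(ValueError):
        begg_test(recessive_effects[:2])


@settings(max_examples=100, deadline=None)
@given(
    data=st.lists(
        st.tuples(
            st.floats(-1.5, 1.5, allow_nan=False),
            st.floats(0.05, 1.0, allow_nan=False),
        ),
        min_size=3,
        max_size=8,
    )
)
def test_begg_tau_matches_scipy_pair_count_oracle(data):
    """Kendall tau of the Begg deviates equals scipy's tau on the same pairs."""
    effects = [eff(lo, se, f"s{i}") for i, (lo, se) in enumerate(data)]
    lo = np.array([e.log_or for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1 / v
    theta_f = (w * lo).sum() / w.sum()
    vstar = np.maximum(v - 1 / w.sum(), 1e-12)
    u = (lo - theta_f) / np.sqrt(vstar)
    k = len(u)
    n_pairs = k * (k - 1) / 2
    # tau-a from scipy's concordance count (tau-b == tau-a without ties)
    tau_scipy, _ = stats.kendalltau(u, v)
    res = begg_test(effects)
    if not np.isnan(tau_scipy) and len(set(u.round(12))) == k and len(set(v.round(12))) == k:
        assert res.kendall_tau == pytest.approx(tau_scipy, abs=1e-9)


def test_funnel_coordinates_fixture(recessive_effects):
    points, ref = funnel_coordinates(recessive_effects)
    assert len(points) == 9
    assert all(p.se > 0 for p in points)


def test_funnel_single_study_reference_is_that_study():
    e = eff(0.25, 0.1, "only")
    points, ref = funnel_coordinates([e])
    assert len(points) == 1
    assert ref == pytest.approx(0.25)


def test_funnel_empty_list_is_an_error():
    with pytest.raises(ValueError):
        funnel_coordinates([])
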