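"""Diversity, information size, alpha-spending boundaries, Z-curve."""

import math

import numpy as np
import pytest
from scipy import stats

from mmtsa import (
    GeneticModel,
    TSAConfig,
    TrialSequentialAnalysis,
    control_event_proportion,
    cumulative_z,
    diversity,
    obf_boundary,
    obf_spending,
    pool_fixed,
    pool_random,
    required_information_size,
    tsa_adjusted_ci,
)
from mmtsa.effects import EffectEstimate
from mmtsa.meta import PooledResult


def eff(log_or, se, sid):
    return EffectEstimate(study_id=sid, log_or=log_or, se=se)


# ---------------------------------------------------------------- diversity

def test_diversity_zero_for_identical_effects():
    effects = [eff(0.2, 0.1, s) for s in "abc"]
    assert diversity(effects).d2 == pytest.approx(0.0, abs=1e-12)


def test_diversity_closed_form_two_studies_with_forced_tau2():
    """Hand-computable case: two studies, se = 0.1 each, tau2 = 0.01.

    v_fixed = 1/(2/0.01) = 0.005; v_random = (0.01 + 0.01)/2 = 0.01;
    D^2 = (v_random - v_fixed)/v_random = 1/2.
    """
    effects = [eff(0.0, 0.1, "a"), eff(0.3, 0.1, "b")]
    v_fixed = pool_fixed(effects).se ** 2
    v_random = pool_random(effects, tau2=0.01).se ** 2
    d2 = (v_random - v_fixed) / v_random
    assert v_fixed == pytest.approx(0.005)
    assert v_random == pytest.approx(0.01)
    assert d2 == pytest.approx(0.5)


def test_diversity_dominates_i2_on_fixture(allele_effects):
    from mmtsa import heterogeneity

    d = diversity(allele_effects)
    assert d.d2 >= heterogeneity(allele_effects).i2 / 100.0
    assert d.v_random >= d.v_fixed


# ----------------------------------------------------- information size

def fig3_config(**kw):
    base = dict(
        alpha=0.05, power=0.80, control_event_proportion=0.3802, rri=0.1681, diversity=0.67
    )
    base.update(kw)
    return TSAConfig(**base)


def test_required_information_size_reproduces_published_value():
    ris = required_information_size(fig3_config())
    assert ris == pytest.approx(2823, rel=0.01)


def test_adjustment_factor_is_exactly_one_over_one_minus_d2():
    adj = required_information_size(fig3_config())
    unadj = required_information_size(fig3_config(diversity=0.0))
    assert unadj / adj == pytest.approx(1 - 0.67, rel=2e-3)  # ceil rounding only


def test_doubling_delta_quarters_the_information():
    """Monotone scaling law checked against the explicit closed form."""
    p_c = 0.3802
    for rri in (0.1681, 0.3362):
        cfg = fig3_config(rri=rri, diversity=0.0)
        p_e = p_c * (1 + rri)
        pbar, delta = (p_c + p_e) / 2, p_e - p_c
        core = (stats.norm.ppf(0.975) + stats.norm.ppf(0.80)) ** 2 * 2 * pbar * (1 - pbar) / delta**2
        assert required_information_size(cfg) == math.ceil(core)


def test_total_variant_doubles_the_per_group_constant():
    per_group = required_information_size(fig3_config(diversity=0.0))
    total = required_information_size(fig3_config(diversity=0.0, ris_variant="total"))
    assert total == pytest.approx(2 * per_group, abs=1.0)


def test_zero_rri_is_an_error():
    with pytest.raises(ValueError):
        required_information_size(fig3_config(rri=0.0))


def test_degenerate_diversity_is_an_error():
    with pytest.raises(ValueError):
        TSAConfig(control_event_proportion=0.38, rri=0.17, diversity=1.0)


# ------------------------------------------------------------- boundaries

def test_spending_endpoint_equals_alpha():
    assert obf_spending(1.0) == pytest.approx(0.05, abs=1e-12)
    assert obf_spending([0.5, 1.0])[-1] == pytest.approx(0.05, abs=1e-12)


def test_single_look_at_full_information_is_fixed_sample_test():
    (z,) = obf_boundary([1.0])
    assert z == pytest.approx(1.959964, abs=1e-3)


def test_single_early_look_matches_closed_form():
    # one look: boundary is the two-sided quantile of the spent alpha
    (z,) = obf_boundary([0.25])
    expected = stats.norm.isf(obf_spending(0.25) / 2)
    assert z == pytest.approx(float(expected), abs=1e-6)


def test_five_equal_looks_match_reference_boundaries():
    """Published Lan-DeMets O'Brien-Fleming-type values for K=5, alpha=.05."""
    z = obf_boundary([0.2, 0.4, 0.6, 0.8, 1.0])
    for ours, ref in zip(z, [4.877, 3.357, 2.680, 2.290, 2.031]):
        assert ours == pytest.approx(ref, abs=0.02)


def test_boundaries_decrease_with_information():
    z = obf_boundary([0.2, 0.4, 0.6, 0.8, 1.0])
    assert all(a > b for a, b in zip(z, z[1:]))


def test_two_look_crossing_probability_matches_monte_carlo():
    t = [0.5, 1.0]
    c = obf_boundary(t)
    rng = np.random.default_rng(20240)
    inc = rng.normal(0, np.sqrt([0.5, 0.5]), size=(100_000, 2))
    z = inc.cumsum(axis=1) / np.sqrt(t)
    rate = (np.abs(z) >= c).any(axis=1).mean()
    assert rate == pytest.approx(0.05, abs=0.004)


def test_nonincreasing_fractions_rejected():
    with pytest.raises(ValueError):
        obf_boundary([0.5, 0.5, 1.0])
    with pytest.raises(ValueError):
        obf_boundary([0.5, 1.2])


# ---------------------------------------------------------------- Z-curve

def test_cumulative_curve_ends_at_full_meta_z(table1, allele_effects):
    looks = cumulative_z(table1, GeneticModel.ALLELE)
    assert len(looks) == 9
    full = pool_random(allele_effects)
    assert looks[-1].z == pytest.approx(full.z, rel=1e-12)
    assert looks[-1].cumulative_information == 7046


def test_single_study_curve(table1):
    from mmtsa.study_data import StudySet

    one = StudySet([table1[0]])
    looks = cumulative_z(one)
    assert len(looks) == 1
    e = one[0]
    assert looks[0].cumulative_information == e.n_total


def test_control_event_proportion_is_published_allele_frequency(table1):
    assert round(100 * control_event_proportion(table1), 2) == 38.02


# ------------------------------------------------------------ adjusted CI

def _pooled(log_or=0.1554, se=0.07):
    return PooledResult(
        model_used="random", estimator="dersimonian-laird", genetic_model=None,
        log_or=log_or, se=se, het=None, weights=(1.0,),
    )


def test_adjusted_ci_equals_conventional_at_full_information():
    p = _pooled()
    assert tsa_adjusted_ci(p, 1.959964) == pytest.approx(p.ci95, rel=1e-4)


def test_adjusted_ci_is_wider_before_full_information():
    p = _pooled()
    (z_half,) = obf_boundary([0.5])
    lo, hi = tsa_adjusted_ci(p, z_half)
    clo, chi = p.ci95
    assert lo < clo and hi > chi


# ------------------------------------------------------------- full fit

def test_fit_on_fixture_reaches_information_and_crosses_boundary(table1):
    res = TrialSequentialAnalysis(table1, TSAConfig(rri=0.1681, diversity=0.67)).fit()
    assert res.required_is == pytest.approx(2823, rel=0.01)
    assert res.is_reached
    assert res.boundary_crossed
    assert res.adjustment_factor == pytest.approx(1 / (1 - 0.67))
    # boundary z decreases along capped fractions and ends near 1.96
    bz = [z for _, z in res.boundary]
    fr = [f for f, _ in res.boundary]
    assert bz[-1] == pytest.approx(1.96, abs=0.005)
    increasing = [z for f, z in res.boundary if f < 1.0]
    assert all(a > b for a, b in zip(increasing, increasing[1:]))


def test_fit_with_auto_diversity_matches_published_d2(table1):
    res = TrialSequentialAnalysis(table1, TSAConfig(rri=0.1681, diversity="auto")).fit()
    assert res.d2 == pytest.approx(0.67, abs=0.01)
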