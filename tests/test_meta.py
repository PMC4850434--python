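"""Fixed/random pooling, heterogeneity, model selection, leave-one-out."""

import numpy as np
import pytest

from mmtsa import (
    GeneticModel,
    MetaAnalysis,
    heterogeneity,
    leave_one_out,
    pool_fixed,
    pool_fixed_mh,
    pool_random,
    select_model,
)
from mmtsa.effects import ContrastTable, EffectEstimate


def eff(log_or, se, sid="s"):
    return EffectEstimate(study_id=sid, log_or=log_or, se=se)


def test_random_effects_pool_matches_statsmodels_dl(allele_effects):
    """Independent oracle: statsmodels' DerSimonian-Laird combiner."""
    from statsmodels.stats.meta_analysis import combine_effects

    ours = pool_random(allele_effects)
    sm = combine_effects(
        np.array([e.log_or for e in allele_effects]),
        np.array([e.variance for e in allele_effects]),
        method_re="dl",
    )
    assert ours.log_or == pytest.approx(float(sm.mean_effect_re), rel=1e-10)
    assert ours.se == pytest.approx(float(sm.sd_eff_w_re), rel=1e-10)
    assert ours.het.tau2 == pytest.approx(float(sm.tau2), rel=1e-10)


def test_fixed_pool_of_single_study_is_that_study():
    e = eff(0.3, 0.1)
    res = pool_fixed([e])
    assert (res.log_or, res.se) == (pytest.approx(0.3), pytest.approx(0.1))


def test_two_identical_effects_scale_se_by_sqrt2():
    res = pool_fixed([eff(0.2, 0.1, "a"), eff(0.2, 0.1, "b")])
    assert res.log_or == pytest.approx(0.2)
    assert res.se == pytest.approx(0.1 / np.sqrt(2))


def test_identical_effects_have_zero_heterogeneity():
    het = heterogeneity([eff(0.2, 0.1, "a"), eff(0.2, 0.1, "b"), eff(0.2, 0.1, "c")])
    assert het.q == pytest.approx(0.0, abs=1e-12)
    assert het.i2 == 0.0 and het.tau2 == 0.0


def test_random_with_zero_tau2_equals_fixed(allele_effects):
    forced = pool_random(allele_effects, tau2=0.0)
    fixed = pool_fixed(allele_effects)
    assert forced.log_or == pytest.approx(fixed.log_or, rel=1e-12)
    assert forced.se == pytest.approx(fixed.se, rel=1e-12)


def test_random_se_never_smaller_than_fixed(allele_effects):
    assert pool_random(allele_effects).se >= pool_fixed(allele_effects).se


def test_weights_are_normalized(allele_effects):
    for res in (pool_fixed(allele_effects), pool_random(allele_effects)):
        assert sum(res.weights) == pytest.approx(1.0)


def test_i2_is_scale_equivariant(allele_effects):
    """Multiplying all effects and SEs by c leaves Q and I^2 unchanged."""
    c = 3.7
    scaled = [eff(e.log_or * c, e.se * c, e.study_id) for e in allele_effects]
    h0, h1 = heterogeneity(allele_effects), heterogeneity(scaled)
    assert h1.q == pytest.approx(h0.q, rel=1e-10)
    assert h1.i2 == pytest.approx(h0.i2, rel=1e-10)


@pytest.mark.parametrize(
    "q, df, expect",
    [(20.0, 8, "random"), (8.0, 8, "fixed"), (0.0, 8, "fixed")],
)
def test_model_selection_rule(q, df, expect):
    from scipy import stats

    from mmtsa.meta import HeterogeneityStats

    i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    stats_ = HeterogeneityStats(q=q, df=df, p_q=float(stats.chi2.sf(q, df)), i2=i2, tau2=0.0)
    assert select_model(stats_) == expect


def test_selection_uses_or_rule_moderate_i2_low_pq():
    """I^2 below 50 but Q-p below 0.10 still selects random effects."""
    from mmtsa.meta import HeterogeneityStats

    het = HeterogeneityStats(q=15.05, df=8, p_q=0.058, i2=46.8, tau2=0.017)
    assert select_model(het) == "random"


def test_mantel_haenszel_equals_woolf_on_a_single_table():
    t = ContrastTable(31, 29, 104, 210)
    e = pool_fixed([eff(np.log(31 * 210 / (29 * 104)), np.sqrt(1/31 + 1/29 + 1/104 + 1/210))])
    mh = pool_fixed_mh([t])
    assert mh.log_or == pytest.approx(e.log_or, rel=1e-12)


def test_leave_one_out_needs_three_studies():
    with pytest.raises(ValueError):
        leave_one_out([eff(0.1, 0.1, "a"), eff(0.1, 0.1, "b")])


def test_leave_one_out_identical_studies_identical_results():
    effects = [eff(0.2, 0.1, s) for s in "abc"]
    results = leave_one_out(effects)
    assert len(results) == 3
    assert len({round(r.log_or, 12) for r in results}) == 1


def test_leave_one_out_omitting_outlier_moves_pool_most():
    effects = [eff(0.1, 0.1, "a"), eff(0.12, 0.1, "b"), eff(0.11, 0.1, "c"), eff(2.0, 0.1, "x")]
    full = pool_random(effects).log_or
    shifts = [abs(r.log_or - full) for r in leave_one_out(effects)]
    assert int(np.argmax(shifts)) == 3


def test_leave_one_out_on_fixture_keeps_all_allele_pools_above_one(table1):
    results = MetaAnalysis(table1, GeneticModel.ALLELE).leave_one_out()
    assert len(results) == 9
    assert all(r.odds_ratio > 1.0 for r in results)


def test_summary_mentions_contrast_and_or(table1):
    text = MetaAnalysis(table1, "allele").fit().summary()
    assert "T vs C" in text and "1.16" in text
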