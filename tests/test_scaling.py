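"""Closed-form scaling-test estimators: unbiasedness, variances, t-tests."""

import math
from fractions import Fraction as F

import numpy as np
import pytest

from rilcross import (ALL_NAMES, FULL_MODEL, GenerationMeans,
                      compare_methods, effect_coefficient, estimate_effect,
                      estimator_catalog, expected_generation_means,
                      simulate_individuals, SimulationConfig)
from tests.conftest import means_from_dict

EFFECTS = FULL_MODEL.labels  # mu, A, D, AA, AD, DD


@pytest.mark.parametrize("method", ["traditional", "ril"])
@pytest.mark.parametrize("effect", EFFECTS)
def test_every_estimator_is_exactly_unbiased(method, effect):
    """The contrast's coefficients times the exact design rows recover the
    indicator vector of the target effect (rational arithmetic, no
    tolerance)."""
    est = estimator_catalog(method)[effect]
    recovered = [sum((c * effect_coefficient(g, term)
                      for g, c in est.coefficients.items()), F(0))
                 for term in FULL_MODEL.terms]
    expected = [F(1) if t.label == effect else F(0) for t in FULL_MODEL.terms]
    assert recovered == expected


def test_equal_variance_contrast_variances_are_exact():
    trad = estimator_catalog("traditional")
    ril = estimator_catalog("ril")
    assert {e: trad[e].unit_variance() for e in ("D", "AA", "DD")} == \
        {"D": F(51, 8), "AA": F(24), "DD": F(27, 8)}   # 6.375, 24, 3.375
    assert {e: ril[e].unit_variance() for e in ("D", "AA", "DD")} == \
        {"D": F(1, 2), "AA": F(3, 2), "DD": F(3, 2)}
    assert trad["mu"].unit_variance() == F(1)
    assert trad["A"].unit_variance() == F(2)
    assert trad["AD"].unit_variance() == F(5, 2)


def test_ril_contrasts_use_fewer_generation_means():
    ril = estimator_catalog("ril")
    assert len(ril["A"].generations) == 2
    assert len(ril["D"].generations) == 2
    assert len(ril["AA"].generations) == 3
    assert len(ril["DD"].generations) == 3
    assert len(ril["AD"].generations) == 4  # RIL mean cannot shorten AD


def test_mu_a_ad_shared_between_catalogs():
    trad, ril = estimator_catalog("traditional"), estimator_catalog("ril")
    for e in ("mu", "A", "AD"):
        assert trad[e].coefficients == ril[e].coefficients


def test_unknown_method_rejected():
    with pytest.raises(ValueError, match="unknown method"):
        estimator_catalog("bayesian")


def test_symmetric_input_gives_zero_dominance():
    gm = means_from_dict({"F1": 7.3, "RIL": 7.3}, variance=1.0, n=10)
    est = estimate_effect("D", "ril", gm)
    assert est.estimate == 0.0


def test_constant_means_give_zero_for_all_non_mu_effects():
    gm = means_from_dict({g: 42.0 for g in ALL_NAMES}, variance=1.0, n=10)
    for method in ("traditional", "ril"):
        for e in EFFECTS:
            est = estimate_effect(e, method, gm)
            expected = 42.0 if e == "mu" else 0.0
            assert est.estimate == pytest.approx(expected, abs=1e-12)


def test_noiseless_means_recover_arbitrary_effects(equal_variance_means):
    effects, gm = equal_variance_means
    for method in ("traditional", "ril"):
        for e in EFFECTS:
            est = estimate_effect(e, method, gm)
            assert est.estimate == pytest.approx(effects[e], abs=1e-10)


def test_missing_generation_named_in_error():
    gm = means_from_dict({"F1": 1.0}, variance=1.0, n=5)
    with pytest.raises(KeyError, match="RIL"):
        estimate_effect("D", "ril", gm)


def test_zero_se_flagged_degenerate():
    gm = means_from_dict({"F1": 3.0, "RIL": 1.0}, variance=0.0, n=5)
    est = estimate_effect("D", "ril", gm)
    assert est.degenerate and est.p is None and est.estimate == 1.0


def test_df_policies():
    gm = means_from_dict({"F1": 3.0, "RIL": 1.0}, variance=1.0, n=10)
    assert estimate_effect("D", "ril", gm, df_policy="paper").df == 1.0
    assert estimate_effect("D", "ril", gm, df_policy="pooled").df == 18.0
    # equal variances and n: Satterthwaite reduces to the pooled-like value
    sw = estimate_effect("D", "ril", gm, df_policy="satterthwaite").df
    assert sw == pytest.approx(18.0)
    with pytest.raises(ValueError):
        estimate_effect("D", "ril", gm, df_policy="bonferroni")


def test_simulation_round_trip_estimates_and_se_ratio():
    """mu=100, D=5: both methods recover D; the RIL contrast's SE is smaller
    by about sqrt(0.5/6.375)."""
    cfg = SimulationConfig(effects={"mu": 100.0, "D": 5.0}, n=10_000,
                           sigma_E=1.0, seed=7)
    gm = GenerationMeans.from_dataframe(simulate_individuals(cfg))
    ril = estimate_effect("D", "ril", gm)
    trad = estimate_effect("D", "traditional", gm)
    assert ril.estimate == pytest.approx(5.0, abs=4 * ril.se)
    assert trad.estimate == pytest.approx(5.0, abs=4 * trad.se)
    assert ril.se < trad.se
    assert ril.se / trad.se == pytest.approx(math.sqrt(0.5 / 6.375), rel=0.1)


class TestCompareMethods:
    def test_equal_variance_reductions(self, equal_variance_means):
        _, gm = equal_variance_means
        table = compare_methods(gm).set_index("effect")
        assert table.loc["D", "var_reduction_pct"] == pytest.approx(
            100 * (1 - 0.5 / 6.375))
        assert table.loc["AA", "var_reduction_pct"] == pytest.approx(93.75)
        assert table.loc["DD", "var_reduction_pct"] == pytest.approx(
            100 * (1 - 1.5 / 3.375))

    def test_inflated_ril_variance_shrinks_reductions(self):
        means = expected_generation_means({"mu": 10.0}, ALL_NAMES)
        base = GenerationMeans({g: (m, 1.0, 1) for g, m in means.items()})
        infl = GenerationMeans({g: (m, 10.0 if g == "RIL" else 1.0, 1)
                                for g, m in means.items()})
        t0 = compare_methods(base).set_index("effect")
        t1 = compare_methods(infl).set_index("effect")
        for e in ("D", "AA", "DD"):
            assert t1.loc[e, "var_reduction_pct"] < \
                t0.loc[e, "var_reduction_pct"]

    def test_shared_contrasts_agree_across_methods(self, equal_variance_means):
        _, gm = equal_variance_means
        table = compare_methods(gm).set_index("effect")
        for e in ("A", "AD"):
            assert table.loc[e, "estimate_traditional"] == \
                table.loc[e, "estimate_ril"]
            assert table.loc[e, "var_reduction_pct"] == pytest.approx(0.0)
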