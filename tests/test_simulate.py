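"""Simulators: expected means, noise model, Mendelian per-locus sampling."""

import numpy as np
import pandas as pd
import pytest

from rilcross import (ALL_NAMES, GenerationMeans, LocusModel,
                      SimulationConfig, estimate_effect,
                      estimator_catalog, expected_generation_means,
                      finite_selfing_hybridity, simulate_genotypes,
                      simulate_individuals, simulate_perlocus)


def test_expected_means_additive_only():
    means = expected_generation_means({"mu": 10.0, "A": 2.0}, ALL_NAMES)
    assert means == {"P1": 12.0, "P2": 8.0, "F1": 10.0, "F2": 10.0,
                     "B1": 11.0, "B2": 9.0, "RIL": 10.0}


def test_expected_means_dominance_only():
    means = expected_generation_means({"D": 1.0}, ALL_NAMES)
    assert means == {"P1": -1.0, "P2": -1.0, "F1": 1.0, "F2": 0.0,
                     "B1": 0.0, "B2": 0.0, "RIL": -1.0}


def test_expected_means_mu_only_is_constant():
    means = expected_generation_means({"mu": 7.0}, ALL_NAMES)
    assert set(means.values()) == {7.0}


def test_zero_noise_individuals_equal_their_generation_mean():
    cfg = SimulationConfig(effects={"mu": 5.0, "A": 1.0}, n=10, sigma_E=0.0,
                           seed=1)
    df = simulate_individuals(cfg)
    means = expected_generation_means(cfg.effects, ALL_NAMES)
    for g, grp in df.groupby("generation"):
        assert np.all(grp["phenotype"].to_numpy() == means[g])


def test_same_seed_gives_identical_tables():
    cfg = dict(effects={"mu": 1.0, "DD": 2.0}, n=50, sigma_E=1.5, seed=99)
    a = simulate_individuals(SimulationConfig(**cfg))
    b = simulate_individuals(SimulationConfig(**cfg))
    pd.testing.assert_frame_equal(a, b)
    c = simulate_individuals(SimulationConfig(**{**cfg, "seed": 100}))
    assert not a["phenotype"].equals(c["phenotype"])


def test_variance_inflation_scales_generation_variance(rng):
    cfg = SimulationConfig(effects={"mu": 0.0}, n=4000, sigma_E=1.0,
                           variance_inflation={"RIL": 4.0}, seed=3)
    df = simulate_individuals(cfg)
    v = df.groupby("generation")["phenotype"].var()
    assert v["RIL"] / v["F1"] == pytest.approx(4.0, rel=0.2)


def test_empirical_unbiasedness_of_both_catalogs(rng):
    """Monte-Carlo mean of each estimator equals the truth within error
    (generation means drawn with unit variance around their expectations)."""
    effects = {"mu": 20.0, "A": 1.0, "D": -2.0, "AA": 0.5, "AD": 1.5,
               "DD": -1.0}
    means = expected_generation_means(effects, ALL_NAMES)
    reps = 2000
    draws = {g: rng.normal(means[g], 1.0, reps) for g in ALL_NAMES}
    for method in ("traditional", "ril"):
        for label, est in estimator_catalog(method).items():
            vals = sum(float(c) * draws[g]
                       for g, c in est.coefficients.items())
            mc_se = float(np.sqrt(float(est.unit_variance()) / reps))
            assert abs(vals.mean() - effects[label]) < 4 * mc_se


class TestPerLocus:
    def test_single_locus_reduces_to_composite_model(self):
        lm = LocusModel(additive=[1.0], mu=3.0)
        df, effects = simulate_perlocus(lm, n=20_000, sigma_E=0.0, seed=21)
        assert effects == {"mu": 3.0, "A": 1.0, "D": 0.0, "AA": 0.0,
                           "AD": 0.0, "DD": 0.0}
        expected = expected_generation_means(effects, ALL_NAMES)
        emp = df.groupby("generation")["phenotype"].mean()
        for g in ALL_NAMES:
            # genotype-sampling error only; sd per locus <= 1
            assert emp[g] == pytest.approx(expected[g], abs=0.05)

    def test_canceling_loci_hide_from_composite_additive_effect(self):
        """a1 = +5, a2 = -5: no net additive difference between parents, but
        the segregating RIL generation is far more variable than the F1."""
        lm = LocusModel(additive=[5.0, -5.0])
        df, effects = simulate_perlocus(lm, n=800, sigma_E=1.0, seed=22)
        assert effects["A"] == 0.0
        gm = GenerationMeans.from_dataframe(df)
        assert gm.mean("P1") == pytest.approx(gm.mean("P2"), abs=0.3)
        for method in ("traditional", "ril"):
            est = estimate_effect("A", method, gm)
            assert abs(est.estimate) < 4 * est.se
        assert gm.variance("RIL") > gm.variance("F1")
        assert gm.variance("F2") > gm.variance("F1")

    def test_pairwise_interactions_feed_composite_effects(self):
        lm = LocusModel(additive=[1.0, 0.5], dominance=[0.2, 0.0],
                        interactions={(0, 1): {"aa": 2.0, "dd": -1.0}})
        df, effects = simulate_perlocus(lm, n=50_000, sigma_E=0.0, seed=23)
        assert effects["AA"] == 2.0 and effects["DD"] == -1.0
        expected = expected_generation_means(effects, ALL_NAMES)
        emp = df.groupby("generation")["phenotype"].mean()
        for g in ALL_NAMES:
            assert emp[g] == pytest.approx(expected[g], abs=0.08)

    def test_ril_heterozygosity_matches_selfing_theory(self, rng):
        t = 3
        geno = simulate_genotypes("RIL", 2000, 50, rng, t_selfing=t)
        het = float((geno == 0).mean())
        expect = float(finite_selfing_hybridity(t).H)  # (1/2)^3
        se = np.sqrt(expect * (1 - expect) / geno.size)
        assert abs(het - expect) < 4 * se
        ideal = simulate_genotypes("RIL", 500, 20, rng, t_selfing=None)
        assert not np.any(ideal == 0)

    def test_generation_genotype_laws(self, rng):
        assert np.all(simulate_genotypes("P1", 10, 4, rng) == 1)
        assert np.all(simulate_genotypes("P2", 10, 4, rng) == -1)
        assert np.all(simulate_genotypes("F1", 10, 4, rng) == 0)
        b1 = simulate_genotypes("B1", 5000, 2, rng)
        assert set(np.unique(b1)) == {0, 1}
        f2 = simulate_genotypes("F2", 20_000, 1, rng)
        assert (f2 == 0).mean() == pytest.approx(0.5, abs=0.02)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            LocusModel(additive=[])
        with pytest.raises(ValueError):
            LocusModel(additive=[1.0], dominance=[1.0, 2.0])
        with pytest.raises(ValueError):
            LocusModel(additive=[1.0, 2.0],
                       interactions={(0, 5): {"aa": 1.0}})
        with pytest.raises(ValueError):
            LocusModel(additive=[1.0, 2.0],
                       interactions={(0, 1): {"ab": 1.0}})
        with pytest.raises(ValueError):
            simulate_genotypes("F9", 5, 2, rng)
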