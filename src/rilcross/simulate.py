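"""Simulation of line-cross phenotype data with known truth.

Two levels are supported:

* **composite-effect level** — generation means are computed directly from a
  set of true composite effects (mu, A, D, AA, AD, DD) through the
  source/hybridity design, and individuals are those means plus Gaussian
  environmental noise;
* **per-locus level** — diallelic loci with additive and dominance values
  (and optional pairwise interactions) are Mendelian-sampled through the
  cross, so that segregation variance, transgressive segregation and
  canceling-effect loci emerge mechanistically.  The composite effects
  implied by the locus model are returned alongside the data, so truth is
  always known.

Per-locus values use the F2-reference metric: for locus k with individual
genotype score ``s in {-1, 0, +1}`` (count of P1 alleles minus 1) and
hybridity score ``h in {-1, +1}`` (+1 heterozygous), the genotypic value is
``a_k * s + d_k * h``; pairwise terms are ``aa*s_j*s_k``, ``ad*s_j*h_k``,
``dd*h_j*h_k``.  Generation expectations of s and h are exactly the source
and hybridity indices, so summed locus values reproduce the composite-effect
model: A = sum a_k, D = sum d_k, etc.

All randomness flows through a mandatory seed; identical configs give
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (ALL_NAMES, GenerationSpec, effect_coefficient,
                     finite_selfing_hybridity, resolve_generation)

__all__ = [
    "SimulationConfig",
    "LocusModel",
    "expected_generation_means",
    "simulate_individuals",
    "simulate_genotypes",
    "simulate_perlocus",
]


def expected_generation_means(effects: Mapping[str, float],
                              generations: Sequence[str | GenerationSpec]
                              = ALL_NAMES) -> dict[str, float]:
    """Noiseless generation means implied by composite effects.

    ``mean_g = sum_term coefficient(g, term) * effect_term``; the F2 mean is
    exactly mu.
    """
    out = {}
    for g in generations:
        spec = resolve_generation(g)
        out[spec.name] = float(sum(
            float(effect_coefficient(spec, term)) * value
            for term, value in effects.items()))
    return out


@dataclass
class SimulationConfig:
    """Composite-effect level simulation settings.

    Parameters
    ----------
    effects
        True composite effects, e.g. ``{"mu": 100, "D": 5}`` (phenotype
        units); omitted effects are zero.
    n
        Individuals per generation: one int for all, or a per-generation map
        (whose keys then define which generations are simulated).
    sigma_E
        Environmental (within-generation) standard deviation.
    variance_inflation
        Optional per-generation multiplier on the phenotypic *variance*
        (e.g. ``{"F2": 2.0, "RIL": 3.0}`` to mimic segregation variance).
    t_selfing
        Selfing generations for the RIL; ``None`` means the idealized fully
        homozygous RIL (hybridity index exactly -1).
    seed
        Mandatory seed for reproducibility.
    """

    effects: Mapping[str, float]
    n: Mapping[str, int] | int = 100
    sigma_E: float = 1.0
    variance_inflation: Mapping[str, float] = field(default_factory=dict)
    t_selfing: int | None = None
    seed: int = 0
    generations: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.sigma_E < 0:
            raise ValueError(f"sigma_E must be >= 0, got {self.sigma_E}")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducible runs")

    def generation_list(self) -> list[str]:
        if self.generations is not None:
            gens = [str(g).upper() for g in self.generations]
        elif isinstance(self.n, Mapping):
            gens = [str(g).upper() for g in self.n]
        else:
            gens = list(ALL_NAMES)
        return gens

    def n_for(self, g: str) -> int:
        n = self.n[g] if isinstance(self.n, Mapping) else self.n
        if n < 1:
            raise ValueError(f"n must be >= 1 for {g}, got {n}")
        return int(n)

    def spec_for(self, g: str) -> GenerationSpec:
        if g == "RIL" and self.t_selfing is not None:
            return finite_selfing_hybridity(self.t_selfing, name="RIL")
        return resolve_generation(g)


def simulate_individuals(config: SimulationConfig) -> pd.DataFrame:
    """Simulate per-individual phenotypes around the composite-effect means.

    Returns a tidy table with columns ``generation``, ``id``, ``phenotype``.
    Each phenotype is the generation's expected mean plus a
    ``N(0, sigma_g^2)`` draw, ``sigma_g^2 = inflation_g * sigma_E^2``.
    """
    rng = np.random.default_rng(config.seed)
    gens = config.generation_list()
    frames = []
    for g in gens:
        spec = config.spec_for(g)
        mean = expected_generation_means(config.effects, [spec])[spec.name]
        n = config.n_for(g)
        sd = config.sigma_E * float(np.sqrt(
            config.variance_inflation.get(g, 1.0)))
        values = mean + rng.normal(0.0, sd, n) if sd > 0 else np.full(n, mean)
        frames.append(pd.DataFrame({
            "generation": g,
            "id": [f"{g}_{i + 1:05d}" for i in range(n)],
            "phenotype": values,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Per-locus simulation
# ---------------------------------------------------------------------------


@dataclass
class LocusModel:
    """Diallelic loci in the F2-reference metric; P1 carries the '+' allele
    at every locus.

    ``interactions`` maps an ordered locus pair ``(j, k)`` to a dict with
    any of the keys ``"aa"``, ``"ad"``, ``"dd"``; ``"ad"`` pairs locus j's
    additive score with locus k's hybridity score.
    """

    additive: Sequence[float]
    dominance: Sequence[float] | None = None
    interactions: Mapping[tuple[int, int], Mapping[str, float]] = field(
        default_factory=dict)
    mu: float = 0.0

    def __post_init__(self) -> None:
        self.additive = np.asarray(self.additive, dtype=float)
        if self.additive.size < 1:
            raise ValueError("at least one locus is required")
        if self.dominance is None:
            self.dominance = np.zeros_like(self.additive)
        else:
            self.dominance = np.asarray(self.dominance, dtype=float)
        if self.dominance.shape != self.additive.shape:
            raise ValueError("additive and dominance value lists must have "
                             "the same length")
        if not (np.all(np.isfinite(self.additive))
                and np.all(np.isfinite(self.dominance))):
            raise ValueError("locus values must be finite")
        L = self.additive.size
        for (j, k), vals in self.interactions.items():
            if not (0 <= j < L and 0 <= k < L) or j == k:
                raise ValueError(f"invalid interaction pair ({j}, {k}) "
                                 f"for {L} loci")
            bad = set(vals) - {"aa", "ad", "dd"}
            if bad:
                raise ValueError(f"unknown interaction keys {sorted(bad)} "
                                 f"for pair ({j}, {k})")

    @property
    def n_loci(self) -> int:
        return int(self.additive.size)

    def composite_effects(self) -> dict[str, float]:
        """Composite effects implied by summing locus values."""
        eff = {"mu": self.mu,
               "A": float(self.additive.sum()),
               "D": float(self.dominance.sum()),
               "AA": 0.0, "AD": 0.0, "DD": 0.0}
        for vals in self.interactions.values():
            eff["AA"] += float(vals.get("aa", 0.0))
            eff["AD"] += float(vals.get("ad", 0.0))
            eff["DD"] += float(vals.get("dd", 0.0))
        return eff


def simulate_genotypes(generation: str, n_individuals: int, n_loci: int,
                       rng: np.random.Generator,
                       t_selfing: int | None = None) -> np.ndarray:
    """Mendelian-sample genotype scores for unlinked loci.

    Returns an (n_individuals, n_loci) int array of genotype scores in
    {-1, 0, +1}: +1 = P1/P1, 0 = heterozygous, -1 = P2/P2.  RIL genotypes
    start from an F2 draw, then each heterozygous locus is re-segregated
    through ``t_selfing`` rounds of selfing (infinite rounds when None, so
    every locus fixes at random).
    """
    g = str(generation).strip().upper()
    shape = (n_individuals, n_loci)
    if g == "P1":
        return np.ones(shape, dtype=int)
    if g == "P2":
        return -np.ones(shape, dtype=int)
    if g == "F1":
        return np.zeros(shape, dtype=int)
    if g == "F2":
        # sum of two independent allele draws
        return (rng.integers(0, 2, shape) + rng.integers(0, 2, shape) - 1)
    if g == "B1":
        return rng.integers(0, 2, shape)          # {het, P1P1}
    if g == "B2":
        return rng.integers(0, 2, shape) - 1      # {P2P2, het}
    if g == "RIL":
        geno = (rng.integers(0, 2, shape) + rng.integers(0, 2, shape) - 1)
        if t_selfing is None:
            het = geno == 0
            geno[het] = rng.choice([-1, 1], size=int(het.sum()))
        else:
            if t_selfing < 1:
                raise ValueError("t_selfing must be >= 1")
            # the F2 already is one selfing generation past the F1
            for _ in range(t_selfing - 1):
                het = geno == 0
                k = int(het.sum())
                geno[het] = (rng.integers(0, 2, k)
                             + rng.integers(0, 2, k) - 1)
        return geno
    raise ValueError(f"unknown generation {generation!r}")


def simulate_perlocus(lm: LocusModel,
                      generations: Sequence[str] = ALL_NAMES,
                      n: Mapping[str, int] | int = 100,
                      sigma_E: float = 1.0,
                      t_selfing: int | None = None,
                      seed: int = 0,
                      ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate phenotypes from an explicit locus model.

    Returns the tidy phenotype table and the composite effects implied by
    the locus model (so estimators can be checked against known truth).
    Loci segregate independently (free recombination).
    """
    if sigma_E < 0:
        raise ValueError(f"sigma_E must be >= 0, got {sigma_E}")
    rng = np.random.default_rng(seed)
    a, d = lm.additive, lm.dominance
    frames = []
    for g in (str(x).upper() for x in generations):
        ng = int(n[g] if isinstance(n, Mapping) else n)
        geno = simulate_genotypes(g, ng, lm.n_loci, rng, t_selfing)
        s = geno.astype(float)                      # additive score
        h = np.where(geno == 0, 1.0, -1.0)          # hybridity score
        value = lm.mu + s @ a + h @ d
        for (j, k), vals in lm.interactions.items():
            value = (value
                     + vals.get("aa", 0.0) * s[:, j] * s[:, k]
                     + vals.get("ad", 0.0) * s[:, j] * h[:, k]
                     + vals.get("dd", 0.0) * h[:, j] * h[:, k])
        if sigma_E > 0:
            value = value + rng.normal(0.0, sigma_E, ng)
        frames.append(pd.DataFrame({
            "generation": g,
            "id": [f"{g}_{i + 1:05d}" for i in range(ng)],
            "phenotype": value,
        }))
    return pd.concat(frames, ignore_index=True), lm.composite_effects()
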