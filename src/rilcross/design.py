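"""Generations, effect models, and design matrices for line cross analysis.

A line cross between two inbred parents (P1, P2) produces generations (F1,
F2, backcrosses B1/B2, recombinant inbred lines RIL) whose expected
phenotypic means are linear in a set of *composite genetic effects*: the F2
reference mean mu, the net additive effect A, the net dominance effect D,
and pairwise epistatic effects AA, AD, DD.  Each generation is summarised by
two indices:

* the **source index** ``theta_S = 2*S - 1`` where S is the proportion of
  the generation's genome derived from P1, and
* the **hybridity index** ``theta_H = 2*H - 1`` where H is the expected
  proportion of heterozygous loci.

The coefficient of an effect with ``a`` additive and ``d`` dominance factors
in a generation's mean is ``theta_S**a * theta_H**d`` (with ``0**0 == 1`` so
mu always has coefficient 1).  Coefficients are exact rationals
(:class:`fractions.Fraction`); floating point enters only at estimation
time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "EffectTerm",
    "EffectModel",
    "GenerationSpec",
    "MarkerMatrix",
    "SourceIndexEstimate",
    "STANDARD_GENERATIONS",
    "FULL_MODEL",
    "effect_coefficient",
    "build_design_matrix",
    "design_matrix_array",
    "finite_selfing_hybridity",
    "estimate_source_index_from_markers",
]

RationalLike = Union[Fraction, int, str]


def _frac(x: RationalLike) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(x)


@dataclass(frozen=True, order=True)
class EffectTerm:
    """A composite-effect term with ``a`` additive and ``d`` dominance factors.

    ``(0, 0)`` is mu (the F2 reference mean), ``(1, 0)`` is A, ``(0, 1)`` is
    D, ``(2, 0)`` AA, ``(1, 1)`` AD, ``(0, 2)`` DD; higher orders (AAA, AAD,
    ...) are representable the same way.
    """

    a: int
    d: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.d < 0:
            raise ValueError(f"invalid effect term ({self.a}, {self.d}): "
                             "factor counts must be non-negative")

    @property
    def label(self) -> str:
        if self.a == 0 and self.d == 0:
            return "mu"
        return "A" * self.a + "D" * self.d

    @classmethod
    def parse(cls, term: "EffectTerm | str | tuple[int, int]") -> "EffectTerm":
        if isinstance(term, EffectTerm):
            return term
        if isinstance(term, tuple):
            return cls(*term)
        s = term.strip()
        if s.lower() in ("mu", "m", "μ"):
            return cls(0, 0)
        up = s.upper()
        if up and set(up) <= {"A", "D"}:
            return cls(up.count("A"), up.count("D"))
        raise ValueError(f"cannot parse effect term {term!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


MU = EffectTerm(0, 0)
A = EffectTerm(1, 0)
D = EffectTerm(0, 1)
AA = EffectTerm(2, 0)
AD = EffectTerm(1, 1)
DD = EffectTerm(0, 2)


class EffectModel:
    """An ordered set of effect terms defining the columns of a design matrix.

    mu is always included and comes first; remaining terms are ordered by
    total order ``a + d`` then by ``a`` descending, which puts A before D
    and AA before AD before DD.
    """

    def __init__(self, terms: Iterable[EffectTerm | str | tuple[int, int]]):
        parsed = [EffectTerm.parse(t) for t in terms]
        seen: set[EffectTerm] = set()
        unique = []
        for t in parsed:
            if t not in seen:
                seen.add(t)
                unique.append(t)
        non_mu = [t for t in unique if t != MU]
        non_mu.sort(key=lambda t: (t.a + t.d, -t.a))
        self.terms: tuple[EffectTerm, ...] = (MU, *non_mu)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __contains__(self, term) -> bool:
        return EffectTerm.parse(term) in self.terms

    def __eq__(self, other) -> bool:
        return isinstance(other, EffectModel) and self.terms == other.terms

    def __hash__(self) -> int:
        return hash(self.terms)

    def __repr__(self) -> str:
        return f"EffectModel([{', '.join(self.labels)}])"

    def is_nested_in(self, other: "EffectModel") -> bool:
        return set(self.terms) <= set(other.terms)


#: The full pairwise model mu, A, D, AA, AD, DD.
FULL_MODEL = EffectModel(["mu", "A", "D", "AA", "AD", "DD"])


@dataclass(frozen=True)
class GenerationSpec:
    """A cross generation identified by its source and hybridity indices.

    Parameters
    ----------
    name
        Generation label, e.g. ``"P1"`` or ``"RIL"``.
    S
        Proportion of the genome derived from P1, in [0, 1].
    H
        Expected proportion of heterozygous loci, in [0, 1].
    """

    name: str
    S: Fraction
    H: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", _frac(self.S))
        object.__setattr__(self, "H", _frac(self.H))
        if not 0 <= self.S <= 1:
            raise ValueError(f"{self.name}: S={self.S} outside [0, 1]")
        if not 0 <= self.H <= 1:
            raise ValueError(f"{self.name}: H={self.H} outside [0, 1]")

    @property
    def theta_S(self) -> Fraction:
        """Source index, 2*S - 1, in [-1, +1]."""
        return 2 * self.S - 1

    @property
    def theta_H(self) -> Fraction:
        """Hybridity index, 2*H - 1, in [-1, +1]."""
        return 2 * self.H - 1

    @classmethod
    def from_theta(cls, name: str, theta_S: RationalLike,
                   theta_H: RationalLike) -> "GenerationSpec":
        return cls(name, (1 + _frac(theta_S)) / 2, (1 + _frac(theta_H)) / 2)


#: The seven standard generations of a biparental cross (idealized RIL with
#: theta_H exactly -1, i.e. an infinite number of selfing generations).
STANDARD_GENERATIONS: dict[str, GenerationSpec] = {
    "P1": GenerationSpec("P1", Fraction(1), Fraction(0)),
    "P2": GenerationSpec("P2", Fraction(0), Fraction(0)),
    "F1": GenerationSpec("F1", Fraction(1, 2), Fraction(1)),
    "F2": GenerationSpec("F2", Fraction(1, 2), Fraction(1, 2)),
    "B1": GenerationSpec("B1", Fraction(3, 4), Fraction(1, 2)),
    "B2": GenerationSpec("B2", Fraction(1, 4), Fraction(1, 2)),
    "RIL": GenerationSpec("RIL", Fraction(1, 2), Fraction(0)),
}

#: The six classical generations (no RIL).
CLASSICAL_NAMES = ("P1", "P2", "F1", "F2", "B1", "B2")
#: All seven, RIL last.
ALL_NAMES = CLASSICAL_NAMES + ("RIL",)


def resolve_generation(gen: GenerationSpec | str) -> GenerationSpec:
    """Return a :class:`GenerationSpec`, resolving standard labels
    case-insensitively."""
    if isinstance(gen, GenerationSpec):
        return gen
    key = gen.strip().upper()
    if key in STANDARD_GENERATIONS:
        return STANDARD_GENERATIONS[key]
    raise KeyError(f"unknown generation {gen!r}; known: {sorted(STANDARD_GENERATIONS)}")


def effect_coefficient(gen: GenerationSpec | str,
                       term: EffectTerm | str | tuple[int, int]) -> Fraction:
    """Exact coefficient of an effect term in a generation's expected mean.

    Returns ``theta_S**a * theta_H**d`` as a :class:`~fractions.Fraction`,
    with the convention ``0**0 == 1`` so mu's coefficient is always 1.
    """
    g = resolve_generation(gen)
    t = EffectTerm.parse(term)
    return g.theta_S ** t.a * g.theta_H ** t.d


def build_design_matrix(generations: Sequence[GenerationSpec | str],
                        model: EffectModel = FULL_MODEL,
                        ) -> list[list[Fraction]]:
    """Exact design matrix: rows = generations, columns = model terms.

    Entry (i, j) is ``effect_coefficient(generations[i], model.terms[j])``.
    The first column (mu) is all ones.
    """
    gens = [resolve_generation(g) for g in generations]
    if len(gens) == 0:
        raise ValueError("at least one generation is required")
    names = [g.name for g in gens]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate generation names: {dupes}")
    return [[effect_coefficient(g, t) for t in model.terms] for g in gens]


def design_matrix_array(generations: Sequence[GenerationSpec | str],
                        model: EffectModel = FULL_MODEL) -> np.ndarray:
    """Floating-point design matrix (for estimation)."""
    return np.array(build_design_matrix(generations, model), dtype=float)


def finite_selfing_hybridity(t: int, name: str | None = None) -> GenerationSpec:
    """Generation spec for a RIL population after ``t`` generations of
    selfing from the F1.

    Heterozygosity halves each selfing generation: ``H = (1/2)**t``, so
    ``theta_H = 2*(1/2)**t - 1 -> -1`` as t grows; ``theta_S = 0``
    throughout.  ``t = 1`` is the F2 itself (H = 1/2, theta_H = 0).
    """
    if not isinstance(t, (int, np.integer)) or t < 1:
        raise ValueError(f"selfing generations t must be an integer >= 1, got {t!r}")
    return GenerationSpec(name or f"RIL_t{t}", Fraction(1, 2), Fraction(1, 2 ** t))


# ---------------------------------------------------------------------------
# Marker-based source index for RIL populations
# ---------------------------------------------------------------------------

#: Recognized marker call codes (case-insensitive).  Anything in
#: ``MISSING_CODES`` (or a null cell) is treated as missing.
P1_CODE, P2_CODE, HET_CODE = "P1", "P2", "HET"
MISSING_CODES = {"NA", "MISSING", "", "NAN", "N", "-"}


@dataclass
class MarkerMatrix:
    """RIL marker genotypes: lines x markers, alleles coded by parental origin.

    ``calls`` holds uppercase codes ``P1``/``P2``/``HET`` or ``None`` for
    missing, indexed by line (rows) and marker (columns).
    """

    calls: pd.DataFrame
    het_warn_threshold: float = 0.05

    def __post_init__(self) -> None:
        norm = self.calls.astype("object").copy()
        for col in norm.columns:
            norm[col] = [self._normalize(v) for v in norm[col]]
        self.calls = norm
        flat = [v for v in norm.to_numpy().ravel() if v is not None]
        if not flat:
            raise ValueError("marker matrix contains no non-missing calls")
        het = sum(v == HET_CODE for v in flat) / len(flat)
        if het > self.het_warn_threshold:
            warnings.warn(
                f"heterozygous call frequency {het:.1%} exceeds "
                f"{self.het_warn_threshold:.1%}; lines may not be fully inbred",
                stacklevel=2)

    @staticmethod
    def _normalize(v) -> str | None:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        s = str(v).strip().upper()
        if s in MISSING_CODES:
            return None
        if s in (P1_CODE, P2_CODE, HET_CODE, "H"):
            return HET_CODE if s == "H" else s
        raise ValueError(f"unrecognized marker call {v!r}")

    @property
    def lines(self) -> list:
        return list(self.calls.index)

    @property
    def markers(self) -> list:
        return list(self.calls.columns)

    @classmethod
    def from_csv(cls, path, **read_csv_kwargs) -> "MarkerMatrix":
        df = pd.read_csv(path, index_col=0, dtype=str, **read_csv_kwargs)
        return cls(df)


@dataclass(frozen=True)
class SourceIndexEstimate:
    """Marker-based estimate of a RIL population's source index."""

    theta_S: Fraction
    p1_alleles: int
    total_alleles: int

    def __float__(self) -> float:
        return float(self.theta_S)


def estimate_source_index_from_markers(m: MarkerMatrix) -> SourceIndexEstimate:
    """Estimate theta_S as ``2 * (P1 alleles / total alleles) - 1``.

    Each homozygous call contributes two alleles of its parent's type, each
    heterozygous call one of each; missing calls are excluded from both the
    numerator and the denominator.  Under Mendelian segregation the result
    is close to zero; a marked deviation indicates segregation distortion.
    """
    p1 = total = 0
    for v in m.calls.to_numpy().ravel():
        if v is None:
            continue
        total += 2
        if v == P1_CODE:
            p1 += 2
        elif v == HET_CODE:
            p1 += 1
    if total == 0:
        raise ValueError("all marker calls are missing")
    return SourceIndexEstimate(2 * Fraction(p1, total) - 1, p1, total)
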