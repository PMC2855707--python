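"""Joint scaling tests: simultaneous weighted least-squares estimation of
composite genetic effects from a vector of generation means.

Given observed generation means ``Y``, a design matrix ``X`` built from the
source/hybridity indices, and an effect vector ``beta``, the model is
``Y = X beta``.  Estimation is ordinary least squares
``(X'X)^{-1} X'Y`` or, when generation means have unequal precision,
weighted least squares ``(X'V^{-1}X)^{-1} X'V^{-1}Y`` with ``V`` the
diagonal matrix of squared standard errors of the means.  Model adequacy is
assessed by ``chi2 = sum_i (y_i - yhat_i)^2 / Var(z_i)`` on
``#generations - #parameters`` degrees of freedom, and increasingly complex
nested models are fit until one is adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

from .design import (EffectModel, FULL_MODEL, GenerationSpec,
                     build_design_matrix, resolve_generation)
from .scaling import GenerationMeans

__all__ = [
    "JointScalingFit",
    "GoodnessOfFit",
    "ModelSearchResult",
    "fit_joint",
    "goodness_of_fit",
    "sequential_model_search",
    "default_hierarchy",
]

#: Relative singular-value tolerance below which the design is declared
#: rank-deficient (confounded effects).
RANK_TOL = 1e-10


class RankDeficientDesign(ValueError):
    """The design matrix does not identify all requested effects."""


@dataclass
class JointScalingFit:
    """WLS/OLS solution of the joint scaling system."""

    model: EffectModel
    generations: list[str]
    weighting: str
    beta: np.ndarray              # effect estimates, model.terms order
    covariance: np.ndarray        # covariance of beta
    y: np.ndarray                 # observed generation means
    yhat: np.ndarray              # predicted generation means X @ beta
    chi2: float
    df: int
    p: float | None               # None when saturated (df == 0)

    @property
    def saturated(self) -> bool:
        return self.df == 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.model.labels, self.beta.tolist()))

    def standard_errors(self) -> dict[str, float]:
        return dict(zip(self.model.labels, self.se.tolist()))

    def to_dict(self) -> dict:
        return {
            "model": self.model.labels,
            "generations": self.generations,
            "weighting": self.weighting,
            "beta": self.coefficients(),
            "se": self.standard_errors(),
            "covariance": self.covariance.tolist(),
            "predicted_means": dict(zip(self.generations, self.yhat.tolist())),
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "saturated": self.saturated,
        }


@dataclass(frozen=True)
class GoodnessOfFit:
    chi2: float
    df: int
    p: float | None
    saturated: bool


def _confounded_columns(Xf: np.ndarray, labels: Sequence[str]) -> list[str]:
    """Names of effect columns involved in the null space of X."""
    _, s, vt = np.linalg.svd(Xf)
    null_mask = np.zeros(Xf.shape[1], dtype=bool)
    smax = s.max() if s.size else 0.0
    for i in range(Xf.shape[1]):
        if i >= s.size or (smax > 0 and s[i] / smax < RANK_TOL) or smax == 0:
            null_mask |= np.abs(vt[i]) > 1e-8
    return [lab for lab, bad in zip(labels, null_mask) if bad]


def fit_joint(gm: GenerationMeans,
              model: EffectModel = FULL_MODEL,
              weighting: str = "wls",
              generations: Sequence[str | GenerationSpec] | None = None,
              ) -> JointScalingFit:
    """Fit a joint scaling model to observed generation means.

    Parameters
    ----------
    gm
        Observed per-generation mean, variance and n.
    model
        Effect terms to estimate (mu always included).
    weighting
        ``"wls"`` weights each generation by the inverse squared standard
        error of its mean; ``"ols"`` weights equally (the covariance is
        still propagated from the supplied per-generation variances).
    generations
        Which generations to use; defaults to all present in ``gm``.
    """
    if weighting not in ("wls", "ols"):
        raise ValueError(f"weighting must be 'wls' or 'ols', got {weighting!r}")
    gens = [resolve_generation(g)
            for g in (generations if generations is not None
                      else gm.generations)]
    names = [g.name for g in gens]
    gm.require(names)
    if len(gens) < len(model):
        raise ValueError(
            f"{len(model)} effects cannot be estimated from "
            f"{len(gens)} generation means")

    Xf = np.array(build_design_matrix(gens, model), dtype=float)
    s = np.linalg.svd(Xf, compute_uv=False)
    if s.size < len(model) or s[-1] / s[0] < RANK_TOL:
        bad = _confounded_columns(Xf, model.labels)
        raise RankDeficientDesign(
            f"design matrix is rank-deficient for generations {names}: "
            f"effects {bad} are confounded")

    y = np.array([gm.mean(g) for g in names])
    se2 = np.array([gm.se2(g) for g in names])

    if weighting == "wls":
        if np.any(se2 <= 0):
            zero = [g for g, v in zip(names, se2) if v <= 0]
            raise ValueError(f"wls weighting needs positive SE^2 for every "
                             f"generation; zero for {zero} (use ols)")
        W = 1.0 / se2
        XtWX = Xf.T @ (W[:, None] * Xf)
        beta = np.linalg.solve(XtWX, Xf.T @ (W * y))
        cov = np.linalg.inv(XtWX)
    else:
        XtX = Xf.T @ Xf
        beta = np.linalg.solve(XtX, Xf.T @ y)
        XtX_inv = np.linalg.inv(XtX)
        # propagate the supplied per-generation variances through the OLS
        # projection (sandwich form)
        B = XtX_inv @ Xf.T
        cov = B @ np.diag(se2) @ B.T

    yhat = Xf @ beta
    df = len(gens) - len(model)
    if df == 0:
        chi2, p = 0.0, None
    else:
        resid = y - yhat
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(se2 > 0, resid ** 2 / se2, 0.0)
        chi2 = float(contrib.sum())
        p = float(stats.chi2.sf(chi2, df))
    return JointScalingFit(model, names, weighting, beta, cov, y, yhat,
                           chi2, df, p)


def goodness_of_fit(fit: JointScalingFit) -> GoodnessOfFit:
    """Chi-squared model adequacy of a joint scaling fit.

    A saturated model (df = 0) is reported explicitly rather than as a
    silent perfect fit.
    """
    return GoodnessOfFit(fit.chi2, fit.df, fit.p, fit.saturated)


def default_hierarchy() -> list[EffectModel]:
    """Additive -> +dominance -> +AA -> full pairwise model.

    AA is added before AD and DD because it is estimable from the widest
    range of generation designs.
    """
    return [EffectModel(["mu", "A"]),
            EffectModel(["mu", "A", "D"]),
            EffectModel(["mu", "A", "D", "AA"]),
            EffectModel(["mu", "A", "D", "AA", "AD", "DD"])]


@dataclass
class ModelSearchResult:
    """Outcome of sequential model building."""

    fits: list[tuple[EffectModel, JointScalingFit, bool]]
    selected: JointScalingFit
    alpha: float
    adequate: bool   # False when even the most complex model was rejected

    def path(self) -> list[dict]:
        return [{"model": m.labels, "chi2": f.chi2, "df": f.df, "p": f.p,
                 "saturated": f.saturated, "accepted": acc}
                for m, f, acc in self.fits]


def sequential_model_search(gm: GenerationMeans,
                            hierarchy: Sequence[EffectModel] | None = None,
                            alpha: float = 0.05,
                            weighting: str = "wls",
                            generations: Sequence[str] | None = None,
                            ) -> ModelSearchResult:
    """Fit increasingly complex nested models; stop at the first adequate one.

    A model is adequate when its goodness-of-fit p-value is >= ``alpha`` (a
    saturated model is accepted by construction).  If no model is adequate
    the most complex one is returned with ``adequate=False``.
    """
    if hierarchy is None:
        hierarchy = default_hierarchy()
    hierarchy = list(hierarchy)
    if not hierarchy:
        raise ValueError("model hierarchy is empty")
    for prev, nxt in zip(hierarchy, hierarchy[1:]):
        if not prev.is_nested_in(nxt):
            raise ValueError(f"hierarchy is not nested: {prev} is not a "
                             f"subset of {nxt}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    fits: list[tuple[EffectModel, JointScalingFit, bool]] = []
    selected: JointScalingFit | None = None
    for model in hierarchy:
        fit = fit_joint(gm, model, weighting=weighting,
                        generations=generations)
        accepted = fit.saturated or (fit.p is not None and fit.p >= alpha)
        fits.append((model, fit, accepted))
        if accepted:
            selected = fit
            break
    adequate = selected is not None
    if selected is None:
        selected = fits[-1][1]
    return ModelSearchResult(fits, selected, alpha, adequate)
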