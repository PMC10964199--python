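"""Multimodel line-cross inference engine.

Candidate genetic architectures are subsets of the composite-effect
vocabulary.  Each candidate is fitted to the cohort means by weighted
least squares with the squared standard errors of the means as known
variances, scored by small-sample-corrected AIC (AICc), and the candidates
in the 95% confidence set are combined by Akaike-weight model averaging.
A model that lacks an effect contributes an estimate of exactly zero for
it, so the averaged estimate shrinks toward zero in proportion to the
evidence against the effect.

Everything here is deterministic: candidate order, tie-breaking and the
confidence-set construction are fully specified so repeated runs are
bit-identical.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import CMatrix

__all__ = [
    "DatasetObservations",
    "ModelFit",
    "AveragedArchitecture",
    "enumerate_models",
    "collinearity_diagnostic",
    "drop_collinear",
    "fit_wls",
    "akaike_weights",
    "confidence_set",
    "model_average",
]

DEFAULT_MAX_PARAMS = 7
DEFAULT_COND_THRESHOLD = 1e8
Z_95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class DatasetObservations:
    """Observed cohort means and their error covariance.

    ``v`` holds the diagonal of the error covariance V (squared SEs of the
    cohort means).  When a study reports no uncertainty measures the whole
    dataset falls back to unweighted mode: V is the identity and a residual
    variance parameter is estimated (and counted against AICc).
    """

    y: np.ndarray
    v: np.ndarray
    weighted: bool = True

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.y.shape != self.v.shape or self.y.ndim != 1:
            raise ValueError("y and v must be 1-d arrays of equal length")
        if self.weighted and np.any(self.v <= 0):
            raise ValueError("all error variances must be > 0 in weighted mode")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class ModelFit:
    """One fitted candidate architecture."""

    effects: tuple[str, ...]
    beta: np.ndarray  # intercept first
    beta_cov: np.ndarray
    loglik: float
    aicc: float
    k: int  # parameters counted by AICc
    delta: float = math.nan
    weight: float = math.nan

    def estimate(self, effect: str) -> float:
        return float(self.beta[1 + self.effects.index(effect)])

    def variance(self, effect: str) -> float:
        i = 1 + self.effects.index(effect)
        return float(self.beta_cov[i, i])


def enumerate_models(
    effect_names: Sequence[str],
    n_cohorts: int,
    max_params: int = DEFAULT_MAX_PARAMS,
    include_intercept_only: bool = False,
) -> list[tuple[str, ...]]:
    """Enumerate candidate effect subsets.

    Model space is every non-empty subset of the vocabulary with at most
    ``min(n_cohorts - 1, max_params)`` composite effects (the intercept is
    in every model and does not count against the cap).  Order is by subset
    size, then lexicographic in vocabulary positions, so enumeration is
    deterministic.
    """
    if not effect_names:
        raise ValueError("effect vocabulary is empty")
    if n_cohorts < 3:
        raise ValueError(f"need at least 3 cohorts, got {n_cohorts}")
    cap = min(n_cohorts - 1, max_params)
    out: list[tuple[str, ...]] = []
    if include_intercept_only:
        out.append(())
    for size in range(1, min(cap, len(effect_names)) + 1):
        out.extend(itertools.combinations(effect_names, size))
    return out


def collinearity_diagnostic(
    cmatrix: CMatrix,
    subset: Sequence[str],
    v: np.ndarray | None = None,
) -> tuple[float, tuple[str, str] | None]:
    """Condition number of the (weighted) design submatrix.

    Returns ``(condition_number, worst_pair)`` where ``worst_pair`` names
    the most correlated column pair (the usual culprit when the screen
    fires), or ``None`` when fewer than two columns beyond the intercept.
    """
    x = cmatrix.columns(subset)
    if v is not None:
        x = x / np.sqrt(np.asarray(v, dtype=float))[:, None]
    s = np.linalg.svd(x, compute_uv=False)
    cond = math.inf if s[-1] == 0 else float(s[0] / s[-1])
    worst: tuple[str, str] | None = None
    if len(subset) >= 2:
        names = ["intercept", *subset]
        best_r = -1.0
        for i, j in itertools.combinations(range(x.shape[1]), 2):
            xi, xj = x[:, i], x[:, j]
            ni, nj = np.linalg.norm(xi), np.linalg.norm(xj)
            r = 1.0 if ni == 0 or nj == 0 else abs(float(xi @ xj)) / (ni * nj)
            if r > best_r:
                best_r, worst = r, (names[i], names[j])
    return cond, worst


def drop_collinear(
    cmatrix: CMatrix,
    subset: Sequence[str],
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
    v: np.ndarray | None = None,
) -> bool:
    """True when the candidate must be dropped for near-collinearity.

    Candidates whose C-matrix columns are highly correlated have no stable
    least-squares solution; they are removed from model space and inference
    proceeds with the remaining candidates.
    """
    x = cmatrix.columns(subset)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        return True
    cond, _ = collinearity_diagnostic(cmatrix, subset, v=v)
    return cond > cond_threshold


def fit_wls(
    obs: DatasetObservations,
    cmatrix: CMatrix,
    subset: Sequence[str],
) -> ModelFit | None:
    """Fit one candidate architecture by weighted least squares.

    Solves the weighted normal equations ``(X' V^-1 X) b = X' V^-1 y``.
    With reported SEs, V is treated as known: the Gaussian log-likelihood
    is evaluated at the fixed V and AICc counts ``k = p`` parameters
    (intercept included).  Without SEs, ordinary least squares is used, the
    residual variance is estimated by maximum likelihood and counted, so
    ``k = p + 1``.  Candidates with a non-positive AICc denominator
    ``n - k - 1`` are still solved but unscorable: their AICc is infinite
    and the multimodel ranking must exclude them.  A singular system (or
    more coefficients than cohorts) returns ``None``.
    """
    x = cmatrix.columns(subset)
    n, p = x.shape
    if p > n:
        return None
    v = obs.v if obs.weighted else np.ones(n)
    k = p if obs.weighted else p + 1
    xtvinv = x.T / v
    normal = xtvinv @ x
    try:
        beta = np.linalg.solve(normal, xtvinv @ obs.y)
        beta_cov = np.linalg.inv(normal)
    except np.linalg.LinAlgError:
        return None
    resid = obs.y - x @ beta
    if obs.weighted:
        loglik = -0.5 * float(np.sum(np.log(2 * math.pi * v) + resid**2 / v))
    else:
        sigma2 = float(resid @ resid) / n
        sigma2 = max(sigma2, 1e-300)
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        beta_cov = beta_cov * sigma2
    if n - k - 1 <= 0:
        aicc = math.inf
    else:
        aicc = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    return ModelFit(
        effects=tuple(subset),
        beta=beta,
        beta_cov=beta_cov,
        loglik=loglik,
        aicc=aicc,
        k=k,
    )


def akaike_weights(fits: list[ModelFit]) -> list[ModelFit]:
    """Attach AICc differences and Akaike weights (in place).

    ``w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)`` with
    ``delta_i = AICc_i - min AICc``; subtracting the minimum first keeps the
    exponentials in range.
    """
    if not fits:
        raise ValueError("no fitted models to weight")
    if any(not math.isfinite(f.aicc) for f in fits):
        raise ValueError("unscorable models (infinite AICc) must be excluded")
    best = min(f.aicc for f in fits)
    rel = np.array([math.exp(-(f.aicc - best) / 2.0) for f in fits])
    total = rel.sum()
    for f, r in zip(fits, rel):
        f.delta = f.aicc - best
        f.weight = float(r / total)
    return fits


def confidence_set(
    fits: list[ModelFit],
    level: float = 0.95,
    renormalize: bool = True,
) -> list[ModelFit]:
    """Smallest set of top-weighted models with cumulative weight >= level.

    Models are ranked by weight (descending); ties break toward fewer
    parameters, then lexicographically by effect names.  Within the set the
    weights are renormalized to sum to one (configurable), so averaging over
    the set is a proper weighted mean.
    """
    if not fits:
        raise ValueError("no fitted models")
    ranked = sorted(fits, key=lambda f: (-f.weight, len(f.effects), f.effects))
    chosen: list[ModelFit] = []
    cum = 0.0
    for f in ranked:
        chosen.append(f)
        cum += f.weight
        if cum >= level - 1e-12:
            break
    if renormalize:
        total = sum(f.weight for f in chosen)
        out = []
        for f in chosen:
            g = ModelFit(
                effects=f.effects,
                beta=f.beta,
                beta_cov=f.beta_cov,
                loglik=f.loglik,
                aicc=f.aicc,
                k=f.k,
                delta=f.delta,
                weight=f.weight / total,
            )
            out.append(g)
        return out
    return list(chosen)


@dataclass
class AveragedArchitecture:
    """Model-averaged composite-effect estimates for one dataset."""

    table: pd.DataFrame = field(repr=False)
    n_models: int = 0
    n_confidence: int = 0

    @property
    def effect_names(self) -> list[str]:
        return list(self.table.index)

    @property
    def significant_effects(self) -> dict[str, float]:
        sig = self.table[self.table["significant"]]
        return dict(zip(sig.index, sig["estimate"]))

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


def model_average(
    confset: list[ModelFit],
    effect_names: Sequence[str],
    ci_multiplier: float = Z_95,
    vi_threshold: float = 0.5,
    n_models: int | None = None,
) -> AveragedArchitecture:
    """Average estimates over a (renormalized) confidence set of models.

    For each effect, a model lacking it contributes an estimate of zero
    with zero conditional variance; the unconditional variance adds the
    between-model spread to the within-model variance:

        est   = sum_i w_i * b_i
        var   = sum_i w_i * (var_i + (b_i - est)^2)
        VI    = sum of w_i over models containing the effect

    An effect is declared significant when its variable importance reaches
    ``vi_threshold`` and its confidence interval excludes zero.
    """
    rows = []
    for name in effect_names:
        est = 0.0
        importance = 0.0
        contrib = []  # (weight, estimate, conditional variance)
        for f in confset:
            if name in f.effects:
                b, var = f.estimate(name), f.variance(name)
                importance += f.weight
            else:
                b, var = 0.0, 0.0
            est += f.weight * b
            contrib.append((f.weight, b, var))
        uncond_var = sum(w * (var + (b - est) ** 2) for w, b, var in contrib)
        se = math.sqrt(max(uncond_var, 0.0))
        lo, hi = est - ci_multiplier * se, est + ci_multiplier * se
        significant = importance >= vi_threshold and not (lo <= 0.0 <= hi)
        rows.append(
            {
                "estimate": est,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "importance": importance,
                "significant": significant,
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(effect_names, name="effect"))
    return AveragedArchitecture(
        table=table,
        n_models=n_models if n_models is not None else len(confset),
        n_confidence=len(confset),
    )
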