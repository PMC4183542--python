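"""Constant-rate birth-death probability machinery.

Everything downstream (shift search, placement tests, richness ratios) is built
on a small set of transition quantities of the reconstructed birth-death
process, parameterised by the net diversification rate ``r = lambda - mu``
(per Myr) and the turnover (relative extinction) ``eps = mu / lambda``:

* ``beta(t) = (e^{rt} - 1) / (e^{rt} - eps)`` -- the geometric parameter of
  the clade-size distribution for a lineage of age ``t``,
* ``alpha(t) = eps * beta(t)`` -- the probability the lineage leaves no
  extant descendant,
* ``P_s(t) = (1 - eps) / (1 - eps * e^{-rt})`` -- the survival probability.

The joint likelihood of a dated higher-taxon tree combines (i) the density of
the observed internal split times under the reconstructed process and (ii) the
probability of each terminal's extant species count given its stem age.  The
reconstructed process conditioned on survival is a time-inhomogeneous pure
birth process with per-lineage splitting rate ``lambda * P_s(t)``, which makes
the log-likelihood exactly additive over branches:

* each internal node at age ``t_v`` (the root excluded; the likelihood is
  conditioned on the crown age) contributes ``ln(lambda * P_s(t_v))``,
* each branch between internal nodes, from parent age ``a`` down to child age
  ``b``, contributes ``ln[(1 - beta(a)) / (1 - beta(b))]`` (no reconstructed
  split along the branch),
* each terminal with richness ``n`` and stem age ``t`` contributes the
  survival-conditioned geometric term ``ln(1 - beta(t)) + (n - 1) ln beta(t)``,
  which subsumes the terminal's pendant branch.

With ``eps = 0`` the whole expression collapses to the Yule log-likelihood
``(#splits) ln r - r * (total branch time)``, whose maximiser on the internal
part alone is the classic ``r_hat = (N - 2) / S``.  No combinatorial constant
is included; model comparisons only ever use differences of log-likelihoods,
which are invariant to any additive convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "BDParams",
    "BDTransients",
    "LikelihoodBreakdown",
    "transients",
    "richness_pmf",
    "richness_logpmf",
    "expected_richness",
    "richness_quantile",
    "internal_loglik",
    "terminal_loglik",
    "combined_loglik",
    "fit_params",
    "FitError",
]

R_MIN, R_MAX = 1e-8, 10.0
EPS_MAX = 0.999


class FitError(RuntimeError):
    """Raised when maximum-likelihood optimisation cannot produce a usable fit."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class BDParams:
    """A diversification regime: net rate ``r`` (per Myr) and turnover ``eps``.

    Speciation and extinction rates are derived: ``lam = r / (1 - eps)``,
    ``mu = lam * eps``.
    """

    r: float
    eps: float = 0.0

    def __post_init__(self):
        if not (self.r > 0):
            raise ValueError(f"net diversification rate must be > 0, got {self.r}")
        if not (0.0 <= self.eps < 1.0):
            raise ValueError(f"turnover must be in [0, 1), got {self.eps}")

    @property
    def lam(self) -> float:
        return self.r / (1.0 - self.eps)

    @property
    def mu(self) -> float:
        return self.lam * self.eps


@dataclass(frozen=True)
class BDTransients:
    """Transition quantities of the process at a fixed age ``t``."""

    beta: float
    alpha: float
    p_survival: float


def _log_beta_terms(t, r, eps):
    """Return (log beta, log(1-beta), log P_s), each stable for large r*t.

    Vectorised over ``t`` (array or scalar); t=0 maps to log beta = -inf.
    """
    t = np.asarray(t, dtype=float)
    rt = r * t
    # E = exp(-rt); beta = (1-E)/(1-eps E); 1-beta = (1-eps)E/(1-eps E)
    logE = -rt
    E = np.exp(logE)
    log1mEpsE = np.log1p(-eps * E)
    with np.errstate(divide="ignore"):
        log_beta = np.where(rt > 1e-8, np.log(-np.expm1(logE)), np.log(np.maximum(rt, 0.0))) - log1mEpsE
    log_1mbeta = math.log1p(-eps) + logE - log1mEpsE
    log_ps = math.log1p(-eps) - log1mEpsE
    return log_beta, log_1mbeta, log_ps


def transients(t: float, params: BDParams) -> BDTransients:
    """Evaluate beta, alpha and the survival probability at age ``t`` (Myr)."""
    if t < 0:
        raise ValueError(f"age must be >= 0, got {t}")
    if t == 0:
        return BDTransients(beta=0.0, alpha=0.0, p_survival=1.0)
    log_beta, _, log_ps = _log_beta_terms(t, params.r, params.eps)
    beta = float(np.exp(log_beta))
    return BDTransients(beta=beta, alpha=params.eps * beta, p_survival=float(np.exp(log_ps)))


def richness_logpmf(n, t: float, params: BDParams, conditioned: bool = True):
    """Log-probability of observing ``n`` extant species in a clade of stem age ``t``.

    Conditioned on survival the distribution is geometric on {1, 2, ...} with
    parameter beta(t); unconditioned it has an atom alpha(t) at zero.
    Vectorised over ``n``.
    """
    n = np.asarray(n)
    if t <= 0:
        raise ValueError(f"stem age must be > 0, got {t}")
    if np.any(n < (1 if conditioned else 0)):
        raise ValueError("count below the support of the distribution")
    log_beta, log_1mbeta, _ = _log_beta_terms(t, params.r, params.eps)
    out = log_1mbeta + (n - 1) * log_beta
    if not conditioned:
        beta = np.exp(log_beta)
        alpha = params.eps * beta
        out = np.where(n == 0, np.log(alpha) if alpha > 0 else -np.inf, out + np.log1p(-alpha))
    return out if out.ndim else float(out)


def richness_pmf(n, t: float, params: BDParams, conditioned: bool = True):
    """Probability of ``n`` extant species in a clade of stem age ``t``."""
    return np.exp(richness_logpmf(n, t, params, conditioned=conditioned))


def expected_richness(t: float, params: BDParams, conditioned: bool = True) -> float:
    """Expected clade size at stem age ``t``: ``e^{rt}`` (divided by ``1 - alpha``
    when conditioning on survival)."""
    if t < 0:
        raise ValueError(f"age must be >= 0, got {t}")
    mean = math.exp(params.r * t)
    if conditioned and t > 0:
        tr = transients(t, params)
        mean /= 1.0 - tr.alpha
    return mean


def richness_quantile(q: float, t: float, params: BDParams) -> int:
    """Smallest ``n >= 1`` with ``P(N <= n) >= q`` under the survival-conditioned
    clade-size distribution (closed form: ``P(N <= n) = 1 - beta^n``)."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile level must be in (0, 1), got {q}")
    if t <= 0:
        return 1
    log_beta, log_1mbeta, _ = _log_beta_terms(t, params.r, params.eps)
    if log_beta == -np.inf:
        return 1
    if log_beta >= 0.0:
        # beta so close to 1 that log(beta) underflows; use log(beta) ~ -(1-beta)
        log_beta = -math.exp(log_1mbeta)
    n = math.ceil(math.log1p(-q) / log_beta)
    return max(1, int(n))


def internal_loglik(split_ages, branch_spans, params: BDParams) -> float:
    """Log-density of internal split times under the reconstructed process.

    Parameters
    ----------
    split_ages : array of ages (Myr) of the internal nodes in the regime,
        excluding the tree root (crown conditioning).
    branch_spans : (k, 2) array of (parent_age, child_age) for branches whose
        child end is an internal node (terminal stem branches are covered by
        the terminal likelihood instead).
    params : regime parameters.

    Additive over branches, so regimes partition cleanly; an empty regime
    contributes exactly 0.
    """
    split_ages = np.asarray(split_ages, dtype=float)
    branch_spans = np.asarray(branch_spans, dtype=float).reshape(-1, 2)
    r, eps = params.r, params.eps
    total = 0.0
    if split_ages.size:
        _, _, log_ps = _log_beta_terms(split_ages, r, eps)
        total += split_ages.size * math.log(params.lam) + float(np.sum(log_ps))
    if branch_spans.size:
        _, log_1mb_par, _ = _log_beta_terms(branch_spans[:, 0], r, eps)
        _, log_1mb_chi, _ = _log_beta_terms(branch_spans[:, 1], r, eps)
        total += float(np.sum(log_1mb_par - log_1mb_chi))
    return total


def terminal_loglik(richness, stem_ages, params: BDParams) -> float:
    """Sum of survival-conditioned log-pmf terms over terminals."""
    richness = np.asarray(richness, dtype=float)
    stem_ages = np.asarray(stem_ages, dtype=float)
    if richness.size == 0:
        return 0.0
    log_beta, log_1mbeta, _ = _log_beta_terms(stem_ages, params.r, params.eps)
    return float(np.sum(log_1mbeta + (richness - 1.0) * log_beta))


@dataclass(frozen=True)
class LikelihoodBreakdown:
    """Combined log-likelihood split into its two components."""

    lnL_internal: float
    lnL_terminal: float

    @property
    def lnL_total(self) -> float:
        return self.lnL_internal + self.lnL_terminal


@dataclass(frozen=True)
class RegimeData:
    """Sufficient data of one regime for likelihood evaluation.

    Arrays: ages of internal splits (root excluded), internal branch spans
    (parent_age, child_age), terminal richness counts and their stem ages.
    """

    split_ages: np.ndarray
    branch_spans: np.ndarray
    richness: np.ndarray
    stem_ages: np.ndarray

    @property
    def n_terminals(self) -> int:
        return int(self.richness.size)

    @property
    def is_empty(self) -> bool:
        return self.split_ages.size == 0 and self.branch_spans.size == 0 and self.richness.size == 0

    def loglik(self, params: BDParams) -> LikelihoodBreakdown:
        return LikelihoodBreakdown(
            lnL_internal=internal_loglik(self.split_ages, self.branch_spans, params),
            lnL_terminal=terminal_loglik(self.richness, self.stem_ages, params),
        )

    def loglik_grad(self, r: float, eps: float):
        """(lnL, d lnL/d r, d lnL/d eps) in one vectorised pass.

        Uses the identities lambda*P_s(t) = r / D(t) with D(t) = 1 - eps e^{-rt},
        ln(1-beta) = ln(1-eps) - rt - ln D, ln beta = ln(1-e^{-rt}) - ln D.
        """
        lnL = dr = de = 0.0

        def _D_terms(t):
            E = np.exp(-r * t)
            D = -np.expm1(np.log(eps) - r * t) if eps > 0 else np.ones_like(E)
            # D = 1 - eps*E computed stably; for eps==0 it is exactly 1
            dlnD_dr = eps * t * E / D
            dlnD_de = -E / D
            return E, D, dlnD_dr, dlnD_de

        if self.split_ages.size:
            t = self.split_ages
            _, D, dlnD_dr, dlnD_de = _D_terms(t)
            lnL += t.size * math.log(r) - float(np.sum(np.log(D)))
            dr += t.size / r - float(np.sum(dlnD_dr))
            de += -float(np.sum(dlnD_de))
        if self.branch_spans.size:
            for sign, t in ((+1.0, self.branch_spans[:, 0]), (-1.0, self.branch_spans[:, 1])):
                _, D, dlnD_dr, dlnD_de = _D_terms(t)
                # sign * ln(1-beta(t)) = sign * [ln(1-eps) - r t - ln D]
                lnL += sign * (t.size * math.log1p(-eps) - r * float(np.sum(t)) - float(np.sum(np.log(D))))
                dr += sign * (-float(np.sum(t)) - float(np.sum(dlnD_dr)))
                de += sign * (-t.size / (1.0 - eps) - float(np.sum(dlnD_de)))
        if self.richness.size:
            t = self.stem_ages
            n1 = self.richness - 1.0
            E, D, dlnD_dr, dlnD_de = _D_terms(t)
            one_mE = -np.expm1(-r * t)
            lnL += (t.size * math.log1p(-eps) - r * float(np.sum(t)) - float(np.sum(np.log(D)))
                    + float(np.sum(n1 * (np.log(one_mE) - np.log(D)))))
            dr += (-float(np.sum(t)) - float(np.sum(dlnD_dr))
                   + float(np.sum(n1 * (t * E / one_mE - dlnD_dr))))
            de += (-t.size / (1.0 - eps) - float(np.sum(dlnD_de))
                   - float(np.sum(n1 * dlnD_de)))
        return lnL, dr, de


def combined_loglik(regime_data, regime_params) -> LikelihoodBreakdown:
    """Total log-likelihood over a partition of the tree into regimes.

    ``regime_data`` and ``regime_params`` are parallel sequences of
    :class:`RegimeData` and :class:`BDParams` (or single instances).
    """
    if isinstance(regime_data, RegimeData):
        regime_data = [regime_data]
        regime_params = [regime_params]
    if len(regime_data) != len(regime_params):
        raise ValueError("one parameter set per regime required")
    lin = lter = 0.0
    for data, params in zip(regime_data, regime_params):
        part = data.loglik(params)
        lin += part.lnL_internal
        lter += part.lnL_terminal
    return LikelihoodBreakdown(lnL_internal=lin, lnL_terminal=lter)


# -- maximum likelihood fitting ------------------------------------------------

def _init_rate(data: RegimeData) -> float:
    """Crude moment initialisation for r on one regime."""
    total_n = float(np.sum(data.richness)) if data.richness.size else 0.0
    ages = []
    if data.split_ages.size:
        ages.append(float(np.max(data.split_ages)))
    if data.stem_ages.size:
        ages.append(float(np.max(data.stem_ages)))
    if data.branch_spans.size:
        ages.append(float(np.max(data.branch_spans)))
    t_max = max(ages) if ages else 1.0
    if total_n >= 2 and t_max > 0:
        r0 = math.log(total_n) / t_max
    else:
        splits = data.split_ages.size
        span = float(np.sum(data.branch_spans[:, 0] - data.branch_spans[:, 1])) if data.branch_spans.size else 0.0
        span += float(np.sum(data.stem_ages))
        r0 = splits / span if splits and span > 0 else 0.05
    return min(max(r0, 10 * R_MIN), R_MAX / 10)


# deterministic multi-start grid in (r multiplier, eps) space
_STARTS = [(1.0, 0.05), (1.0, 0.5), (1.0, 0.9), (4.0, 0.3), (0.25, 0.3)]


def _has_information(data: RegimeData) -> bool:
    """A regime is informative if it has any split or any terminal with n > 1,
    or more than one terminal (ages then inform r)."""
    if data.split_ages.size:
        return True
    if data.richness.size and np.any(data.richness > 1):
        return True
    return data.richness.size > 1


def fit_params(
    data: RegimeData,
    fixed_eps: float | None = None,
    init: BDParams | None = None,
    quick: bool = False,
) -> tuple[BDParams, LikelihoodBreakdown]:
    """Maximum-likelihood (r, eps) for one regime by bounded optimisation.

    Works in transformed coordinates (log r, logit eps) with deterministic
    multi-starts; with ``fixed_eps`` only r is free (Brent on log r).  With
    ``quick=True`` only the warm start (``init``) plus one default start are
    used — the mode candidate scans rely on; accepted models are re-polished
    with the full start set.  Raises :class:`FitError` for regimes carrying no
    information (e.g. a single terminal with n = 1).
    """
    if data.is_empty or not _has_information(data):
        raise FitError("regime carries no information to estimate rates from")

    if fixed_eps is not None:
        if not (0.0 <= fixed_eps < 1.0):
            raise ValueError(f"fixed turnover must be in [0, 1), got {fixed_eps}")

        def neg_r(logr):
            return -data.loglik(BDParams(r=math.exp(logr), eps=fixed_eps)).lnL_total

        res = minimize_scalar(
            neg_r, bounds=(math.log(R_MIN), math.log(R_MAX)), method="bounded",
            options={"xatol": 1e-12},
        )
        params = BDParams(r=math.exp(res.x), eps=fixed_eps)
        return params, data.loglik(params)

    def unpack(theta):
        r = math.exp(min(max(theta[0], math.log(R_MIN)), math.log(R_MAX)))
        eps = EPS_MAX / (1.0 + math.exp(-theta[1]))
        return BDParams(r=r, eps=eps)

    def neg_with_grad(theta):
        p = unpack(theta)
        lnL, dr, de = data.loglik_grad(p.r, p.eps)
        if not np.isfinite(lnL):
            return np.inf, np.zeros(2)
        # chain rule through theta1 = log r, theta2 = logit(eps / EPS_MAX)
        g1 = dr * p.r
        g2 = de * p.eps * (1.0 - p.eps / EPS_MAX)
        return -lnL, np.array([-g1, -g2])

    def neg(theta):
        try:
            return -data.loglik(unpack(theta)).lnL_total
        except (OverflowError, FloatingPointError):
            return np.inf

    r0 = _init_rate(data)
    starts = [(math.log(r0 * m), math.log(e / (EPS_MAX - e))) for m, e in _STARTS]
    if init is not None:
        e = min(max(init.eps, 1e-6), EPS_MAX - 1e-6)
        starts.insert(0, (math.log(init.r), math.log(e / (EPS_MAX - e))))
    best = None
    if quick:
        # candidate-scan budget: gradient-based fits from the warm start and
        # one heuristic start; accepted models are re-polished afterwards
        for theta0 in starts[:2]:
            res = minimize(neg_with_grad, theta0, jac=True, method="L-BFGS-B",
                           options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 200})
            if best is None or res.fun < best.fun:
                best = res
    else:
        for theta0 in starts:
            res = minimize(neg_with_grad, theta0, jac=True, method="L-BFGS-B",
                           options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        # derivative-free polish from the gradient optimum guards against any
        # rough edge of the transformed surface
        res = minimize(neg, best.x, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000})
        if res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("optimisation failed to converge from any start", best=best)
    params = unpack(best.x)
    return params, data.loglik(params)
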