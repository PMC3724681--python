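"""Random-effects pooling, profile-likelihood inference and conclusion
classification.

The standard random-effects pooled estimate weights each study by
``1/(sigma2_i + tau2)`` and builds a normal-theory Wald interval around it,
treating the tau^2 plug-in as known.  The profile-likelihood method instead
inverts the likelihood-ratio statistic, re-maximising tau^2 at every fixed
value of the pooled effect, so the interval reflects the uncertainty in the
heterogeneity estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .tau2 import Tau2Result, tau2_likelihood

NS = "NS"
SIG = "Sig"
NO_CONV = "NoConv"
NO_COMP = "NoComp"


@dataclass
class PooledResult:
    """A pooled effect with its interval and statistical conclusion."""

    mu_hat: float
    se: float
    ci_low: float
    ci_high: float
    model: str                 # FE | RE
    tau2_method: str = ""
    tau2: float = 0.0
    conclusion: str = NS
    alpha: float = 0.05
    converged: bool = True


def _wald(mu: float, se: float, alpha: float) -> tuple[float, float]:
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return mu - z * se, mu + z * se


def classify_conclusion(result: PooledResult, null_value: float = 0.0) -> str:
    """Sig / NS at the result's alpha; NoConv and NoComp pass through."""
    if result.conclusion in (NO_CONV, NO_COMP):
        return result.conclusion
    z = stats.norm.ppf(1.0 - result.alpha / 2.0)
    return SIG if abs(result.mu_hat - null_value) / result.se >= z else NS


def pool_random(theta, sigma2, tau2: float, alpha: float = 0.05,
                tau2_method: str = "", model: Optional[str] = None,
                null_value: float = 0.0) -> PooledResult:
    """Random-effects pooling with weights ``1/(sigma2_i + tau2)``.

    With ``tau2 = 0`` this reproduces the inverse-variance fixed-effect
    numbers exactly.  The confidence interval is the normal-quantile Wald
    interval at the requested two-sided ``alpha``.
    """
    theta = np.asarray(theta, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    w = 1.0 / (sigma2 + tau2)
    mu = float(np.sum(w * theta) / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    lo, hi = _wald(mu, se, alpha)
    if model is None:
        model = "FE" if tau2 == 0 and not tau2_method else "RE"
    res = PooledResult(mu, se, lo, hi, model, tau2_method, tau2, alpha=alpha)
    res.conclusion = classify_conclusion(res, null_value)
    return res


def _loglik(mu: float, tau2: float, theta: np.ndarray, sigma2: np.ndarray) -> float:
    v = sigma2 + tau2
    return float(-0.5 * np.sum(np.log(v) + (theta - mu) ** 2 / v))


def _profile_tau2(mu: float, theta: np.ndarray, sigma2: np.ndarray) -> float:
    """Maximise the log-likelihood over tau2 >= 0 at fixed mu."""
    # fixed-point iteration on the tau2 score at fixed mu, truncated at 0
    tau2 = max(0.0, float(np.var(theta) - sigma2.mean()))
    for _ in range(200):
        w = 1.0 / (sigma2 + tau2)
        new = max(0.0, float(np.sum(w * w * ((theta - mu) ** 2 - sigma2)) / np.sum(w * w)))
        if abs(new - tau2) <= 1e-12:
            tau2 = new
            break
        tau2 = new
    return tau2


def pl_estimate(theta, sigma2, alpha: float = 0.05, tol: float = 1e-8,
                max_evals: int = 200, null_value: float = 0.0) -> PooledResult:
    """Profile-likelihood point estimate and confidence interval.

    The point estimate is the joint ML maximiser (mu, tau2).  Each CI bound
    is a root of ``2 [l_p(mu_hat) - l_p(mu)] = chi2_1(1 - alpha)`` where
    ``l_p`` profiles tau2 (re-maximised, truncated at zero) at each fixed
    mu.  Roots are bracketed by stepping outward from the Wald interval;
    failure to bracket or converge yields a ``NoConv`` result.
    """
    theta = np.asarray(theta, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    ml = tau2_likelihood(theta, sigma2, "ML")
    w = 1.0 / (sigma2 + ml.tau2)
    mu_hat = float(np.sum(w * theta) / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    crit = stats.chi2.ppf(1.0 - alpha, 1)
    l_max = _loglik(mu_hat, ml.tau2, theta, sigma2)

    def g(mu: float) -> float:
        return 2.0 * (l_max - _loglik(mu, _profile_tau2(mu, theta, sigma2), theta, sigma2)) - crit

    def find_bound(direction: int) -> Optional[float]:
        # step outward from the Wald bound until g changes sign, then brentq
        step = max(se, 1e-6)
        inner = mu_hat
        outer = mu_hat + direction * stats.norm.ppf(1 - alpha / 2) * step
        evals = 0
        while g(outer) < 0:
            inner = outer
            outer = outer + direction * step
            step *= 1.6
            evals += 1
            if evals > max_evals:
                return None
        try:
            return float(optimize.brentq(g, min(inner, outer), max(inner, outer),
                                         xtol=tol, maxiter=max_evals))
        except (ValueError, RuntimeError):
            return None

    lo = find_bound(-1)
    hi = find_bound(+1)
    if lo is None or hi is None or not ml.converged:
        res = PooledResult(mu_hat, se, float("nan"), float("nan"), "RE", "PL",
                           ml.tau2, conclusion=NO_CONV, alpha=alpha, converged=False)
        return res
    res = PooledResult(mu_hat, se, lo, hi, "RE", "PL", ml.tau2, alpha=alpha)
    # PL significance is read off the interval itself
    res.conclusion = SIG if (null_value < lo or null_value > hi) else NS
    return res


def pool_with_tau2(theta, sigma2, tau2_result: Tau2Result, alpha: float = 0.05,
                   null_value: float = 0.0) -> PooledResult:
    """Pool under a tau^2 estimate, propagating failure/non-convergence."""
    if tau2_result.failed:
        return PooledResult(float("nan"), float("nan"), float("nan"), float("nan"),
                            "RE", tau2_result.method, float("nan"),
                            conclusion=NO_COMP, alpha=alpha, converged=False)
    res = pool_random(theta, sigma2, tau2_result.tau2, alpha,
                      tau2_method=tau2_result.method, model="RE",
                      null_value=null_value)
    if not tau2_result.converged:
        res.conclusion = NO_CONV
        res.converged = False
    return res
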