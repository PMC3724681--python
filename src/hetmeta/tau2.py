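"""Between-study variance (tau^2) estimators.

Implements the full family of heterogeneity-variance estimators compared in
the sensitivity analyses this package supports, grouped by their a-priori
stance on heterogeneity:

* zero-or-positive: DL, DL2, DLb, VC, VC2, ML, REML, B0 — these can return
  exactly zero (negative moment/likelihood solutions are truncated);
* positive-only: DLi, MVa, MVb, BP — these assume strictly positive
  heterogeneity (DLi floors the DL estimate at 0.01; the model-error-variance
  and positive Bayes estimators are positive by construction).

All functions take plain arrays of per-study effects ``theta`` and known
within-study variances ``sigma2``; use :func:`hetmeta.effects.as_arrays`
to obtain them from :class:`~hetmeta.effects.EffectEstimate` lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

ZERO_OR_POSITIVE = ("DL", "DL2", "DLb", "VC", "VC2", "ML", "REML", "B0")
POSITIVE_ONLY = ("DLi", "MVa", "MVb", "BP")
METHODS = ZERO_OR_POSITIVE + POSITIVE_ONLY

#: Floor used by the positive-only variants (DLi, and the MVb ratio
#: denominator when the VC estimate is zero).
POSITIVE_FLOOR = 0.01


class InsufficientStudiesError(ValueError):
    """tau^2 estimation needs at least two studies."""


@dataclass
class Tau2Result:
    """A tau^2 estimate together with how it was obtained."""

    tau2: float
    method: str
    truncated: bool = False       # pre-truncation value was negative
    converged: bool = True        # meaningful for ML/REML only
    iterations: int = 0
    bootstrap_reps: int = 0       # DLb only
    failed: bool = False          # estimator not computable (e.g. MVa, equal effects)
    reason: str = ""

    @property
    def group(self) -> str:
        return "positive-only" if self.method in POSITIVE_ONLY else "zero-or-positive"


def _check(theta: np.ndarray, sigma2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if theta.size < 2:
        raise InsufficientStudiesError("need at least 2 studies")
    if np.any(sigma2 <= 0):
        raise ValueError("within-study variances must be positive")
    return theta, sigma2


def _dk_moment(theta: np.ndarray, sigma2: np.ndarray, a: np.ndarray) -> float:
    """Generalised method-of-moments tau^2 for arbitrary weights ``a``.

    With ``a = 1/sigma2`` this is the classical DerSimonian-Laird moment
    equation; with ``a = 1`` the Hedges variance-component estimator; with
    random-effects weights from a first pass, the two-step refinements.
    Returns the *untruncated* solution.
    """
    sa = a.sum()
    ybar = float(np.sum(a * theta) / sa)
    num = float(np.sum(a * (theta - ybar) ** 2)) - (
        float(np.sum(a * sigma2)) - float(np.sum(a * a * sigma2) / sa)
    )
    den = sa - float(np.sum(a * a) / sa)
    return num / den


def tau2_dl(theta, sigma2, theta_f: Optional[float] = None) -> Tau2Result:
    """DerSimonian-Laird moment estimator.

    ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` with
    ``w = 1/sigma2`` and Q centred at ``theta_f`` (the IV fixed-effect
    estimate by default; pass the MH or Peto fixed estimate to make the
    estimator follow that pooling approach).
    """
    theta, sigma2 = _check(theta, sigma2)
    k = theta.size
    w = 1.0 / sigma2
    sw = w.sum()
    if theta_f is None:
        theta_f = float(np.sum(w * theta) / sw)
    q = float(np.sum(w * (theta - theta_f) ** 2))
    raw = (q - (k - 1)) / (sw - float(np.sum(w * w)) / sw)
    return Tau2Result(max(0.0, raw), "DL", truncated=raw < 0)


def tau2_vc(theta, sigma2) -> Tau2Result:
    """Hedges variance-component estimator.

    Partitions the total variance of the effects around their unweighted
    mean: ``tau2 = max(0, sum(theta - mean)^2/(k-1) - mean(sigma2))``.
    """
    theta, sigma2 = _check(theta, sigma2)
    k = theta.size
    raw = float(np.sum((theta - theta.mean()) ** 2) / (k - 1) - sigma2.mean())
    return Tau2Result(max(0.0, raw), "VC", truncated=raw < 0)


def tau2_two_step(theta, sigma2, variant: str = "DL2") -> Tau2Result:
    """Two-step DerSimonian-Kacker refinements DL2 and VC2.

    Step 1 computes the truncated DL (or VC) estimate; step 2 re-solves the
    generalised moment equation with random-effects weights
    ``a_i = 1/(sigma2_i + tau2_step1)``, centring at the step-1
    random-effects estimate.  Exactly one refinement step is taken.
    """
    theta, sigma2 = _check(theta, sigma2)
    if variant == "DL2":
        step1 = tau2_dl(theta, sigma2).tau2
    elif variant == "VC2":
        step1 = tau2_vc(theta, sigma2).tau2
    else:
        raise ValueError(f"unknown two-step variant {variant!r}")
    a = 1.0 / (sigma2 + step1)
    raw = _dk_moment(theta, sigma2, a)
    return Tau2Result(max(0.0, raw), variant, truncated=raw < 0)


def tau2_moment(theta, sigma2, variant: str = "DL") -> Tau2Result:
    """Moment estimators DL, DL2, VC, VC2 behind one dispatcher."""
    if variant == "DL":
        return tau2_dl(theta, sigma2)
    if variant == "VC":
        return tau2_vc(theta, sigma2)
    return tau2_two_step(theta, sigma2, variant)


def tau2_likelihood(theta, sigma2, variant: str = "ML", tol: float = 1e-10,
                    max_iter: int = 100) -> Tau2Result:
    """ML and REML estimators by truncated fixed-point iteration.

    With ``w_i = 1/(sigma2_i + tau2)`` and ``mu = sum(w theta)/sum(w)``
    recomputed every iteration, the updates are::

        ML:   tau2 <- max(0, sum(w^2 [(theta-mu)^2 - sigma2]) / sum(w^2))
        REML: tau2 <- max(0, sum(w^2 [(theta-mu)^2 - sigma2]) / sum(w^2) + 1/sum(w))

    Iteration starts from the truncated VC estimate; truncation at every
    step keeps the iterate non-negative.  Non-convergence after
    ``max_iter`` steps is reported, not raised, so simulation harnesses can
    count it.
    """
    theta, sigma2 = _check(theta, sigma2)
    if variant not in ("ML", "REML"):
        raise ValueError(f"unknown likelihood variant {variant!r}")
    tau2 = tau2_vc(theta, sigma2).tau2
    it = 0
    delta = math.inf
    for it in range(1, max_iter + 1):
        w = 1.0 / (sigma2 + tau2)
        mu = float(np.sum(w * theta) / w.sum())
        new = float(np.sum(w * w * ((theta - mu) ** 2 - sigma2)) / np.sum(w * w))
        if variant == "REML":
            new += 1.0 / float(w.sum())
        new = max(0.0, new)
        delta = abs(new - tau2)
        tau2 = new
        if delta <= tol:
            break
    return Tau2Result(tau2, variant, converged=delta <= tol, iterations=it)


def tau2_dlb(theta, sigma2, reps: int = 10_000,
             rng: Union[int, np.random.Generator, None] = None) -> Tau2Result:
    """Non-parametric bootstrap DL estimator (DLb).

    Resamples the k (theta_i, sigma2_i) pairs with replacement ``reps``
    times, computes the truncated DL estimate on each resample and returns
    the mean.  A resample made of a single distinct study has Q = 0 and
    contributes 0, so DLb is zero only when *every* resample looks
    homogeneous — the source of its higher heterogeneity-detection rate.
    """
    theta, sigma2 = _check(theta, sigma2)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    k = theta.size
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    idx = gen.integers(0, k, size=(reps, k))
    t = theta[idx]
    w = 1.0 / sigma2[idx]
    sw = w.sum(axis=1)
    ybar = (w * t).sum(axis=1) / sw
    q = (w * (t - ybar[:, None]) ** 2).sum(axis=1)
    den = sw - (w * w).sum(axis=1) / sw
    est = np.maximum(0.0, (q - (k - 1)) / den)
    return Tau2Result(float(est.mean()), "DLb", bootstrap_reps=reps)


def tau2_dli(theta, sigma2) -> Tau2Result:
    """DL with a positivity floor: the DL estimate if positive, else 0.01."""
    dl = tau2_dl(theta, sigma2)
    if dl.tau2 > 0:
        return Tau2Result(dl.tau2, "DLi")
    return Tau2Result(POSITIVE_FLOOR, "DLi", truncated=dl.truncated)


def tau2_mv(theta, sigma2, variant: str = "MVa") -> Tau2Result:
    """Sidik-Jonkman model-error-variance estimators MVa and MVb.

    Reparameterises study variability through the within- to between-study
    variance ratios ``r_i = sigma2_i / tau2_prior``.  MVa uses the crude
    prior ``tau2_prior = mean((theta - mean(theta))^2)``; MVb uses the VC
    estimate (plus 0.01 when VC = 0, so the ratios stay finite).  With
    weights ``v_i = 1/(r_i + 1)`` and their weighted mean ``mu_v``::

        tau2 = sum(v_i (theta_i - mu_v)^2) / (k - 1)

    which is positive whenever the effects are not all equal.  MVa cannot
    produce an estimate when all effects are equal (the prior is zero); that
    case is flagged ``failed`` rather than raised.
    """
    theta, sigma2 = _check(theta, sigma2)
    k = theta.size
    if variant == "MVa":
        prior = float(np.sum((theta - theta.mean()) ** 2) / k)
        if prior == 0.0:
            return Tau2Result(float("nan"), "MVa", failed=True,
                              reason="all effects equal: crude prior variance is zero")
    elif variant == "MVb":
        vc = tau2_vc(theta, sigma2).tau2
        prior = vc if vc > 0 else vc + POSITIVE_FLOOR
    else:
        raise ValueError(f"unknown MV variant {variant!r}")
    r = sigma2 / prior
    v = 1.0 / (r + 1.0)
    mu_v = float(np.sum(v * theta) / v.sum())
    tau2 = float(np.sum(v * (theta - mu_v) ** 2) / (k - 1))
    return Tau2Result(tau2, variant)


def tau2_rukhin(theta, sigma2, n_totals: Optional[Sequence[float]] = None,
                variant: str = "BP") -> Tau2Result:
    """Rukhin Bayes-type estimators B0 and BP.

    With ``S2 = sum((theta - mean(theta))^2)`` and study sizes ``n_i``
    (``N = sum n_i``), the zero-prior Bayes estimator is::

        B0 = max(0, S2/(k+1) - (k-1)/(k+1) * sum((n_i - 1) sigma2_i) / (N - k))

    i.e. the sample spread shrunk by a size-weighted pooled within-study
    variance; negative values are truncated.  Dropping the correction term
    gives the always-positive variant ``BP = S2/(k+1)``, which needs no
    study sizes and no truncation.
    """
    theta, sigma2 = _check(theta, sigma2)
    k = theta.size
    s2 = float(np.sum((theta - theta.mean()) ** 2))
    if variant == "BP":
        return Tau2Result(s2 / (k + 1), "BP")
    if variant != "B0":
        raise ValueError(f"unknown Rukhin variant {variant!r}")
    if n_totals is None:
        raise ValueError("B0 requires per-study subject counts n_totals")
    n = np.asarray(n_totals, dtype=float)
    if n.size != k or np.any(np.isnan(n)):
        raise ValueError("B0 requires a subject count for every study")
    big_n = n.sum()
    pooled_within = float(np.sum((n - 1.0) * sigma2) / (big_n - k))
    raw = s2 / (k + 1) - (k - 1) / (k + 1) * pooled_within
    return Tau2Result(max(0.0, raw), "B0", truncated=raw < 0)


def estimate_tau2(theta, sigma2, method: str, *, n_totals=None,
                  reps: int = 10_000, rng=None, theta_f: Optional[float] = None,
                  tol: float = 1e-10, max_iter: int = 100) -> Tau2Result:
    """Dispatch to any estimator by its label (see :data:`METHODS`)."""
    method = {m.lower(): m for m in METHODS}.get(method.lower(), method)
    if method == "DL":
        return tau2_dl(theta, sigma2, theta_f=theta_f)
    if method in ("DL2", "VC2"):
        return tau2_two_step(theta, sigma2, method)
    if method == "VC":
        return tau2_vc(theta, sigma2)
    if method in ("ML", "REML"):
        return tau2_likelihood(theta, sigma2, method, tol=tol, max_iter=max_iter)
    if method == "DLb":
        return tau2_dlb(theta, sigma2, reps=reps, rng=rng)
    if method == "DLi":
        return tau2_dli(theta, sigma2)
    if method in ("MVa", "MVb"):
        return tau2_mv(theta, sigma2, method)
    if method in ("B0", "BP"):
        return tau2_rukhin(theta, sigma2, n_totals=n_totals, variant=method)
    raise ValueError(f"unknown tau2 method {method!r}")
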