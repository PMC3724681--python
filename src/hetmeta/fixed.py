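"""Fixed-effect pooling (inverse-variance, Mantel-Haenszel, Peto) and
heterogeneity statistics.

Cochran's Q is computed with inverse-variance weights around *the
fixed-effect estimate of the chosen approach* — IV, Mantel-Haenszel or
Peto — so the moment-based between-study variance estimators downstream are
method-dependent by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .effects import EffectEstimate, StudyRecord, as_arrays, included


class EmptyMetaError(ValueError):
    """No non-excluded studies to pool."""


@dataclass
class FixedPooled:
    """A fixed-effect pooled estimate on the analysis scale."""

    mu_hat: float
    se: float
    method: str  # IV | MH | Peto
    measure: str
    k: int
    weights: Optional[np.ndarray] = None
    computable: bool = True
    reason: str = ""

    @property
    def variance(self) -> float:
        return self.se ** 2


@dataclass
class HeterogeneityStats:
    """Cochran's Q with its derived indices H^2 and I^2 (in percent)."""

    Q: float
    df: int
    H2: float
    I2: float


def pool_iv_fixed(effects: Sequence[EffectEstimate]) -> FixedPooled:
    """Inverse-variance fixed-effect pooling: weights 1/sigma_i^2."""
    kept = included(effects)
    if not kept:
        raise EmptyMetaError("no computable studies")
    theta, sigma2 = as_arrays(kept)
    w = 1.0 / sigma2
    mu = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return FixedPooled(mu, se, "IV", kept[0].measure, len(kept), w)


def _not_computable(method: str, measure: str, k: int, reason: str) -> FixedPooled:
    return FixedPooled(float("nan"), float("nan"), method, measure, k,
                       computable=False, reason=reason)


def pool_mh(records: Sequence[StudyRecord], measure: str) -> FixedPooled:
    """Mantel-Haenszel fixed-effect pooling of 2x2 tables.

    Pooled estimates use the classical MH weights; standard errors use the
    Robins-Breslow-Greenland variance for the odds ratio and the
    Greenland-Robins variances for the risk ratio and risk difference.
    MH estimates are computed from raw cell counts without continuity
    correction (the weighting itself handles sparse cells); studies that
    contribute no information to the chosen measure drop out of the sums.
    """
    tables = []
    for rec in records:
        a, b, c, d = rec.cells
        if measure in ("logOR", "logRR") and ((a == 0 and c == 0) or (b == 0 and d == 0)):
            continue  # double-zero / double-full: no ratio information
        tables.append((a, b, c, d))
    k = len(tables)
    if k == 0:
        return _not_computable("MH", measure, 0, "no computable studies")
    arr = np.array(tables, dtype=float)
    a, b, c, d = arr.T
    n1 = a + b
    n2 = c + d
    n = n1 + n2

    if measure == "logOR":
        r = a * d / n
        s = b * c / n
        R, S = r.sum(), s.sum()
        if R == 0 or S == 0:
            return _not_computable("MH", measure, k, "MH odds ratio undefined (zero margin sum)")
        mu = math.log(R / S)
        p = (a + d) / n
        q = (b + c) / n
        var = (np.sum(p * r) / (2 * R * R)
               + np.sum(p * s + q * r) / (2 * R * S)
               + np.sum(q * s) / (2 * S * S))
    elif measure == "logRR":
        R = np.sum(a * n2 / n)
        S = np.sum(c * n1 / n)
        if R == 0 or S == 0:
            return _not_computable("MH", measure, k, "MH risk ratio undefined (no events in an arm)")
        mu = math.log(R / S)
        var = float(np.sum((n1 * n2 * (a + c) - a * c * n) / n ** 2) / (R * S))
    elif measure == "RD":
        w = n1 * n2 / n
        W = w.sum()
        mu = float(np.sum(w * (a / n1 - c / n2)) / W)
        var = float(np.sum((a * b * n2 ** 3 + c * d * n1 ** 3) / (n1 * n2 * n ** 2)) / W ** 2)
    else:
        raise ValueError(f"unsupported MH measure {measure!r}")
    if var <= 0:
        return _not_computable("MH", measure, k, "non-positive MH variance")
    return FixedPooled(mu, math.sqrt(var), "MH", measure, k)


def pool_peto(records: Sequence[StudyRecord]) -> FixedPooled:
    """Peto fixed-effect pooled log odds ratio: sum(O-E)/sum(V), se = 1/sqrt(sum V)."""
    from .effects import DegenerateStudyError, peto_components

    o_minus_e, v = [], []
    for rec in records:
        try:
            oe_i, v_i = peto_components(rec)
        except DegenerateStudyError:
            continue
        o_minus_e.append(oe_i)
        v.append(v_i)
    k = len(v)
    total_v = sum(v)
    if k == 0 or total_v == 0:
        return _not_computable("Peto", "logPetoOR", k, "sum of Peto variances is zero")
    mu = sum(o_minus_e) / total_v
    return FixedPooled(mu, 1.0 / math.sqrt(total_v), "Peto", "logPetoOR", k)


def generalized_q(effects: Sequence[EffectEstimate],
                  theta_f: Optional[float] = None) -> HeterogeneityStats:
    """Cochran's Q around a fixed-effect estimate, with H^2 and I^2.

    ``Q = sum_i w_i (theta_i - theta_F)^2`` with inverse-variance weights
    ``w_i = 1/sigma_i^2``.  ``theta_f`` defaults to the IV fixed estimate;
    pass the MH or Peto estimate to centre Q at that approach's pooled
    effect instead.
    """
    theta, sigma2 = as_arrays(effects)
    k = theta.size
    if k < 2:
        raise EmptyMetaError("Q requires at least 2 studies")
    w = 1.0 / sigma2
    if theta_f is None:
        theta_f = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_f) ** 2))
    df = k - 1
    h2 = q / df
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityStats(q, df, h2, i2)
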