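"""Performance assessment of heterogeneity estimators over simulated
meta-analyses.

Four criteria are computed per (scenario, method) cell:

* mean bias and mean absolute bias of tau2_hat against the true tau2;
* the percentage of exactly-zero tau2 estimates (erroneous homogeneity);
* coverage — the share of 95% random-effects confidence intervals that
  contain the true overall effect;
* the error-interval ratio c — estimated CI width divided by the width of
  the interval computed at the true tau2, summarised by its median and
  quartiles (c = 1 is perfect interval calibration).

Replicates where an estimator fails or does not converge are excluded from
these denominators and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pooling import NO_COMP, NO_CONV, PooledResult, pl_estimate, pool_random
from .simulate import Scenario, simulate_meta
from .tau2 import METHODS, estimate_tau2

#: Methods assessed by default (all tau^2 estimators; add "PL" for
#: profile-likelihood interval assessment, which has no tau^2 of its own
#: beyond ML's).
DEFAULT_METHODS = list(METHODS)


@dataclass
class AssessmentSummary:
    """Criteria summaries for one estimator in one scenario cell."""

    distribution: str
    tau2_true: float
    k: int
    method: str
    n_reps: int
    mean_bias: float
    mean_abs_bias: float
    pct_zero: float
    coverage: float
    c_q25: float
    c_median: float
    c_q75: float
    n_nonconverged: int = 0
    n_failed: int = 0


def bias_summary(tau2_hats: Sequence[float], tau2_true: float) -> tuple[float, float]:
    """(mean bias, mean absolute bias) of the estimates against the truth."""
    arr = np.asarray(tau2_hats, dtype=float)
    if arr.size == 0:
        raise ValueError("no estimates to summarise")
    dev = arr - tau2_true
    return float(dev.mean()), float(np.abs(dev).mean())


def zero_rate(tau2_hats: Sequence[float]) -> float:
    """Percentage of estimates that are exactly zero (after truncation)."""
    arr = np.asarray(tau2_hats, dtype=float)
    if arr.size == 0:
        raise ValueError("no estimates to summarise")
    return 100.0 * float(np.mean(arr == 0.0))


def coverage(pooled_results: Iterable[PooledResult], mu_true: float = 0.5) -> float:
    """Percentage of CIs containing the true effect (converged results only)."""
    hits = total = 0
    for res in pooled_results:
        if res.conclusion in (NO_CONV, NO_COMP):
            continue
        total += 1
        hits += res.ci_low <= mu_true <= res.ci_high
    if total == 0:
        raise ValueError("no converged results")
    return 100.0 * hits / total


def c_ratio(pooled_at_tau2hat: PooledResult, pooled_at_tau2true: PooledResult) -> float:
    """Ratio of estimated to true-tau2 CI widths (both at the same alpha)."""
    w_hat = pooled_at_tau2hat.ci_high - pooled_at_tau2hat.ci_low
    w_true = pooled_at_tau2true.ci_high - pooled_at_tau2true.ci_low
    if not np.isfinite(w_true) or w_true <= 0:
        raise ValueError("true-tau2 interval has non-positive width")
    return w_hat / w_true


def assess_scenario(scenario: Scenario,
                    methods: Optional[Sequence[str]] = None,
                    dlb_reps: int = 10_000,
                    alpha: float = 0.05) -> list[AssessmentSummary]:
    """Run one simulation cell and summarise every method's performance.

    ``methods`` may include any tau^2 estimator label plus ``"PL"`` (the
    profile-likelihood interval, assessed on coverage and c only; its point
    tau^2 is the ML estimate).  DLb's bootstrap replicates are controlled by
    ``dlb_reps``.  Fully reproducible given ``scenario.seed``.
    """
    methods = list(DEFAULT_METHODS if methods is None else methods)
    store: dict[str, dict[str, list]] = {
        m: {"tau2": [], "covered": [], "c": [], "nonconv": 0, "failed": 0}
        for m in methods
    }
    for r in range(scenario.reps):
        meta = simulate_meta(scenario, r)
        true_pool = pool_random(meta.theta_hat_i, meta.sigma2_i,
                                scenario.tau2_true, alpha)
        w_true = true_pool.ci_high - true_pool.ci_low
        for m in methods:
            s = store[m]
            if m == "PL":
                res = pl_estimate(meta.theta_hat_i, meta.sigma2_i, alpha)
                if res.conclusion == NO_CONV:
                    s["nonconv"] += 1
                    continue
                s["tau2"].append(res.tau2)
                s["covered"].append(res.ci_low <= scenario.mu_true <= res.ci_high)
                s["c"].append((res.ci_high - res.ci_low) / w_true)
                continue
            t2 = estimate_tau2(meta.theta_hat_i, meta.sigma2_i, m,
                               n_totals=meta.n_i, reps=dlb_reps,
                               rng=np.random.default_rng([scenario.seed, r, 7]))
            if t2.failed:
                s["failed"] += 1
                continue
            if not t2.converged:
                s["nonconv"] += 1
                continue
            res = pool_random(meta.theta_hat_i, meta.sigma2_i, t2.tau2, alpha,
                              tau2_method=m, model="RE")
            s["tau2"].append(t2.tau2)
            s["covered"].append(res.ci_low <= scenario.mu_true <= res.ci_high)
            s["c"].append((res.ci_high - res.ci_low) / w_true)

    out = []
    for m in methods:
        s = store[m]
        tau2s = np.asarray(s["tau2"], dtype=float)
        if tau2s.size == 0:
            raise ValueError(f"method {m} produced no usable replicates")
        mb, mab = bias_summary(tau2s, scenario.tau2_true)
        q25, q50, q75 = np.percentile(np.asarray(s["c"]), [25, 50, 75])
        out.append(AssessmentSummary(
            distribution=scenario.distribution, tau2_true=scenario.tau2_true,
            k=scenario.k, method=m, n_reps=int(tau2s.size),
            mean_bias=mb, mean_abs_bias=mab, pct_zero=zero_rate(tau2s),
            coverage=100.0 * float(np.mean(s["covered"])),
            c_q25=float(q25), c_median=float(q50), c_q75=float(q75),
            n_nonconverged=s["nonconv"], n_failed=s["failed"],
        ))
    return out


def run_grid(scenarios: Iterable[Scenario],
             methods: Optional[Sequence[str]] = None,
             dlb_reps: int = 10_000, alpha: float = 0.05) -> pd.DataFrame:
    """Assess every scenario and return a tidy summary table."""
    rows = []
    for sc in scenarios:
        for summ in assess_scenario(sc, methods, dlb_reps, alpha):
            rows.append(vars(summ))
    return pd.DataFrame(rows)
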