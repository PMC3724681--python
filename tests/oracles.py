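"""Independent oracle implementations for cross-checking.

These are deliberately naive, loop-based transcriptions of the published
closed-form estimators and pooling formulas, written separately from the
package internals (which are vectorised and share helper code).  Iterative
estimators are checked instead against brute-force grid/likelihood
maximisation in the tests.
"""

import math


def dl_oracle(theta, sigma2):
    k = len(theta)
    w = [1.0 / s for s in sigma2]
    sw = sum(w)
    theta_f = sum(wi * ti for wi, ti in zip(w, theta)) / sw
    q = sum(wi * (ti - theta_f) ** 2 for wi, ti in zip(w, theta))
    denom = sw - sum(wi * wi for wi in w) / sw
    return max(0.0, (q - (k - 1)) / denom)


def vc_oracle(theta, sigma2):
    k = len(theta)
    ybar = sum(theta) / k
    s2 = sum((t - ybar) ** 2 for t in theta) / (k - 1)
    return max(0.0, s2 - sum(sigma2) / k)


def _dk_generalised(theta, sigma2, a):
    """DerSimonian-Kacker generalised moment solution for weights a."""
    sa = sum(a)
    ybar_a = sum(ai * ti for ai, ti in zip(a, theta)) / sa
    q_a = sum(ai * (ti - ybar_a) ** 2 for ai, ti in zip(a, theta))
    correction = sum(ai * si for ai, si in zip(a, sigma2)) - \
        sum(ai * ai * si for ai, si in zip(a, sigma2)) / sa
    denom = sa - sum(ai * ai for ai in a) / sa
    return (q_a - correction) / denom


def dl2_oracle(theta, sigma2):
    step1 = dl_oracle(theta, sigma2)
    a = [1.0 / (s + step1) for s in sigma2]
    return max(0.0, _dk_generalised(theta, sigma2, a))


def vc2_oracle(theta, sigma2):
    step1 = vc_oracle(theta, sigma2)
    a = [1.0 / (s + step1) for s in sigma2]
    return max(0.0, _dk_generalised(theta, sigma2, a))


def mva_oracle(theta, sigma2):
    k = len(theta)
    ybar = sum(theta) / k
    prior = sum((t - ybar) ** 2 for t in theta) / k
    r = [s / prior for s in sigma2]
    v = [1.0 / (ri + 1.0) for ri in r]
    mu_v = sum(vi * ti for vi, ti in zip(v, theta)) / sum(v)
    return sum(vi * (ti - mu_v) ** 2 for vi, ti in zip(v, theta)) / (k - 1)


def mvb_oracle(theta, sigma2):
    k = len(theta)
    prior = vc_oracle(theta, sigma2)
    if prior == 0.0:
        prior = 0.01
    r = [s / prior for s in sigma2]
    v = [1.0 / (ri + 1.0) for ri in r]
    mu_v = sum(vi * ti for vi, ti in zip(v, theta)) / sum(v)
    return sum(vi * (ti - mu_v) ** 2 for vi, ti in zip(v, theta)) / (k - 1)


def bp_oracle(theta, sigma2):
    k = len(theta)
    ybar = sum(theta) / k
    return sum((t - ybar) ** 2 for t in theta) / (k + 1)


def b0_oracle(theta, sigma2, n):
    k = len(theta)
    ybar = sum(theta) / k
    s2 = sum((t - ybar) ** 2 for t in theta)
    big_n = sum(n)
    pooled = sum((ni - 1.0) * si for ni, si in zip(n, sigma2)) / (big_n - k)
    return max(0.0, s2 / (k + 1) - (k - 1) / (k + 1) * pooled)


def dli_oracle(theta, sigma2):
    dl = dl_oracle(theta, sigma2)
    return dl if dl > 0 else 0.01


def loglik(mu, tau2, theta, sigma2):
    """Normal random-effects log-likelihood (up to an additive constant)."""
    return -0.5 * sum(math.log(s + tau2) + (t - mu) ** 2 / (s + tau2)
                      for t, s in zip(theta, sigma2))


def restricted_loglik(tau2, theta, sigma2):
    """REML log-likelihood profiled in mu (up to an additive constant)."""
    w = [1.0 / (s + tau2) for s in sigma2]
    mu = sum(wi * ti for wi, ti in zip(w, theta)) / sum(w)
    return loglik(mu, tau2, theta, sigma2) - 0.5 * math.log(sum(w))


def pool_oracle(theta, sigma2, tau2, z=1.959963984540054):
    w = [1.0 / (s + tau2) for s in sigma2]
    mu = sum(wi * ti for wi, ti in zip(w, theta)) / sum(w)
    se = 1.0 / math.sqrt(sum(w))
    return mu, se, mu - z * se, mu + z * se


def mh_or_oracle(tables):
    """Mantel-Haenszel pooled OR with RBG variance; tables are (a,b,c,d)."""
    R = sum(a * d / (a + b + c + d) for a, b, c, d in tables)
    S = sum(b * c / (a + b + c + d) for a, b, c, d in tables)
    var = 0.0
    for a, b, c, d in tables:
        n = a + b + c + d
        p, q = (a + d) / n, (b + c) / n
        r, s = a * d / n, b * c / n
        var += p * r / (2 * R * R) + (p * s + q * r) / (2 * R * S) + q * s / (2 * S * S)
    return math.log(R / S), var


def peto_oracle(tables):
    """Pooled log Peto OR and its variance from (a,b,c,d) tables."""
    total_oe = total_v = 0.0
    for a, b, c, d in tables:
        n = a + b + c + d
        e = (a + b) * (a + c) / n
        v = (a + b) * (c + d) * (a + c) * (b + d) / (n ** 2 * (n - 1))
        total_oe += a - e
        total_v += v
    return total_oe / total_v, 1.0 / total_v
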