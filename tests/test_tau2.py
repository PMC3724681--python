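import itertools
import math

import numpy as np
import pytest

import oracles
from hetmeta import (
    estimate_tau2,
    tau2_dl,
    tau2_dlb,
    tau2_dli,
    tau2_likelihood,
    tau2_mv,
    tau2_rukhin,
    tau2_vc,
)
from hetmeta.tau2 import InsufficientStudiesError, METHODS
from conftest import random_instances


class TestCanonicalInstance:
    """theta=(0,2), sigma2=(1,1): the moment, REML and MV estimators all
    land on 1 while ML lands on 0 — a sharp divergence worth pinning."""

    def test_divergence_across_estimators(self, canonical):
        theta, sigma2 = canonical
        assert tau2_dl(theta, sigma2).tau2 == pytest.approx(1.0)
        assert tau2_vc(theta, sigma2).tau2 == pytest.approx(1.0)
        assert tau2_likelihood(theta, sigma2, "REML").tau2 == pytest.approx(1.0, abs=1e-8)
        assert tau2_mv(theta, sigma2, "MVa").tau2 == pytest.approx(1.0)
        assert tau2_likelihood(theta, sigma2, "ML").tau2 == 0.0
        assert tau2_dli(theta, sigma2).tau2 == pytest.approx(1.0)

    def test_ml_zero_is_the_likelihood_maximum(self, canonical):
        theta, sigma2 = canonical
        grid = np.linspace(0, 5, 2001)
        ll = [oracles.loglik(_mu_grid(theta, sigma2, t)[0], t, theta, sigma2)
              for t in grid]
        assert grid[int(np.argmax(ll))] == pytest.approx(0.0, abs=5e-3)

    def test_reml_one_is_the_restricted_maximum(self, canonical):
        theta, sigma2 = canonical
        grid = np.linspace(0, 5, 5001)
        rl = [oracles.restricted_loglik(t, theta, sigma2) for t in grid]
        assert grid[int(np.argmax(rl))] == pytest.approx(1.0, abs=5e-3)


class TestHomogeneousInput:
    def test_zero_or_positive_methods_return_exact_zero(self):
        theta = np.full(6, 0.7)
        sigma2 = np.linspace(0.1, 0.5, 6)
        n = np.full(6, 100)
        for m in ("DL", "DL2", "VC", "VC2", "ML", "REML"):
            res = estimate_tau2(theta, sigma2, m)
            assert res.tau2 == 0.0, m
            assert res.converged
        assert estimate_tau2(theta, sigma2, "DLb", rng=0).tau2 == 0.0
        # B0 on equal effects: spread term is zero, estimate truncates to 0
        assert estimate_tau2(theta, sigma2, "B0", n_totals=n).tau2 == 0.0

    def test_positive_only_methods_floor_or_fail(self):
        theta = np.full(4, 0.7)
        sigma2 = np.full(4, 0.2)
        assert tau2_dli(theta, sigma2).tau2 == 0.01
        mva = tau2_mv(theta, sigma2, "MVa")
        assert mva.failed
        mvb = tau2_mv(theta, sigma2, "MVb")  # prior floored at 0.01
        assert mvb.tau2 == pytest.approx(0.0, abs=1e-15)  # equal effects: weighted SS vanishes
        assert tau2_rukhin(theta, sigma2, variant="BP").tau2 == 0.0


ORACLES = {
    "DL": oracles.dl_oracle,
    "DL2": oracles.dl2_oracle,
    "VC": oracles.vc_oracle,
    "VC2": oracles.vc2_oracle,
    "DLi": oracles.dli_oracle,
    "MVa": oracles.mva_oracle,
    "MVb": oracles.mvb_oracle,
    "BP": oracles.bp_oracle,
}


class TestOracleEquivalence:
    @pytest.mark.parametrize("method", sorted(ORACLES))
    def test_closed_forms_match_independent_transcription(self, method):
        for theta, sigma2, n in random_instances(1000, seed=42):
            expected = ORACLES[method](list(theta), list(sigma2))
            got = estimate_tau2(theta, sigma2, method).tau2
            assert got == pytest.approx(expected, abs=1e-10)

    def test_b0_matches_independent_transcription(self):
        for theta, sigma2, n in random_instances(1000, seed=43):
            expected = oracles.b0_oracle(list(theta), list(sigma2), list(n))
            got = estimate_tau2(theta, sigma2, "B0", n_totals=n).tau2
            assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("variant,objective", [
        ("ML", lambda t, th, s2: max(oracles.loglik(mu, t, th, s2)
                                     for mu in _mu_grid(th, s2, t))),
        ("REML", lambda t, th, s2: oracles.restricted_loglik(t, th, s2)),
    ])
    def test_iterative_estimators_match_grid_maximisation(self, variant, objective):
        for theta, sigma2, n in random_instances(60, seed=7, k_range=(3, 15)):
            res = tau2_likelihood(theta, sigma2, variant)
            if not res.converged:
                continue
            hi = max(1.0, 4 * res.tau2 + 0.5)
            grid = np.linspace(0, hi, 4001)
            vals = [objective(t, list(theta), list(sigma2)) for t in grid]
            best = grid[int(np.argmax(vals))]
            assert res.tau2 == pytest.approx(best, abs=max(1e-4, 2 * hi / 4000))


def _mu_grid(theta, sigma2, tau2):
    w = [1.0 / (s + tau2) for s in sigma2]
    mu = sum(wi * ti for wi, ti in zip(w, theta)) / sum(w)
    return [mu]  # at fixed tau2 the likelihood is maximised at the weighted mean


class TestBootstrapDL:
    def test_two_study_enumeration_identity(self, canonical):
        """For k=2 the four equally likely resamples give DL, 0, 0, DL, so
        the infinite-replicate DLb equals DL/2."""
        theta, sigma2 = canonical
        res = tau2_dlb(theta, sigma2, reps=100_000, rng=12345)
        # MC SE of the mean of {0,1} draws at p=1/2 over 1e5 reps
        mc_se = 0.5 / math.sqrt(100_000)
        assert abs(res.tau2 - 0.5) < 3 * mc_se

    def test_three_study_exhaustive_enumeration(self):
        theta = np.array([0.0, 1.0, 3.0])
        sigma2 = np.array([0.5, 1.0, 2.0])
        vals = []
        for idx in itertools.product(range(3), repeat=3):
            vals.append(oracles.dl_oracle([theta[i] for i in idx],
                                          [sigma2[i] for i in idx]))
        exact = np.mean(vals)
        res = tau2_dlb(theta, sigma2, reps=200_000, rng=99)
        mc_se = np.std(vals) / math.sqrt(200_000)
        assert abs(res.tau2 - exact) < 3 * mc_se

    def test_seeded_and_reproducible(self, canonical):
        theta, sigma2 = canonical
        a = tau2_dlb(theta, sigma2, reps=500, rng=7).tau2
        b = tau2_dlb(theta, sigma2, reps=500, rng=7).tau2
        assert a == b


class TestProperties:
    def test_every_estimator_nonnegative(self):
        for theta, sigma2, n in random_instances(200, seed=2):
            for m in METHODS:
                res = estimate_tau2(theta, sigma2, m, n_totals=n, reps=200, rng=0)
                if not res.failed:
                    assert res.tau2 >= 0.0, m

    def test_dl_zero_iff_q_below_df(self):
        for theta, sigma2, n in random_instances(200, seed=9):
            w = 1.0 / sigma2
            tf = np.sum(w * theta) / w.sum()
            q = float(np.sum(w * (theta - tf) ** 2))
            assert (tau2_dl(theta, sigma2).tau2 == 0.0) == (q <= theta.size - 1)

    def test_dli_floor(self):
        for theta, sigma2, n in random_instances(100, seed=4):
            dli = tau2_dli(theta, sigma2).tau2
            dl = tau2_dl(theta, sigma2).tau2
            assert dli == (dl if dl > 0 else 0.01)
            assert dli >= 0.01 or dli == dl

    def test_likelihood_score_residual_small_at_convergence(self):
        for theta, sigma2, n in random_instances(50, seed=21, k_range=(3, 12)):
            for variant in ("ML", "REML"):
                res = tau2_likelihood(theta, sigma2, variant)
                if not res.converged or res.tau2 == 0.0:
                    continue
                w = 1.0 / (sigma2 + res.tau2)
                mu = np.sum(w * theta) / w.sum()
                upd = np.sum(w * w * ((theta - mu) ** 2 - sigma2)) / np.sum(w * w)
                if variant == "REML":
                    upd += 1.0 / w.sum()
                assert abs(upd - res.tau2) < 1e-8

    def test_insufficient_studies_raise(self):
        with pytest.raises(InsufficientStudiesError):
            tau2_dl(np.array([1.0]), np.array([0.5]))

    def test_b0_requires_study_sizes(self, canonical):
        theta, sigma2 = canonical
        with pytest.raises(ValueError):
            tau2_rukhin(theta, sigma2, variant="B0")

    def test_method_dependent_q_centre_changes_dl(self, canonical):
        theta, sigma2 = np.array([0.0, 1.0, 2.5]), np.array([0.2, 0.9, 0.4])
        iv = tau2_dl(theta, sigma2)
        shifted = tau2_dl(theta, sigma2, theta_f=0.0)
        assert shifted.tau2 > iv.tau2  # IV centre minimises Q
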