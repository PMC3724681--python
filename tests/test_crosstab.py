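import numpy as np
import pytest

from hetmeta import (
    StudyRecord,
    analyse_one,
    crosstab,
    generate_corpus,
    run_method_matrix,
)
from hetmeta.crosstab import (
    STRATA,
    STRATUM_FE_POS,
    STRATUM_FE_ZERO,
    STRATUM_RE_POS,
    CorpusAnalysis,
)
from hetmeta.pooling import NO_COMP, NS, SIG


def precomp(effects, variances, aid="A"):
    return [StudyRecord(f"{aid}s{i}", "precomputed", effect=e, variance=v)
            for i, (e, v) in enumerate(zip(effects, variances))]


class TestAnalyseOne:
    def test_homogeneous_analysis_dl_equals_fe(self):
        # identical effects: DL tau2 = 0, so the DL conclusion must equal FE's
        res = analyse_one(precomp([0.5, 0.5, 0.5], [0.04, 0.05, 0.06]),
                          "IV", "MD", methods=["FE", "DL"])
        assert res.tau2_dl == 0.0
        assert res.baseline_stratum == STRATUM_FE_ZERO
        assert res.conclusions["DL"] == res.conclusions["FE"]

    def test_single_study_is_nocomp(self):
        res = analyse_one(precomp([0.5], [0.04]), "IV", "MD", methods=["FE", "DL"])
        assert res.baseline_conclusion == NO_COMP
        assert all(c == NO_COMP for c in res.conclusions.values())

    def test_heterogeneous_analysis_stratified_re(self):
        res = analyse_one(precomp([0.0, 2.0], [1.0, 1.0]), "IV", "MD",
                          methods=["FE", "DL"])
        assert res.tau2_dl == pytest.approx(1.0)
        assert res.baseline_model == "RE-DL"
        assert res.baseline_stratum == STRATUM_RE_POS

    def test_declared_fe_baseline_with_heterogeneity(self):
        res = analyse_one(precomp([0.0, 2.0], [1.0, 1.0]), "IV", "MD",
                          methods=["FE", "DL"], baseline_model="FE")
        assert res.baseline_stratum == STRATUM_FE_POS

    def test_re_se_never_below_fe_se(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            k = int(rng.integers(2, 8))
            recs = precomp(rng.normal(0, 0.6, size=k), rng.uniform(0.02, 0.3, size=k))
            res = analyse_one(recs, "IV", "MD", methods=["FE", "DL", "REML", "BP"])
            for m, se in res.se.items():
                if m != "FE" and np.isfinite(se):
                    assert se >= res.se["FE"] - 1e-12


class TestCrossTab:
    def make(self, stratum, base, cand):
        return CorpusAnalysis("a", "IV", "MD", 3, "FE", stratum, base,
                              0.0, {"X": cand}, {})

    def test_candidate_equal_to_baseline_never_changes(self):
        analyses = [self.make(STRATUM_FE_ZERO, NS, NS),
                    self.make(STRATUM_FE_ZERO, SIG, SIG)]
        ct = crosstab(analyses, candidate="X")
        assert all(v == 0.0 for v in ct.pct_changed.values() if v == v)

    def test_hand_tabulated_counts(self):
        analyses = [self.make(STRATUM_FE_ZERO, NS, NS),
                    self.make(STRATUM_FE_ZERO, NS, SIG),
                    self.make(STRATUM_FE_POS, SIG, NS),
                    self.make(STRATUM_FE_POS, SIG, SIG)]
        ct = crosstab(analyses, candidate="X")
        t = ct.table.set_index(["stratum", "baseline_conclusion", "candidate_conclusion"])
        assert t.loc[(STRATUM_FE_ZERO, NS, NS), "count"] == 1
        assert t.loc[(STRATUM_FE_ZERO, NS, SIG), "count"] == 1
        assert ct.pct_changed[STRATUM_FE_ZERO] == pytest.approx(50.0)
        assert ct.pct_changed[STRATUM_FE_POS] == pytest.approx(50.0)

    def test_cell_percentages_sum_to_100_per_stratum(self):
        rng = np.random.default_rng(8)
        analyses = [self.make(rng.choice(STRATA),
                              rng.choice([NS, SIG]), rng.choice([NS, SIG]))
                    for _ in range(100)]
        ct = crosstab(analyses, candidate="X")
        sums = ct.table.groupby("stratum")["cell_pct"].sum()
        assert np.allclose(sums.values, 100.0)


class TestCorpusGeneration:
    def test_same_seed_identical_corpus(self):
        a = generate_corpus(40, seed=11)
        b = generate_corpus(40, seed=11)
        assert a.equals(b)

    def test_size_distribution_weighted_to_small_metas(self):
        corpus = generate_corpus(800, seed=5)
        sizes = corpus.groupby("analysis_id").size()
        share_small = float((sizes <= 3).mean())
        assert share_small == pytest.approx(0.55, abs=0.06)

    def test_pure_null_mixture_yields_high_dl_zero_rate(self):
        corpus = generate_corpus(60, tau2_mixture=((1.0, 0.0),), seed=21)
        analyses = run_method_matrix(corpus, methods=["FE", "DL"], seed=0)
        zero_share = np.mean([a.tau2_dl == 0.0 for a in analyses
                              if np.isfinite(a.tau2_dl)])
        assert zero_share > 0.5


@pytest.fixture(scope="module")
def analyses():
    corpus = generate_corpus(80, seed=2)
    return run_method_matrix(corpus, methods=["FE", "DL", "DLb", "REML", "MVa"],
                             seed=2, dlb_reps=300)


class TestMethodMatrix:
    def test_strata_partition_the_corpus(self, analyses):
        assert all(a.baseline_stratum in STRATA for a in analyses)
        total = sum(1 for a in analyses)
        assert total == 80

    def test_bootstrap_flags_heterogeneity_more_often_than_dl(self):
        # DLb = 0 requires every bootstrap resample to look homogeneous,
        # so on a heterogeneous corpus it flags tau2 > 0 strictly more often
        from hetmeta import as_arrays, compute_effects, estimate_tau2
        from hetmeta.crosstab import _records_from_rows

        corpus = generate_corpus(120, tau2_mixture=((1.0, 0.10),), seed=31)
        dl_pos = dlb_pos = 0
        for i, (aid, grp) in enumerate(corpus.groupby("analysis_id")):
            effects = compute_effects(_records_from_rows(grp), str(grp.iloc[0]["measure"]))
            theta, sigma2 = as_arrays(effects)
            if theta.size < 2:
                continue
            dl_pos += estimate_tau2(theta, sigma2, "DL").tau2 > 0
            dlb_pos += estimate_tau2(theta, sigma2, "DLb", reps=300,
                                     rng=np.random.default_rng(i)).tau2 > 0
        assert dlb_pos > dl_pos

    def test_deterministic_given_seed(self):
        corpus = generate_corpus(30, seed=9)
        r1 = run_method_matrix(corpus, methods=["FE", "DL", "DLb"], seed=7, dlb_reps=200)
        r2 = run_method_matrix(corpus, methods=["FE", "DL", "DLb"], seed=7, dlb_reps=200)
        assert [a.conclusions for a in r1] == [a.conclusions for a in r2]
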