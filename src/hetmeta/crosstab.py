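"""Conclusion-sensitivity analysis across heterogeneity methods.

Re-analyses a corpus of meta-analyses under a panel of methods and
cross-tabulates each candidate method's statistical conclusion (significant
vs non-significant at the analysis's alpha) against a baseline model
choice, stratified by detected heterogeneity:

* baseline fixed-effect with DL tau2_hat = 0 (homogeneity plausibly assumed),
* baseline fixed-effect with DL tau2_hat > 0 (heterogeneity detected but
  ignored),
* baseline random-effects DL with tau2_hat > 0 (heterogeneity accounted for).

A synthetic corpus generator produces Cochrane-like mixtures of small
continuous and dichotomous meta-analyses so the machinery can be exercised
and validated without access to a real review database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .effects import (
    DICHOTOMOUS,
    CONTINUOUS,
    PRECOMPUTED,
    StudyRecord,
    as_arrays,
    compute_effects,
    included,
)
from .fixed import pool_iv_fixed, pool_mh, pool_peto
from .pooling import NO_COMP, NS, SIG, PooledResult, classify_conclusion, pool_random, pool_with_tau2
from .tau2 import METHODS, estimate_tau2, tau2_dl

STRATUM_FE_ZERO = "FE, tau2=0"
STRATUM_FE_POS = "FE, tau2>0"
STRATUM_RE_POS = "RE-DL, tau2>0"
STRATA = (STRATUM_FE_ZERO, STRATUM_FE_POS, STRATUM_RE_POS)


@dataclass
class CorpusAnalysis:
    """One corpus meta-analysis evaluated under every method."""

    analysis_id: str
    approach: str                    # IV | MH | Peto
    measure: str
    k: int
    baseline_model: str              # FE | RE-DL
    baseline_stratum: str
    baseline_conclusion: str
    tau2_dl: float
    conclusions: dict = field(default_factory=dict)   # method -> NS/Sig/NoConv/NoComp
    se: dict = field(default_factory=dict)            # method -> standard error


@dataclass
class CrossTab:
    """Counts and cell percentages of candidate vs baseline conclusions."""

    baseline: str
    candidate: str
    table: pd.DataFrame              # stratum, baseline_conclusion, candidate_conclusion, count, cell_pct
    pct_changed: dict                # stratum -> % of computable analyses whose conclusion flipped


def _analysis_methods(methods: Optional[Sequence[str]]) -> list[str]:
    return ["FE"] + list(METHODS) if methods is None else list(methods)


def analyse_one(records: Sequence[StudyRecord], approach: str, measure: str,
                analysis_id: str = "", methods: Optional[Sequence[str]] = None,
                alpha: float = 0.05, baseline_model: Optional[str] = None,
                dlb_reps: int = 10_000, rng=None) -> CorpusAnalysis:
    """Evaluate one meta-analysis under the fixed baseline and all methods.

    DL's Q (and hence every moment estimator fed by it) is centred at the
    fixed-effect estimate of the chosen approach — IV, Mantel-Haenszel or
    Peto — so the heterogeneity estimate is approach-dependent.
    """
    methods = _analysis_methods(methods)
    effects = compute_effects(records, measure)
    kept = included(effects)
    k = len(kept)

    def all_status(status: str, stratum: str = STRATUM_FE_ZERO) -> CorpusAnalysis:
        return CorpusAnalysis(analysis_id, approach, measure, k,
                              baseline_model or "FE", stratum, status,
                              float("nan"),
                              {m: status for m in methods}, {})

    if k <= 1:
        # mirrors the corpus rule: not computable when one or zero studies remain
        return all_status(NO_COMP)

    theta, sigma2 = as_arrays(kept)
    n_totals = np.array([float("nan") if e.n_total is None else float(e.n_total)
                         for e in kept])
    if approach == "MH":
        fixed = pool_mh(records, measure)
    elif approach == "Peto":
        fixed = pool_peto(records)
    else:
        fixed = pool_iv_fixed(effects)
    if not fixed.computable:
        return all_status(NO_COMP)

    dl = tau2_dl(theta, sigma2, theta_f=fixed.mu_hat)

    if baseline_model is None:
        baseline_model = "FE" if dl.tau2 == 0 else "RE-DL"
    if dl.tau2 == 0:
        stratum = STRATUM_FE_ZERO
    elif baseline_model == "FE":
        stratum = STRATUM_FE_POS
    else:
        stratum = STRATUM_RE_POS

    fe_result = PooledResult(fixed.mu_hat, fixed.se,
                             *_wald_bounds(fixed.mu_hat, fixed.se, alpha),
                             "FE", alpha=alpha)
    fe_result.conclusion = classify_conclusion(fe_result)
    if baseline_model == "FE":
        baseline_conclusion = fe_result.conclusion
    else:
        base = pool_random(theta, sigma2, dl.tau2, alpha, tau2_method="DL", model="RE")
        baseline_conclusion = base.conclusion

    out = CorpusAnalysis(analysis_id, approach, measure, k, baseline_model,
                         stratum, baseline_conclusion, dl.tau2)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for m in methods:
        if m == "FE":
            out.conclusions[m] = fe_result.conclusion
            out.se[m] = fe_result.se
            continue
        try:
            t2 = estimate_tau2(theta, sigma2, m, n_totals=n_totals,
                               reps=dlb_reps, rng=gen, theta_f=fixed.mu_hat)
        except ValueError:
            out.conclusions[m] = NO_COMP
            continue
        res = pool_with_tau2(theta, sigma2, t2, alpha)
        out.conclusions[m] = res.conclusion
        out.se[m] = res.se
    return out


def _wald_bounds(mu: float, se: float, alpha: float) -> tuple[float, float]:
    from scipy import stats
    z = stats.norm.ppf(1 - alpha / 2)
    return mu - z * se, mu + z * se


def run_method_matrix(corpus: pd.DataFrame,
                      methods: Optional[Sequence[str]] = None,
                      alpha: float = 0.05, seed: Optional[int] = None,
                      dlb_reps: int = 10_000) -> list[CorpusAnalysis]:
    """Analyse every meta-analysis in a corpus table under every method.

    The corpus is the long study-level table produced by
    :func:`generate_corpus` (or read from its CSV): one row per study with
    an ``analysis_id``, the study columns of the effects module, plus
    per-analysis ``measure``, ``approach`` and optional ``baseline_model``
    and ``alpha`` columns.
    """
    analyses = []
    for i, (aid, grp) in enumerate(corpus.groupby("analysis_id", sort=True)):
        first = grp.iloc[0]
        measure = str(first["measure"])
        approach = str(first.get("approach", "IV"))
        a = float(first["alpha"]) if "alpha" in grp.columns and not pd.isna(first["alpha"]) else alpha
        declared = None
        if "baseline_model" in grp.columns and not pd.isna(first["baseline_model"]):
            declared = str(first["baseline_model"])
        records = _records_from_rows(grp)
        analyses.append(
            analyse_one(records, approach, measure, analysis_id=str(aid),
                        methods=methods, alpha=a, baseline_model=declared,
                        dlb_reps=dlb_reps,
                        rng=np.random.default_rng([0 if seed is None else seed, i]))
        )
    return analyses


def _records_from_rows(grp: pd.DataFrame) -> list[StudyRecord]:
    records = []
    for _, row in grp.iterrows():
        design = str(row["design"])
        if design == DICHOTOMOUS:
            rec = StudyRecord(str(row["study_id"]), design,
                              events1=int(row["events1"]), total1=int(row["total1"]),
                              events2=int(row["events2"]), total2=int(row["total2"]))
        elif design == CONTINUOUS:
            rec = StudyRecord(str(row["study_id"]), design,
                              n1=float(row["n1"]), mean1=float(row["mean1"]), sd1=float(row["sd1"]),
                              n2=float(row["n2"]), mean2=float(row["mean2"]), sd2=float(row["sd2"]))
        else:
            rec = StudyRecord(str(row["study_id"]), PRECOMPUTED,
                              effect=float(row["effect"]), variance=float(row["variance"]),
                              n_total=None if pd.isna(row.get("n_total")) else int(row["n_total"]))
        records.append(rec)
    return records


def crosstab(analyses: Sequence[CorpusAnalysis], baseline: str = "baseline",
             candidate: str = "DLb") -> CrossTab:
    """Cross-tabulate a candidate method's conclusions against the baseline.

    ``baseline="baseline"`` uses each analysis's own baseline model choice;
    any method label uses that method's conclusion as the reference.  The
    '% changed' summaries count, per stratum, the computable analyses
    (both conclusions in {NS, Sig}) whose conclusion flipped.
    """
    rows = []
    changed = {s: [0, 0] for s in STRATA}  # stratum -> [flips, computable]
    for a in analyses:
        base = a.baseline_conclusion if baseline == "baseline" else a.conclusions.get(baseline, NO_COMP)
        cand = a.conclusions.get(candidate, NO_COMP)
        rows.append((a.baseline_stratum, base, cand))
        if base in (NS, SIG) and cand in (NS, SIG):
            changed[a.baseline_stratum][1] += 1
            changed[a.baseline_stratum][0] += base != cand
    df = pd.DataFrame(rows, columns=["stratum", "baseline_conclusion",
                                     "candidate_conclusion"])
    counts = (df.value_counts().rename("count").reset_index()
              .sort_values(["stratum", "baseline_conclusion", "candidate_conclusion"])
              .reset_index(drop=True))
    totals = counts.groupby("stratum")["count"].transform("sum")
    counts["cell_pct"] = 100.0 * counts["count"] / totals
    pct_changed = {s: (100.0 * f / n if n else float("nan"))
                   for s, (f, n) in changed.items()}
    return CrossTab(baseline, candidate, counts, pct_changed)


# ---------------------------------------------------------------------------
# Synthetic corpus generation

#: Default meta-analysis size law: heavily weighted towards 2-3 studies,
#: mimicking the predominance of very small meta-analyses in systematic
#: review databases (P(k <= 3) = 0.55), with a geometric tail to k = 30.
def default_size_distribution() -> dict[int, float]:
    probs = {2: 0.35, 3: 0.20}
    tail = np.array([0.82 ** i for i in range(4, 31)])
    tail = 0.45 * tail / tail.sum()
    probs.update({k: float(p) for k, p in zip(range(4, 31), tail)})
    return probs


#: Default heterogeneity mixture: half the analyses truly homogeneous, the
#: rest split between low, moderate and large between-study variance.
DEFAULT_TAU2_MIXTURE = ((0.50, 0.0), (0.20, 0.01), (0.15, 0.03), (0.15, 0.10))


def generate_corpus(n_analyses: int = 200,
                    size_distribution: Optional[dict[int, float]] = None,
                    tau2_mixture: Sequence[tuple[float, float]] = DEFAULT_TAU2_MIXTURE,
                    outcome_mix: float = 0.5,
                    fe_baseline_share: float = 0.0,
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a synthetic corpus of meta-analyses as a long study table.

    ``outcome_mix`` is the probability an analysis has a continuous outcome
    (mean difference, IV pooling); the rest are dichotomous 2x2 analyses
    pooled with Mantel-Haenszel odds ratios.  Overall true effects are drawn
    from a null-centred normal so significant and non-significant analyses
    both occur; true study effects scatter around them with the mixture's
    tau^2.  ``fe_baseline_share`` is the probability an analysis declares a
    fixed-effect baseline regardless of detected heterogeneity, emulating
    reviewers who ignore a positive tau2 estimate; other analyses leave the
    baseline undeclared (chosen from the DL estimate downstream).
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sizes = size_distribution or default_size_distribution()
    ks = np.array(sorted(sizes))
    kp = np.array([sizes[k] for k in ks], dtype=float)
    kp /= kp.sum()
    mix_p = np.array([p for p, _ in tau2_mixture], dtype=float)
    mix_p /= mix_p.sum()
    mix_t = np.array([t for _, t in tau2_mixture], dtype=float)

    rows = []
    for i in range(n_analyses):
        aid = f"A{i:05d}"
        k = int(rng.choice(ks, p=kp))
        tau2 = float(mix_t[rng.choice(mix_t.size, p=mix_p)])
        mu = float(rng.normal(0.0, 0.3))
        theta = mu + math.sqrt(tau2) * rng.standard_normal(k)
        declared = "FE" if rng.random() < fe_baseline_share else None
        if rng.random() < outcome_mix:
            measure, approach = "MD", "IV"
            for j in range(k):
                n = int(rng.integers(20, 201))
                sd = 1.0
                m1 = float(rng.normal(theta[j], sd / math.sqrt(n)))
                m2 = float(rng.normal(0.0, sd / math.sqrt(n)))
                s1 = float(sd * math.sqrt(rng.chisquare(n - 1) / (n - 1)))
                s2 = float(sd * math.sqrt(rng.chisquare(n - 1) / (n - 1)))
                rows.append(dict(analysis_id=aid, study_id=f"{aid}s{j}",
                                 design=CONTINUOUS, measure=measure,
                                 approach=approach, baseline_model=declared,
                                 n1=n, mean1=m1, sd1=s1,
                                 n2=n, mean2=m2, sd2=s2))
        else:
            measure, approach = "logOR", "MH"
            for j in range(k):
                n = int(rng.integers(20, 201))
                p0 = float(rng.uniform(0.05, 0.5))
                logit1 = math.log(p0 / (1 - p0)) + theta[j]
                p1 = 1.0 / (1.0 + math.exp(-logit1))
                e1 = int(rng.binomial(n, p1))
                e2 = int(rng.binomial(n, p0))
                rows.append(dict(analysis_id=aid, study_id=f"{aid}s{j}",
                                 design=DICHOTOMOUS, measure=measure,
                                 approach=approach, baseline_model=declared,
                                 events1=e1, total1=n,
                                 events2=e2, total2=n))
    return pd.DataFrame(rows)
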