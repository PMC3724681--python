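# hetmeta

Heterogeneity estimation and conclusion-sensitivity analysis for
meta-analysis.

When study-level results are pooled, the choice between a fixed-effect and
a random-effects model — and, within the latter, the choice of
between-study variance estimator — can flip a meta-analysis between a
statistically significant and a non-significant conclusion. Because the
between-study variance τ² is estimated with large uncertainty when the
number of studies k is small (and most published meta-analyses combine only
two or three studies), "no heterogeneity detected" very often means
"heterogeneity present but undetected". `hetmeta` is a library and
command-line tool for quantifying exactly this fragility, aimed at
methodologists and systematic reviewers.

## The model

Each study i reports an effect estimate θ̂ᵢ with known within-study variance
σ̂ᵢ². Under the random-effects model

θ̂ᵢ = μ + bᵢ + εᵢ,  bᵢ ~ N(0, τ²),  εᵢ ~ N(0, σ̂ᵢ²),

the pooled estimate is μ̂ = Σwᵢ*θ̂ᵢ / Σwᵢ* with wᵢ* = 1/(σ̂ᵢ² + τ̂²) and
SE(μ̂) = (Σwᵢ*)^(−1/2). Everything therefore hinges on τ̂². The package
implements twelve estimators, grouped by their a-priori stance:

* **zero-or-positive** — DerSimonian-Laird (DL), its two-step refinement
  (DL2), a non-parametric bootstrap DL (DLb: resample the k studies with
  replacement 10,000 times, average the truncated DL estimates), Hedges'
  variance-component estimator (VC) and its two-step refinement (VC2),
  maximum likelihood (ML), restricted maximum likelihood (REML), and the
  Rukhin Bayes estimator with zero prior variance (B0, which weights by
  study sizes nᵢ);
* **positive-only** — DL floored at 0.01 (DLi), the Sidik-Jonkman
  model-error-variance estimators (MVa, MVb), and the always-positive
  Rukhin estimator (BP).

Around the estimators sit the rest of the workflow: effect sizes from raw
study summaries (MD, Hedges-g SMD, log OR/RR, RD, log Peto OR, with
standard rare-event handling), fixed-effect pooling by inverse variance,
Mantel-Haenszel and Peto, Cochran's Q / H² / I² centred at the
approach-appropriate fixed estimate, Wald and profile-likelihood confidence
intervals, a simulation framework with six true-effect distributions, the
four standard performance criteria (bias, % zero estimates, coverage, and
the error-interval ratio c = estimated CI width / CI width at the true τ²),
and a cross-tabulation engine that counts conclusion changes between
methods, stratified by whether heterogeneity was detected and acted on.

## Worked example

```python
import numpy as np
from hetmeta import METHODS, estimate_tau2, pool_with_tau2

theta  = np.array([0.12, -0.35, 0.61, 0.20, -0.05, 0.44, 0.90, 0.03])
sigma2 = np.array([0.04, 0.09, 0.12, 0.02, 0.30, 0.07, 0.15, 0.05])

for method in ("DL", "DLb", "ML", "BP"):
    t2 = estimate_tau2(theta, sigma2, method, reps=10_000,
                       rng=np.random.default_rng(1))
    res = pool_with_tau2(theta, sigma2, t2)
    print(f"{method:>4s} tau2={t2.tau2:.4f} mu={res.mu_hat:.4f} "
          f"CI=({res.ci_low:.4f}, {res.ci_high:.4f}) {res.conclusion}")
```

prints

```
  DL tau2=0.0254 mu=0.2037 CI=(-0.0084, 0.4158) NS
 DLb tau2=0.0279 mu=0.2045 CI=(-0.0113, 0.4203) NS
  ML tau2=0.0000 mu=0.1940 CI=(0.0276, 0.3604) Sig
  BP tau2=0.1228 mu=0.2218 CI=(-0.0922, 0.5357) NS
```

The same eight studies are "significantly" positive under ML (which
estimates zero heterogeneity here and collapses to fixed-effect) and
non-significant under every method that detects spread between studies —
the conclusion is an artefact of the heterogeneity method. The scripts in
`examples/` walk through this (`estimate_heterogeneity.py`), a simulation
assessment (`simulate_and_assess.py`), and a corpus-level sensitivity
cross-tab (`conclusion_sensitivity.py`).

The same operations are available from a shell:

```sh
hetmeta estimate studies.csv --measure MD            # all methods, one CSV row each
hetmeta simulate --dist skew_extreme --tau2 0.03 --k 5 --reps 1000 --seed 1 -o metas.csv
hetmeta assess --dist normal --tau2 0.1 --k 5 --methods DL,DLb,REML --reps 1000 -o grid.csv
hetmeta compare --candidates all --seed 1 -o crosstab.csv
```

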