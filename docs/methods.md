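# Methods

## Model and scope

`hetmeta` works on the standard two-stage summary-data model: study i
contributes an effect estimate θ̂ᵢ and a within-study variance σ̂ᵢ² that is
treated as known. Under the random-effects model θ̂ᵢ ~ N(μ, σ̂ᵢ² + τ²), and
the package's job is (a) estimating τ², (b) pooling μ under fixed- and
random-effects assumptions, (c) assessing the estimators by simulation and
(d) quantifying how much pooled conclusions move when the method changes.
Uncertainty in τ̂² is ignored by every pooling method except profile
likelihood, which is the point: the plug-in treatment is what practice
does, and its fragility is what the sensitivity machinery measures.

## Effect sizes

Continuous outcomes use the mean difference (variance SD₁²/n₁ + SD₂²/n₂)
or the Hedges-corrected standardised mean difference g with variance
N/(n₁n₂) + g²/(2(N − 3.94)), the form used by mainstream review software.
Dichotomous 2×2 tables give log OR, log RR (delta-method variances) or the
risk difference. Ratio measures receive a +0.5 continuity correction on
all four cells when any cell is zero; the risk difference uses raw counts.
Double-zero (or double-full) tables carry no information about a ratio and
are flagged excluded; for the risk difference such tables are retained in
Mantel-Haenszel pooling (whose weights need no per-study variance) but are
flagged when an inverse-variance σ̂ᵢ² would be zero, preserving the
invariant that every effect entering IV pooling has σ̂ᵢ² > 0. Peto's
one-step log odds ratio is (O − E)/V with variance 1/V, V the
hypergeometric variance; V = 0 (an empty margin) excludes the study.

Fixed-effect pooling: inverse variance; Mantel-Haenszel with
Robins-Breslow-Greenland (OR) and Greenland-Robins (RR, RD) standard
errors; Peto Σ(O−E)/ΣV. Cochran's Q is always computed with IV weights but
centred at the fixed-effect estimate of the chosen approach (IV, MH or
Peto), so DL-family τ̂² estimates are deliberately approach-dependent.
Meta-analyses that cannot be computed (one usable study, empty margins)
return tagged `NoComp` statuses rather than exceptions so that corpus-level
tabulations can count them.

## τ² estimators

Let w = 1/σ̂², Q = Σw(θ̂ − θ̂_F)², k the number of studies, θ̄ᵤ the
unweighted mean effect, S² = Σ(θ̂ᵢ − θ̄ᵤ)².

* **DL** = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)).
* **DL2 / VC2**: one refinement step of the DerSimonian-Kacker generalised
  moment equation with weights aᵢ = 1/(σ̂ᵢ² + τ̂²_step1), centred at the
  corresponding random-effects estimate; step 1 is DL (or VC), truncated.
  Exactly one step is taken, not iteration to convergence.
* **DLb**: resample the k (θ̂ᵢ, σ̂ᵢ²) pairs with replacement (default
  10,000 replicates, seeded), compute truncated DL on each resample,
  return the mean. Resamples containing a single distinct study have Q = 0
  and contribute 0. For k = 2 the four equally likely resamples give
  exactly DLb → DL/2 as replicates → ∞, a useful enumeration oracle.
* **DLi**: DL if positive, else 0.01.
* **VC** (Hedges) = max(0, S²/(k−1) − Σσ̂ᵢ²/k).
* **ML / REML**: truncated fixed-point iteration with w = 1/(σ̂² + τ²) and
  μ̂ recomputed each step; the REML update adds 1/Σw. Start at the
  truncated VC estimate, tolerance 1e-10 on successive τ² change, 100
  iterations maximum, truncation at every step. Non-convergence is
  returned as a status (`converged=False`), not an exception, and the
  assessment and cross-tab layers count it.
* **MVa / MVb** (Sidik-Jonkman model error variance): ratios
  rᵢ = σ̂ᵢ²/τ̂₀² with prior τ̂₀² = S²/k (MVa) or the VC estimate, plus 0.01
  when VC = 0 (MVb); weights vᵢ = 1/(rᵢ+1); τ̂² = Σvᵢ(θ̂ᵢ−μ̂ᵥ)²/(k−1).
  MVa fails (tagged, not raised) when all effects are equal.
* **B0 / BP** (Rukhin Bayes): B0 = max(0, S²/(k+1) − (k−1)/(k+1) ·
  Σ(nᵢ−1)σ̂ᵢ²/(N−k)) with N = Σnᵢ the total subjects; BP = S²/(k+1),
  always non-negative, needs no study sizes and no truncation.

Pinned divergence: on θ̂ = (0, 2), σ̂² = (1, 1), DL = VC = REML = MVa =
DLi = 1 while ML = 0 (the global ML maximiser is on the boundary) and
DLb → 1/2. The test suite verifies every closed form against an
independent naive transcription on 1,000 random instances to 1e-10, the
iterative estimators against brute-force grid maximisation of their
(restricted) likelihoods, and DL/ML/REML/MH additionally against R's
`metafor`.

## Pooling and inference

Random-effects pooling uses wᵢ* = 1/(σ̂ᵢ² + τ̂²) and normal-quantile Wald
intervals (never t); α = 0.05 two-sided by default and configurable per
analysis. τ̂² = 0 reproduces the fixed-effect numbers exactly. Conclusions
are classified Sig/NS by whether the null (0 on additive and log scales)
lies outside the CI, with NoConv/NoComp passed through.

Profile likelihood: the point estimate is the joint ML maximiser; each CI
bound solves 2[ℓ_p(μ̂) − ℓ_p(μ)] = χ²₁(0.95), where ℓ_p re-maximises τ²
(truncated at 0) at each fixed μ by the same fixed-point scheme. Bounds
are bracketed by stepping outward from the Wald interval (growth factor
1.6) and then found by Brent's method to 1e-8; failure to bracket within
200 expansions yields `NoConv`. Because the profile accounts for τ²
uncertainty, the PL interval is never narrower than the Wald interval at
τ̂²_ML, and collapses onto the fixed-effect interval when the profile is
flat at zero heterogeneity.

## Simulation design

Each replicate draws, for k ∈ [2, 30] studies:

* σᵢ²: χ² (1 df) / 4, rejection-sampled into (0.009, 0.6). Quadrature
  gives E[σᵢ²] = 0.1732 and m = E[1/σᵢ²] = 17.836, so the three
  heterogeneity levels τ² = 0.01 / 0.03 / 0.10 imply H² = 1 + τ²m =
  1.18 / 1.54 / 2.78 and I² = 100·τ²m/(1+τ²m) = 15.1 / 34.9 / 64.1%.
  The 1-df choice is forced by these constants jointly.
* θᵢ: mean 0.5, variance τ², from one of six shapes — normal; two skewed
  shapes with (skewness, kurtosis) = (1, 4) and (2, 9) (kurtosis
  non-excess), generated by a Fleishman cubic polynomial transform of a
  standard normal because those moment pairs exceed the skew-normal
  family's range; uniform on 0.5 ± √(3τ²); a symmetric bimodal mixture
  N(0.5 ± δ, ω²) with δ = ω = √(τ²/2) (modes separated, variance exact);
  and a double-spike on 0.5 ± √τ² for interventions with two distinct
  regimes. The last three are the simplest constructions matching the
  stated intent and moments; the bimodal δ = ω split is this package's
  choice.
* θ̂ᵢ = θᵢ + N(0, σᵢ²), with σ̂ᵢ² = σᵢ² (variances known by design);
  nᵢ ~ uniform integers [50, 500], independent of effects, feeding B0.

Replicate r of a scenario uses the seed sequence (scenario seed, r), so
every replicate is individually reproducible and scenarios are independent
streams. What the generator does **not** emulate: estimated (noisy) σ̂ᵢ²,
correlation between effect size and precision (small-study effects),
publication selection, and non-normal within-study error — so nominal
performance here is a best case for real data, and the comparisons between
estimators, not the absolute coverage figures, are the transferable
result.

## Assessment criteria

Per (scenario, method) cell: mean bias and mean absolute bias of τ̂²; the
percentage of estimates exactly 0 after truncation (no epsilon — truncation
assigns the literal value); coverage of μ = 0.5 by the 95% interval; and
the error-interval ratio c = (estimated CI width)/(CI width at the true
τ²), summarised by median and quartiles. Failed or non-converged
replicates are excluded from all four denominators and reported as counts.
Monte-Carlo tolerances in the tests are 3 standard errors at the stated
replication sizes.

The headline acceptance checks run at: 10⁶ draws (within-variance mean),
10⁴ replicates (coverage at τ² = 0, k = 10; parameter recovery at k = 30,
τ² = 0.10), and 18 cells × 10³ replicates with 500 bootstrap replicates
per DLb call (detection ordering). These sizes keep the full suite under a
minute of simulation while leaving Monte-Carlo error well below the effect
sizes being asserted. One documented outcome: DL coverage at τ² = 0,
k = 10 is ≈96.3%, not 95% — truncating negative τ̂² to zero widens roughly
half the intervals, so the truncated-DL interval genuinely over-covers
under exact homogeneity (confirmed independently with `metafor`). The
acceptance test asserting nominal 95% coverage therefore fails, and is
left failing deliberately; see the repository notes on test expectations.

## Sensitivity cross-tabs

A corpus (real or synthetic) is re-analysed under every method; each
analysis is assigned a baseline stratum — fixed-effect with τ̂²_DL = 0,
fixed-effect with τ̂²_DL > 0 (heterogeneity detected but ignored), or
random-effects DL with τ̂²_DL > 0 — using a declared per-analysis baseline
when the corpus provides one and otherwise defaulting to FE iff τ̂²_DL = 0.
Conclusion changes are counted per stratum among computable analyses. The
synthetic corpus generator draws meta-analysis sizes from a 2-3-heavy law
(P(k ≤ 3) = 0.55), true τ² from a mixture with a point mass at zero,
overall effects from N(0, 0.3²), and builds either continuous two-arm
summaries or binomial 2×2 tables; `fe_baseline_share` lets a fraction of
analyses declare a fixed-effect baseline regardless of detected
heterogeneity, emulating reviewer behaviour. It is a structural stand-in
for a real review database, not a calibrated model of one: the cross-tab
percentages it produces exercise and validate the engine but are not
estimates of any published corpus's rates.

## Numerical notes and limitations

* All ratio-scale effects are pooled on the log scale; normal quantiles
  throughout.
* DLb cost is O(reps × k) per call; harness-level defaults scale the
  bootstrap down (500-2,000 replicates) where thousands of calls are made,
  and the estimator's Monte-Carlo SE at those sizes is accounted for in
  the tests' tolerances.
* ML/REML fixed-point iteration converges linearly; the 0.1-3.5%
  non-convergence seen in unfavourable cells is reported, never retried
  silently.
* k = 2 meta-analyses are supported everywhere but estimates of τ² from
  two studies are close to noise; that fragility is a finding the
  simulation framework is designed to display, not a defect to paper over.
* MVa is undefined when all effects are exactly equal; B0 requires study
  sizes; both conditions surface as tagged statuses.
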