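"""Assess estimator performance on a simulated scenario.

Simulates 500 meta-analyses of k=5 studies with moderate heterogeneity
(tau2 = 0.03, normal effects around 0.5) and summarises each estimator's
bias, rate of zero heterogeneity estimates, CI coverage of the true effect,
and the median error-interval ratio c (estimated / true-tau2 CI width;
c = 1 is perfect interval calibration).
"""

from hetmeta import Scenario, assess_scenario

scenario = Scenario(distribution="normal", tau2_true=0.03, k=5,
                    reps=500, seed=42)
summaries = assess_scenario(scenario, methods=["DL", "DLb", "DLi", "REML",
                                               "ML", "MVa", "BP"],
                            dlb_reps=1000)

print(f"scenario: {scenario.distribution}, tau2={scenario.tau2_true}, "
      f"k={scenario.k}, reps={scenario.reps}\n")
print(f"{'method':>6s} {'bias':>8s} {'|bias|':>8s} {'%zero':>7s} "
      f"{'cover%':>7s} {'c_med':>7s}")
for s in summaries:
    print(f"{s.method:>6s} {s.mean_bias:8.4f} {s.mean_abs_bias:8.4f} "
          f"{s.pct_zero:7.1f} {s.coverage:7.1f} {s.c_median:7.3f}")

print("\n%zero is the share of replicates judged homogeneous (tau2_hat = 0):"
      "\nnote how the bootstrapped DL (DLb) flags heterogeneity far more often"
      "\nthan DL while keeping coverage close to nominal.")
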