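"""Pool per-study odds ratios with DerSimonian-Laird random effects.

Each study contributes a Woolf log odds ratio and variance from its 2x2
table (Haldane-corrected on zero cells); the moment estimator tau2
absorbs between-study heterogeneity before inverse-variance pooling.
"""

import triovar as tv

tables = {
    "study_A": tv.TwoByTwo(40, 160, 20, 180),
    "study_B": tv.TwoByTwo(25, 75, 30, 70),
    "study_C": tv.TwoByTwo(90, 310, 41, 359),
    "study_D": tv.TwoByTwo(12, 88, 0, 100),   # zero cell -> Haldane correction
}
studies = [tv.make_study(label, t) for label, t in tables.items()]
result = tv.dersimonian_laird(studies)

print(tv.forest_table(studies, result).round(3).to_string(index=False))
print(f"\npooled OR {result.pooled_or:.3f} "
      f"(95% CI {result.ci_low:.3f}-{result.ci_high:.3f}), "
      f"tau2 = {result.tau2:.4f}, Q = {result.Q:.2f}, k = {result.k}")
print("\ntau2 > 0 means the studies disagree beyond sampling noise, so the")
print("random-effects CI is wider than a fixed-effect CI would be.")
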