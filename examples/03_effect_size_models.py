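"""Fit the two carrier-encoding effect-size models on a simulated cohort.

Model 1 mirrors an unphased genotyping study (common-variant heterozygote
and homozygote indicators). Model 2 adds what sequencing trios buys:
confidently trans-phased compound heterozygotes and rare-variant
heterozygotes as their own categories. Firth penalization keeps the
rare-category estimates finite despite quasi-separation, and Tjur's R2
measures the variance in case/control status each model explains.
"""

import numpy as np

import triovar as tv

config = tv.SimulationConfig(seed=5)  # 179 trios + 26 cases + 200 controls
cohort = tv.simulate_cohort(config)
gm, ped = cohort.genotypes, cohort.pedigree

common = tuple(v.key for v in gm.variants if v.variant_id.startswith("common"))
rare = tuple(v.key for v in gm.variants if v.variant_id.startswith("rare"))
labels = tuple((v.key, v.variant_id) for v in gm.variants)
panel = tv.Panel(common=common, rare=rare, labels=labels)
enc = tv.build_carrier_encoding(gm, ped, panel)


def fit(df):
    y = (df["status"] == "case").to_numpy(float)
    cols = [c for c in df.columns if c != "status" and df[c].nunique() > 1]
    X = np.column_stack([np.ones(len(df)), df[cols].to_numpy(float)])
    return tv.logistic_fit(y, X, method="firth", names=["intercept"] + cols), y


for name, df in (("Model 1 (unphased)", enc.model1), ("Model 2 (phased)", enc.model2)):
    model_fit, y = fit(df)
    r2 = tv.tjur_r2(model_fit.fitted, y)
    print(f"\n{name}: Tjur R2 = {r2:.3f}")
    for cov, coef, (lo, hi) in zip(model_fit.names[1:],
                                   model_fit.coefficients[1:],
                                   model_fit.wald_ci()[1:]):
        print(f"  {cov:28s} OR {np.exp(coef):6.2f}  (95% CI {lo:.2f}-{hi:.2f})")

print("\nModel 2 moves trans-phased double heterozygotes out of the single-het")
print("rows into a compound-heterozygote category and adds rare carriers;")
print("its higher Tjur R2 is the variance explained recovered by phase.")
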