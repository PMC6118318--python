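import numpy as np
import pytest

import triovar as tv


@pytest.fixture(scope="session")
def small_cohort():
    """50 trios + 5 unphased cases + 60 controls with mild missingness."""
    config = tv.SimulationConfig(n_trios=50, n_case_only=5, n_controls=60,
                                 seed=7, missing_rate=0.01)
    return tv.simulate_cohort(config)


@pytest.fixture(scope="session")
def study_sized_cohort():
    """Cohort with the study's design: 179 trios, 26 unphased cases, 200 controls."""
    config = tv.SimulationConfig(seed=5)
    return tv.simulate_cohort(config)


def panel_from_cohort(cohort) -> tv.Panel:
    """Risk panel (common/rare split) read off the simulator's variant labels."""
    gm = cohort.genotypes
    common = tuple(v.key for v in gm.variants if v.variant_id.startswith("common"))
    rare = tuple(v.key for v in gm.variants if v.variant_id.startswith("rare"))
    labels = tuple((v.key, v.variant_id) for v in gm.variants)
    return tv.Panel(common=common, rare=rare, labels=labels)


@pytest.fixture(scope="session")
def study_encoding(study_sized_cohort):
    panel = panel_from_cohort(study_sized_cohort)
    return tv.build_carrier_encoding(study_sized_cohort.genotypes,
                                     study_sized_cohort.pedigree, panel)


def fit_encoding(encoding_df, method="firth"):
    y = (encoding_df["status"] == "case").to_numpy(dtype=float)
    cols = [c for c in encoding_df.columns
            if c != "status" and encoding_df[c].nunique() > 1]
    X = np.column_stack([np.ones(len(encoding_df)),
                         encoding_df[cols].to_numpy(dtype=float)])
    return tv.logistic_fit(y, X, method=method, names=["intercept"] + cols), y
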