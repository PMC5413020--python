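import numpy as np
import pandas as pd
import pytest

from tcafinger import (
    CohortDesign,
    FeatureTable,
    differential_analysis,
    generate_cohort,
    pretreat,
)

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-design cohort: 8 cases / 30 controls, Table-2-style
    planted effects, 1000 noise features, fixed seed."""
    return generate_cohort(CohortDesign(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def pretreated(default_cohort):
    table, _ = default_cohort
    return pretreat(table)


@pytest.fixture(scope="session")
def diff_results(pretreated):
    return differential_analysis(pretreated)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: no intensity noise, no missingness, no mass error,
    no background features."""
    design = CohortDesign(
        seed=7, intensity_cv=0.0, missing_rate=0.0, mass_error_sd=0.0,
        n_noise_features=0,
    )
    return generate_cohort(design)


def make_table(intensities, classes=None, mz=None):
    """Small hand-built FeatureTable for unit tests."""
    intens = np.asarray(intensities, dtype=float)
    n_feat, n_samp = intens.shape
    if classes is None:
        half = n_samp // 2
        classes = ["case"] * half + ["control"] * (n_samp - half)
    fids = [f"f{i}" for i in range(n_feat)]
    sids = [f"s{j}" for j in range(n_samp)]
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 200, n_feat),
            "rt_seconds": np.linspace(60, 600, n_feat),
            "polarity": "negative",
        },
        index=pd.Index(fids, name="feature_id"),
    )
    samples = pd.DataFrame(
        {
            "class": classes,
            "family": ["F1" if c == "case" else "control" for c in classes],
            "age": 10.0,
            "sex": "F",
        },
        index=pd.Index(sids, name="sample_id"),
    )
    return FeatureTable(
        features, samples, pd.DataFrame(intens, index=features.index, columns=samples.index)
    )
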