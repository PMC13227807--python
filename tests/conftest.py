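import numpy as np
import pandas as pd
import pytest

from seromir import cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest study-like cohort shared by read-only tests."""
    cfg = cohort.gse120584_like_config(
        n_ad=120, n_control=80, n_features=300, seed=42
    )
    return cohort.generate_cohort(cfg)


def make_pheno(n_ad, n_control, seed=0):
    """Phenotype table with the default group-wise covariate imbalance."""
    rng = np.random.default_rng(seed)
    n = n_ad + n_control
    diagnosis = ["AD"] * n_ad + ["control"] * n_control
    age = np.r_[rng.normal(80, 6, n_ad), rng.normal(71, 6, n_control)].clip(55, 95)
    sex = np.where(rng.random(n) < 0.6, "female", "male")
    apoe = rng.choice(3, size=n, p=[0.6, 0.33, 0.07])
    return pd.DataFrame(
        {"diagnosis": diagnosis, "age": age, "sex": sex, "apoe4": apoe},
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id"),
    )


def make_expr(values, feature_ids=None, sample_ids=None):
    values = np.asarray(values, float)
    feature_ids = feature_ids or [f"m{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(values.shape[1])]
    return pd.DataFrame(
        values,
        index=pd.Index(feature_ids, name="feature_id"),
        columns=sample_ids,
    )
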