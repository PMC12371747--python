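import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ntcpval import ntcp, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=674) with features and true-model lp."""
    cfg = synthetic.GeneratorConfig(n=674, seed=20240901)
    records, y = synthetic.generate_cohort(cfg)
    feats = [
        ntcp.featurize(
            r,
            dose_representation=cfg.dose_representation,
            smg_combination=cfg.smg_combination,
        )
        for r in records
    ]
    lp = ntcp.linear_predictors(cfg.true_model, feats)
    return cfg, records, feats, np.asarray(y, float), lp


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
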