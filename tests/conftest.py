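import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from ldsig import ExpressionStudy, SynthConfig, gen_mouse_study

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def small_config(**overrides) -> SynthConfig:
    """A fast, down-scaled generator config for unit tests."""
    base = dict(
        seed=0,
        n_genes=600,
        n_baseline_signature=40,
        n_ld_response={"sensitive": 60, "resistant": 20},
        n_thresholded=10,
        n_plateau=12,
        n_opposite=8,
        n_patients=80,
        n_cohort_genes=120,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    cfg = small_config(seed=11)
    return gen_mouse_study(cfg)


@pytest.fixture()
def tiny_study():
    """A hand-built 2-gene x 4-sample study for exact-arithmetic tests."""
    meta = pd.DataFrame(
        {
            "strain": ["sensitive", "sensitive", "resistant", "resistant"],
            "tissue": ["mammary"] * 4,
            "dose": ["sham"] * 4,
            "time": ["early"] * 4,
            "replicate": [1, 2, 1, 2],
        },
        index=["s1", "s2", "r1", "r2"],
    )
    values = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
    return ExpressionStudy(gene_ids=["Gena", "Genb"], values=values, sample_meta=meta)
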