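import numpy as np
import pytest

import episcreen as ep


@pytest.fixture(scope="session")
def xor_cohort():
    """n=500 cohort with a strong embedded pure pairwise interaction."""
    prev = dict(ep.TABLE1_PREVALENCES)
    prev["pse"] = prev["ses_low"] = 0.5
    spec = ep.CohortSpec(n=500, beta_age=0.0, prevalences=prev, baseline=0.5,
                         penetrance=[ep.xor_penetrance(delta=0.4)], seed=3)
    return ep.generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """n=233 cohort with no effects of any kind."""
    spec = ep.CohortSpec(n=233, beta_age=0.0, seed=17)
    return ep.generate_cohort(spec)


@pytest.fixture(scope="session")
def confounded_cohort():
    """n=617 cohort with the default age->outcome confounding."""
    return ep.generate_cohort(ep.CohortSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
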