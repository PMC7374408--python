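import numpy as np
import pytest
from hypothesis import settings

import gaitbelief as gb

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")
from gaitbelief.synthetic_cohort import GeneratorSpec, generate_cohort


@pytest.fixture(scope="session")
def default_spec():
    return GeneratorSpec(seed=7)


@pytest.fixture(scope="session")
def cohort(default_spec):
    """Default synthetic cohort: 31 NP + 41 OA, 22 post-op, d=2 on 6 modes."""
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def config(default_spec):
    return default_spec.pipeline_config()


@pytest.fixture(scope="session")
def subjects(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def proms(cohort):
    return cohort[1]


@pytest.fixture(scope="session")
def truth(cohort):
    return cohort[2]


@pytest.fixture(scope="session")
def pca_models(subjects, config):
    return gb.fit_all_pca(subjects, config)


@pytest.fixture(scope="session")
def feature_matrix(pca_models, subjects, config):
    return gb.build_feature_matrix(pca_models, subjects, "baseline", variables=config.variables)


@pytest.fixture(scope="session")
def labels(subjects):
    return [s.cohort for s in subjects]


def random_boe(rng) -> gb.BodyOfEvidence:
    masses = rng.dirichlet(np.ones(3))
    return gb.BodyOfEvidence(*masses)
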