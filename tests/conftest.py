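import pytest

from mhei.simulate import CohortSpec, make_cohort, make_food_db


@pytest.fixture(scope="session")
def db():
    return make_food_db(seed=1)


@pytest.fixture(scope="session")
def near_max_cohort(db):
    spec = CohortSpec(n_subjects=8, profile="near_max", seed=1)
    return make_cohort(spec, db)


@pytest.fixture(scope="session")
def random_cohort(db):
    spec = CohortSpec(n_subjects=20, profile="random", days=2, seed=7)
    return make_cohort(spec, db)
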