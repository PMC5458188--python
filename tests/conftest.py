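import numpy as np
import pytest

from ccassoc import datasets


@pytest.fixture(scope="session")
def variants():
    return datasets.study_variants()


@pytest.fixture(scope="session")
def genotype_tables():
    return datasets.genotype_tables()


@pytest.fixture(scope="session")
def covariate_tables():
    return datasets.covariate_tables()


@pytest.fixture(scope="session")
def table_cohort():
    """Cohort reproducing the published per-variant genotype counts."""
    return datasets.cohort_from_genotype_tables()


@pytest.fixture(scope="session")
def activity_cohort(variants):
    """Cohort reproducing the published rs73013281 x physical-activity
    joint counts (carrier vs CC by stratum)."""
    return datasets.cohort_from_joint_counts(
        variants["rs73013281"],
        "physical_activity",
        datasets.stratified_joint_counts()["physical_activity"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
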