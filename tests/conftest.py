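import numpy as np
import pandas as pd
import pytest

from cortexmeth import simcohort as sc


@pytest.fixture(scope="session")
def profiles():
    """600 probes, 60 planted discriminating sites per cell type."""
    return sc.make_reference_profiles(600, 3, 60, separation=0.5, seed=11)


@pytest.fixture(scope="session")
def profiles_rich():
    """Enough planted sites (120/type) to build a full 100-site panel."""
    return sc.make_reference_profiles(1200, 3, 120, separation=0.5, seed=12)


@pytest.fixture(scope="session")
def reference(profiles_rich):
    beta, labels = sc.make_reference_samples(profiles_rich, n_per_type=12, seed=13)
    return beta, labels


@pytest.fixture(scope="session")
def cohort(profiles):
    """Default two-region cohort: 120 donors, pathology-coupled DLPFC."""
    return sc.make_cohort(profiles, n_donors=120, seed=21)


@pytest.fixture(scope="session")
def null_cohort(profiles):
    """Cohort with no proportion coupling and no planted effects."""
    zero = {c: 0.0 for c in sc.CELLTYPES}
    return sc.make_cohort(profiles, n_donors=120, proportion_coupling=zero,
                          seed=22)


def attach_proportions(cohort_obj):
    """Phenotypes augmented with the two model proportion covariates."""
    pheno = cohort_obj.phenotypes.copy()
    pheno["prop_NeuN+"] = cohort_obj.true_proportions["NeuN+"]
    pheno["prop_DN"] = cohort_obj.true_proportions["DN"]
    return pheno
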