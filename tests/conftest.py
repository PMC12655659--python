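import numpy as np
import pytest

from radpk import (CovariateSet, ThetaSet, VarianceSpec, final_theta,
                   final_variance, generate_study)


@pytest.fixture(scope="session")
def theta() -> ThetaSet:
    return final_theta()


@pytest.fixture(scope="session")
def variance() -> VarianceSpec:
    return final_variance()


@pytest.fixture(scope="session")
def patient_cov() -> CovariateSet:
    return CovariateSet(age=31, cml=1, sex="male", weight=65, height=168)


@pytest.fixture(scope="session")
def hv_cov() -> CovariateSet:
    return CovariateSet(age=31, cml=0, sex="male", weight=71, height=173)


@pytest.fixture(scope="session")
def cl_only_variance(variance) -> VarianceSpec:
    """Variability restricted to clearance IIV + residual error (the
    configuration used by the recovery and SCM experiments)."""
    return variance.replace(omega_mtt=0.0, omega_n=0.0, omega_iov=0.0)


@pytest.fixture(scope="session")
def study_table(theta, variance):
    """One synthetic study under the full published variability."""
    return generate_study(theta, variance, seed=20240901)


@pytest.fixture(scope="session")
def study_table_cl_only(theta, cl_only_variance):
    return generate_study(theta, cl_only_variance, seed=20240902)
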