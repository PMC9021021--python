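import numpy as np
import pytest

from normcharts import GeneralizedGammaChart, simulate


@pytest.fixture(scope="session")
def gmv_truth():
    return simulate.preset("gmv_like")


@pytest.fixture(scope="session")
def reference_cohort(gmv_truth):
    """20 studies x 200 scans from the GMV-like truth, fixed seed."""
    return simulate.make_reference_cohort(
        gmv_truth, n_studies=20, n_per_study=200, seed=0)


@pytest.fixture(scope="session")
def fitted_chart(gmv_truth, reference_cohort):
    return GeneralizedGammaChart(spec=gmv_truth.spec).fit(reference_cohort)


@pytest.fixture(scope="session")
def small_cohort(gmv_truth):
    """A quicker 6 x 80 cohort for tests that refit repeatedly."""
    return simulate.make_reference_cohort(
        gmv_truth, n_studies=6, n_per_study=80, seed=1)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.Philox(12345))
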