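import numpy as np
import pytest

from weibinc import AgeIncidenceSeries, CohortSpec, WeibullParams, simulate_counts

BINS = np.arange(86)


@pytest.fixture(scope="session")
def weibull_truth():
    """Default ground truth: lifetime cumulative incidence about 2.5%."""
    return WeibullParams(P=0.05, lambda_=90.0, k=6.0)


@pytest.fixture(scope="session")
def noiseless_series(weibull_truth):
    spec = CohortSpec(family="weibull", params=weibull_truth, noiseless=True)
    return simulate_counts(spec)


@pytest.fixture(scope="session")
def noisy_series(weibull_truth):
    spec = CohortSpec(family="weibull", params=weibull_truth, seed=11)
    return simulate_counts(spec)


@pytest.fixture()
def toy_series():
    return AgeIncidenceSeries.from_frequencies("toy", [0, 1, 2], [0.1, 0.2, 0.0])
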