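import warnings

import pytest

from hwsense.synthetic_data import SyntheticConfig, generate_dataset

# statsmodels emits benign IterationLimit/RuntimeWarnings while profiling alpha
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic dataset shared read-only across the suite."""
    return generate_dataset(seed=7)


@pytest.fixture(scope="session")
def quick_dataset():
    """Smaller dataset (short climatology) for fast structural checks."""
    return generate_dataset(SyntheticConfig(seed=7, baseline_years=30))
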