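import pandas as pd
import pytest

import healthreserves as hr


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Mid-sized cohort under the default calibrated configuration."""
    return hr.generate_cohort(hr.GeneratorConfig(n_individuals=4000, seed=7))


@pytest.fixture(scope="session")
def analysis_table(default_cohort) -> pd.DataFrame:
    included, _ = hr.apply_exclusions(default_cohort)
    return hr.build_analysis_table(included)


@pytest.fixture(scope="session")
def large_default_cohort() -> pd.DataFrame:
    """n = 20,000 under defaults, for marginal-calibration checks."""
    return hr.generate_cohort(hr.GeneratorConfig(n_individuals=20000, seed=0))
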