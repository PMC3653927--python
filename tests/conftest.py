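import numpy as np
import pandas as pd
import pytest

from willowbirds.io_design import MODEL_COVARIATES, CountArray, CovariateTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def small_counts():
    """2 species x 3 points x 2 years x 3 visits toy count array."""
    rng = np.random.default_rng(7)
    values = rng.poisson(1.2, size=(2, 3, 2, 3))
    return CountArray(
        values=values,
        species=["sp_a", "sp_b"],
        points=["P1", "P2", "P3"],
        years=[2005, 2006],
        visits=[1, 2, 3],
    )


@pytest.fixture
def standard_covariates():
    """Standardized 5-point covariate table for the four model columns."""
    rng = np.random.default_rng(11)
    raw = rng.normal(size=(5, len(MODEL_COVARIATES)))
    raw = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
    frame = pd.DataFrame(
        raw, columns=list(MODEL_COVARIATES), index=[f"P{i}" for i in range(5)]
    )
    return CovariateTable(frame=frame, standardized=True)
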