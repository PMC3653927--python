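import numpy as np
import pandas as pd

from willowbirds.io_design import MODEL_COVARIATES, CovariateTable


def make_standardized_table(values: np.ndarray, points=None) -> CovariateTable:
    """Standardize arbitrary raw covariate values into a model-ready table."""
    values = np.asarray(values, dtype=float)
    std = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    points = points or [f"P{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(std, columns=list(MODEL_COVARIATES), index=points)
    return CovariateTable(frame=frame, standardized=True)


def std_view(covariates: CovariateTable) -> CovariateTable:
    """Model-ready table from a generator table carrying *_std columns."""
    std_cols = [f"{c}_std" for c in MODEL_COVARIATES]
    frame = covariates.frame[std_cols].rename(
        columns=dict(zip(std_cols, MODEL_COVARIATES))
    )
    return CovariateTable(frame=frame, standardized=True)
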