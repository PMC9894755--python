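import warnings

import numpy as np
import pandas as pd
import pytest

from vagmet.cohort_io import CohortMetadata, MetaboliteMatrix
from vagmet.preprocess import log10_transform, min_impute, robust_standardize
from vagmet.simulate import SimulationConfig, generate_cohort

warnings.filterwarnings("ignore", message="X does not have valid feature names")


@pytest.fixture(scope="session")
def cohort():
    """Default study-shaped synthetic cohort (232 samples, 300 features)."""
    return generate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def standardized(cohort):
    matrix, *_ = cohort
    std, _ = robust_standardize(log10_transform(matrix))
    return std


@pytest.fixture(scope="session")
def complete(standardized):
    full, _ = min_impute(standardized)
    return full


def toy_matrix(values, scale_tag="raw"):
    """MetaboliteMatrix from a 2-D array; NaN entries become masked."""
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    return MetaboliteMatrix(
        [f"s{i}" for i in range(n)],
        [f"m{j}" for j in range(f)],
        values,
        np.isnan(values),
        scale_tag,
    )


def toy_metadata(outcomes, race=None, gab=None, **extra):
    n = len(outcomes)
    if gab is None:
        gab = [33.0 if o == "sPTB" else 39.0 for o in outcomes]
    df = pd.DataFrame(
        {
            "outcome": list(outcomes),
            "gab_weeks": gab,
            "race": race if race is not None else ["Black"] * n,
            **extra,
        },
        index=[f"s{i}" for i in range(n)],
    )
    return CohortMetadata(df)
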