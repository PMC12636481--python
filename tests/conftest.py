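import numpy as np
import pandas as pd
import pytest

from proteomediate.io import ProteinMatrix
from proteomediate.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_samples=150, n_analytes=60, n_true_mediators=3,
                     module_spec=((10, 0.6),), seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_matrix(values: np.ndarray, sample_ids=None, analyte_ids=None,
                row_flags=None, col_flags=None, transform="raw") -> ProteinMatrix:
    """Build a ProteinMatrix from a plain array for unit tests."""
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    analyte_ids = analyte_ids or [f"a{j}" for j in range(p)]
    meta = pd.DataFrame(
        {"analyte_id": analyte_ids, "target": analyte_ids, "gene": analyte_ids,
         "col_check": col_flags or ["PASS"] * p}
    ).set_index("analyte_id")
    return ProteinMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=analyte_ids),
        analyte_meta=meta,
        row_check=pd.Series(row_flags or ["PASS"] * n, index=sample_ids),
        transform=transform,
    )
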