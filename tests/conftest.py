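import numpy as np
import pandas as pd
import pytest

from connectome_cbr import DesignMatrix, edge_index_for, hcp_like_spec
from connectome_cbr.synthetic import generate_cohort


def make_design(values: np.ndarray, subject_ids=None) -> DesignMatrix:
    """Wrap a raw (n, m) array as a DesignMatrix with synthetic labels."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    # smallest parcellation whose upper triangle holds >= m edges
    n_rois = 2
    while n_rois * (n_rois - 1) // 2 < m:
        n_rois += 1
    edges = edge_index_for([f"R{i}" for i in range(n_rois)])[:m]
    if subject_ids is None:
        subject_ids = [f"S{j:03d}" for j in range(n)]
    return DesignMatrix(values=values, edge_index=edges, subject_order=tuple(subject_ids))


def make_cohort_table(b: np.ndarray, attribute: str = "age", sex=None) -> pd.DataFrame:
    n = len(b)
    if sex is None:
        sex = np.where(np.arange(n) % 2 == 0, "female", "male")
    return pd.DataFrame(
        {"subject_id": [f"S{j:03d}" for j in range(n)], "sex": sex, attribute: b}
    )


@pytest.fixture
def small_signal_cohort():
    """A 200-subject, 20-ROI cohort with 5 age-signal edges at rho = 0.5."""
    spec = hcp_like_spec(
        n_subjects=200, n_rois=20, n_signal_edges=5, planted_rho=0.5, seed=7
    )
    return generate_cohort(spec)
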