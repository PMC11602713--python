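import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cadrdvp.containers import IntensityMatrix

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def build_matrix(values, proteins=None, sample_meta=None, scale="log2"):
    """Assemble an IntensityMatrix from a 2-D array and metadata rows.

    ``sample_meta`` is a list of (sample_id, individual, cohort, cell_type,
    replicate) tuples; defaults to one healthy keratinocyte replicate per
    column.
    """
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    proteins = proteins or [f"P{i}" for i in range(1, n_prot + 1)]
    if sample_meta is None:
        sample_meta = [(f"s{j}", f"ind{j}", "healthy", "keratinocyte", 1)
                       for j in range(1, n_samp + 1)]
    samples = pd.DataFrame(
        sample_meta,
        columns=["sample_id", "individual", "cohort", "cell_type", "replicate"],
    ).set_index("sample_id")
    grid = pd.DataFrame(values, index=pd.Index(proteins, name="protein"),
                        columns=samples.index)
    return IntensityMatrix(values=grid, samples=samples, scale=scale)


def two_cohort_meta(n_per_cohort, cell_type="keratinocyte",
                    cohorts=("healthy", "TEN")):
    meta = []
    for cohort in cohorts:
        for i in range(1, n_per_cohort + 1):
            sid = f"{cohort}{i}"
            meta.append((sid, f"{cohort}_ind{i}", cohort, cell_type, 1))
    return meta


@pytest.fixture
def matrix_factory():
    return build_matrix
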