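import numpy as np
import pandas as pd
import pytest

from metasig import Cohort, SimulationSpec, simulate_study


def make_cohort(values, labels, gene_ids=None, cohort_id="c1", role="training"):
    """Small Cohort from a nested list (genes x samples) and 0/1 labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = gene_ids or [f"G{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    expr = pd.DataFrame(values, index=genes, columns=samples)
    return Cohort(
        id=cohort_id,
        expression=expr,
        labels=pd.Series(list(labels), index=samples),
        role=role,
    )


@pytest.fixture
def tiny_cohort():
    # 3 genes x 4 samples, first two samples are cases
    return make_cohort(
        [[3, 4, 1, 2], [5, 6, 7, 8], [1, 1, 2, 2]],
        [1, 1, 0, 0],
    )


@pytest.fixture(scope="session")
def default_study():
    """One simulated study at the default design, shared across tests."""
    return simulate_study(SimulationSpec(rng_seed=11))


@pytest.fixture(scope="session")
def strong_study():
    """Strong-signal study (|delta| = 3) for end-to-end separation checks."""
    return simulate_study(SimulationSpec(delta_scale=3.0, rng_seed=11))
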