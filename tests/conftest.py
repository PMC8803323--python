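import numpy as np
import pandas as pd
import pytest

from mclsubtype.clustering import nmf_consensus
from mclsubtype.synthetic import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def reference_spec():
    return default_cohort_spec(seed=1)


@pytest.fixture(scope="session")
def reference_cohort(reference_spec):
    """One 134-sample / 35-lesion / 4-cluster draw (matrix, ccf, metadata)."""
    return generate_cohort(reference_spec)


@pytest.fixture(scope="session")
def reference_consensus(reference_cohort):
    """Full consensus run on the reference cohort (K=2..10, 50 restarts)."""
    matrix, _, _ = reference_cohort
    return nmf_consensus(matrix, range(2, 11), n_restarts=50, seed=1)


@pytest.fixture
def toy_structure():
    """Tight 3-residue cluster (~2 A apart) plus one far outlier, 8 residues."""
    coords = pd.DataFrame(
        {
            "x": [0.0, 2.0, 1.0, 40.0, 10.0, 20.0, 30.0, 50.0],
            "y": [0.0, 0.0, 2.0, 0.0, 5.0, 5.0, 5.0, 5.0],
            "z": [0.0] * 8,
        },
        index=pd.Index(range(1, 9), name="Residue"),
    )
    return coords
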