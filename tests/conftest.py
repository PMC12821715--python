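import numpy as np
import pandas as pd
import pytest

from arspattern.data_io import IntensityMatrix, reference_design
from arspattern.normalization import normalize
from arspattern.synthetic_data import SyntheticSpec, generate_experiment


@pytest.fixture(scope="session")
def design():
    return reference_design()


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(42)
    vals = 10.0 ** rng.normal(6, 0.5, size=(20, 21))
    design = reference_design()
    return IntensityMatrix(
        pd.DataFrame(vals, index=[f"P{i:02d}" for i in range(20)], columns=design.sample_ids)
    )


@pytest.fixture(scope="session")
def planted_experiment():
    """One synthetic experiment with all three planted classes (seed fixed)."""
    spec = SyntheticSpec(
        n_proteins=600,
        n_arsr_dependent=20,
        arsr_fold=4.0,
        n_arsenite_responsive=20,
        arsenite_fold=3.0,
        n_inverse=10,
        inverse_fold=3.0,
        noise_cv=0.2,
        dropout_rate=0.05,
        seed=11,
    )
    matrix, design, truth = generate_experiment(spec)
    return spec, matrix, design, truth


@pytest.fixture(scope="session")
def planted_normalized(planted_experiment):
    _, matrix, design, _ = planted_experiment
    return normalize(matrix), design
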