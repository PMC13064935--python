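import numpy as np
import pandas as pd
import pytest

import coexkit as ck


def make_matrix(values, genes=None, samples=None, unit=ck.Unit.LOG_TPM):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ck.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_log_matrix(rng):
    """5 genes x 8 samples of random log-expression."""
    return make_matrix(rng.normal(2.0, 1.0, size=(5, 8)))


@pytest.fixture(scope="session")
def demo_cohort():
    """Small two-program synthetic cohort shared across tests."""
    spec = ck.default_demo_spec(seed=7, n_samples=120, n_genes=300)
    matrix, alterations, annotations, truth = ck.generate_cohort(spec)
    return {"spec": spec, "matrix": matrix, "alterations": alterations,
            "annotations": annotations, "truth": truth,
            "log": ck.log_transform(matrix)}
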