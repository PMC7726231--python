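import numpy as np
import pandas as pd
import pytest

from degpath.matrix_io import ExpressionMatrix, LOG2_CENTERED, RAW, StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_raw_matrix(rng):
    """5 genes x 4 samples, strictly positive raw intensities with quality."""
    values = pd.DataFrame(
        rng.lognormal(5.0, 1.0, size=(5, 4)),
        index=[f"G{i}" for i in range(5)],
        columns=[f"S{i}" for i in range(4)],
    )
    quality = pd.DataFrame(1.0, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, quality, RAW)


@pytest.fixture
def two_group_design():
    return StudyDesign(
        {"C1": "ctrl", "C2": "ctrl", "T1": "trt", "T2": "trt"},
        control_label="ctrl", treatment_label="trt",
    )


def make_log2_matrix(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df, None, LOG2_CENTERED)
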