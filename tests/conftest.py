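import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from bepanel import (
    ExpressionMatrix,
    SampleAnnotation,
    SyntheticConfig,
    generate_cohort,
)


@pytest.fixture
def small_cohort():
    """30/30 cohort, 200 genes, 10 planted at 1.5 log2 units, sigma 1."""
    cfg = SyntheticConfig(
        n_neg=30, n_pos=30, n_genes=200, n_discriminative=10,
        effect_size=1.5, noise_sd=1.0, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def separable_cohort():
    """Two well-separated Gaussian clusters: 20+20 samples, 3 genes, 6-sigma shift."""
    cfg = SyntheticConfig(
        n_neg=20, n_pos=20, n_genes=3, n_discriminative=3,
        effect_size=6.0, noise_sd=1.0, seed=5,
    )
    return generate_cohort(cfg)


def toy_matrix(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def toy_annotation(labels, samples=None) -> SampleAnnotation:
    samples = samples or [f"s{j}" for j in range(len(labels))]
    names = ["negative" if l == 0 else "positive" if l == 1 else "third" for l in labels]
    return SampleAnnotation(pd.DataFrame({"label": names}, index=samples))
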