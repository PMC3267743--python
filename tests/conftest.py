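import numpy as np
import pandas as pd
import pytest

from ctnorm import CtMatrix, SampleAnnotation


@pytest.fixture
def toy3() -> CtMatrix:
    """3 genes x 2 samples with one censored cell; restricted set = {g1, g2}."""
    frame = pd.DataFrame(
        {"s1": [20.0, 24.0, 30.0], "s2": [22.0, 26.0, np.nan]},
        index=["g1", "g2", "g3"],
    )
    return CtMatrix(frame)


@pytest.fixture
def two_group_annotations():
    return [
        SampleAnnotation("a1", "brain"),
        SampleAnnotation("a2", "brain"),
        SampleAnnotation("a3", "brain"),
        SampleAnnotation("b1", "placenta"),
        SampleAnnotation("b2", "placenta"),
        SampleAnnotation("b3", "placenta"),
    ]


def random_ct_matrix(
    rng: np.random.Generator,
    n_genes: int = 12,
    n_samples: int = 6,
    nd_fraction: float = 0.0,
    low: float = 16.0,
    high: float = 33.0,
    ct_max: float = 40.0,
) -> CtMatrix:
    """Random matrix with explicit (not near-threshold) ND cells planted."""
    values = rng.uniform(low, high, size=(n_genes, n_samples))
    if nd_fraction > 0:
        mask = rng.random(values.shape) < nd_fraction
        # keep at least one fully numeric gene per sample so means exist
        mask[0, :] = False
        values = np.where(mask, np.nan, values)
    frame = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return CtMatrix(frame, ct_max=ct_max)
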