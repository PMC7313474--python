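import numpy as np
import pandas as pd
import pytest

from switchscan import ExpressionMatrix


@pytest.fixture
def tiny_em() -> ExpressionMatrix:
    """3 genes x 4 samples, 2 case / 2 control, log2 scale."""
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.uniform(4, 10, size=(3, 4)),
        index=["G1", "G2", "G3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    cond = {"S1": "case", "S2": "case", "S3": "control", "S4": "control"}
    return ExpressionMatrix(data, cond)


def make_em(values: np.ndarray, n_case: int, n_control: int,
            genes=None) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with simple labels."""
    n_genes, n_samples = values.shape
    assert n_samples == n_case + n_control
    samples = [f"case{i}" for i in range(n_case)] + [
        f"ctrl{i}" for i in range(n_control)
    ]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cond = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), cond
    )
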