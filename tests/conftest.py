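import numpy as np
import pytest

from crosstx.config import RunConfig
from crosstx.io import ExpressionDataset


@pytest.fixture
def config():
    return RunConfig(seed=0)


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, 2 case + 2 control, log2 scale."""
    return ExpressionDataset(
        dataset_id="tiny",
        tissue="brain",
        organism="human",
        platform_id="P1",
        scale="log2",
        genes=["A", "B", "C"],
        samples=["s1", "s2", "s3", "s4"],
        values=np.array(
            [[5.0, 5.2, 3.0, 3.1], [2.0, 2.1, 2.0, 2.2], [1.0, 1.1, 4.0, 4.2]]
        ),
        group={"s1": "case", "s2": "case", "s3": "control", "s4": "control"},
    )


def make_dataset(values, scale="log2", organism="human", tissue="brain",
                 n_case=None, dataset_id="ds"):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if n_case is None:
        n_case = n_samples // 2
    samples = [f"s{i}" for i in range(n_samples)]
    return ExpressionDataset(
        dataset_id=dataset_id,
        tissue=tissue,
        organism=organism,
        platform_id="P",
        scale=scale,
        genes=[f"g{i}" for i in range(n_genes)],
        samples=samples,
        values=values,
        group={s: ("case" if i < n_case else "control") for i, s in enumerate(samples)},
    )
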