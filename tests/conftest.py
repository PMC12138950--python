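import numpy as np
import pandas as pd
import pytest

from metaregnet.dataio import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, platform="intensity", samples=None, genes=None,
                subtypes=None, batches=None, cohort="c1"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    ann = None
    if subtypes is not None or batches is not None:
        ann = pd.DataFrame(index=samples)
        ann["cohort"] = cohort
        if subtypes is not None:
            ann["subtype"] = subtypes
        if batches is not None:
            ann["batch"] = batches
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            platform, ann)


@pytest.fixture
def toy_matrix():
    return make_matrix([[1.0, 2.0], [3.0, 4.0]])
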