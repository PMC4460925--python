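import numpy as np
import pandas as pd
import pytest

from funpat.core import ExpressionSeries, SampleDesign


def make_design(n_times=5, n_reps=2, conditions=("control", "treatment")):
    rows = []
    for cond in conditions:
        for t in range(n_times):
            for r in range(1, n_reps + 1):
                rows.append((f"{cond}_t{t}_r{r}", cond, float(t), r))
    tab = pd.DataFrame([(c, t, r) for _, c, t, r in rows],
                       index=pd.Index([s for s, *_ in rows], name="sample"),
                       columns=["condition", "time", "replicate"])
    return SampleDesign(tab)


def make_expression(design, values=None, n_genes=4, rng=None, scale="normalized"):
    rng = rng or np.random.default_rng(0)
    if values is None:
        values = rng.uniform(1, 100, size=(n_genes, len(design.samples)))
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionSeries(pd.DataFrame(values, index=genes, columns=design.samples),
                            scale=scale)


@pytest.fixture
def design():
    return make_design()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
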