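import numpy as np
import pandas as pd
import pytest

from diffconn.io import ExpressionStudy


def make_design(n_if=2, n_id=2):
    rows = []
    for group, n in (("IF", n_if), ("ID", n_id)):
        for p in range(n):
            pid = f"{group}{p + 1:02d}"
            for tp in ("pre", "post"):
                rows.append((f"{pid}_{tp}", pid, group, tp))
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "group", "timepoint"]
    ).set_index("sample_id")


def make_study(n_genes=5, n_if=2, n_id=2, seed=0):
    design = make_design(n_if, n_id)
    rng = np.random.default_rng(seed)
    matrix = pd.DataFrame(
        rng.normal(8, 1, size=(n_genes, len(design))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=design.index,
    )
    return ExpressionStudy(matrix, design)


@pytest.fixture
def small_study():
    return make_study()


@pytest.fixture
def table1():
    from diffconn.io import load_table1

    return load_table1()
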