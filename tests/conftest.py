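import numpy as np
import pandas as pd
import pytest

from revkit.de import CountMatrix, DESignature
from revkit.synthetic import SimulationParams, make_truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def desk_params():
    """Desk-scale study conditions with a sizeable planted reversal signal."""
    return SimulationParams(n_genes=2000, frac_disease_de=0.3, reversal_prob=0.5, seed=11)


@pytest.fixture(scope="session")
def desk_truth(desk_params):
    return make_truth(desk_params)


@pytest.fixture
def toy_counts():
    """4 genes x 4 samples, 2 treated vs 2 vehicle."""
    counts = pd.DataFrame(
        {
            "T1": [10, 100, 0, 5],
            "T2": [12, 110, 0, 6],
            "V1": [11, 95, 1, 50],
            "V2": [9, 105, 0, 55],
        },
        index=["G1", "G2", "G3", "G4"],
    )
    groups = pd.Series(
        ["treated", "treated", "vehicle", "vehicle"], index=counts.columns, name="group"
    )
    return CountMatrix(counts=counts, groups=groups)


def make_signature(label, records):
    """records: list of (gene, logfc, qvalue) or (gene, logfc, pvalue, qvalue)."""
    rows = []
    for rec in records:
        if len(rec) == 3:
            gene, logfc, q = rec
            p = q
        else:
            gene, logfc, p, q = rec
        rows.append({"gene": gene, "logfc": logfc, "pvalue": p, "qvalue": q})
    table = pd.DataFrame(rows).set_index("gene")
    return DESignature(label=label, table=table)


@pytest.fixture
def make_sig():
    return make_signature
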