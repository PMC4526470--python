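import numpy as np
import pandas as pd
import pytest

from refstab import CtTable, RelQuantMatrix, evaluate_all, simulate_ct, soybean_preset


def make_design(samples, groups=None, bio_rep=None):
    """Design frame for a list of samples (default: one 'control' group)."""
    n = len(samples)
    return pd.DataFrame(
        {
            "group": groups if groups is not None else ["control"] * n,
            "bio_rep": bio_rep if bio_rep is not None else list(range(1, n + 1)),
        },
        index=pd.Index(samples, name="sample"),
    )


def make_table(cq_rows, genes, samples, groups=None):
    """CtTable from a nested list of Cq values (NaN = missing)."""
    df = pd.DataFrame(cq_rows, index=genes, columns=samples, dtype=float)
    return CtTable(df, make_design(samples, groups))


def make_rq(log2_rows, genes, samples, groups=None):
    """RelQuantMatrix directly from log2 quantities (for method unit tests)."""
    x = pd.DataFrame(log2_rows, index=genes, columns=samples, dtype=float)
    return RelQuantMatrix(
        q=np.exp2(x),
        reference_cq=pd.Series(0.0, index=x.index),
        amplification_factor=pd.Series(2.0, index=x.index),
        design=make_design(samples, groups),
    )


def random_table(rng, n_genes=4, n_samples=5, groups=None):
    """Random complete Cq table in a realistic 18-30 cycle range."""
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    base = rng.uniform(18, 28, size=n_genes)
    cq = base[:, None] + rng.normal(0, 0.8, size=(n_genes, n_samples))
    return make_table(cq, genes, samples, groups)


@pytest.fixture(scope="session")
def preset_table():
    table, truth = simulate_ct(soybean_preset(seed=1))
    return table, truth


@pytest.fixture(scope="session")
def preset_eval(preset_table):
    table, _ = preset_table
    return evaluate_all(table)
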