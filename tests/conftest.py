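import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import comicsim as c

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cell():
    """A 30-gene, 10-miRNA synthetic cell with sparse sites."""
    spec = c.SynthSpec(n_genes=30, n_mirnas=10, sites_per_gene_mean=5, seed=7)
    return c.make_cell(spec)


@pytest.fixture()
def toy_table():
    """Two genes, two miRNAs, three sites."""
    return c.make_table([
        ("mir-a", "gene-1", 100, -1.0),
        ("mir-a", "gene-2", 200, -0.5),
        ("mir-b", "gene-1", 300, -2.0),
    ])


@pytest.fixture()
def toy_profile():
    return c.CellProfile(
        mirna_counts=pd.Series({"mir-a": 60, "mir-b": 40}),
        mrna_counts=pd.Series({"gene-1": 30, "gene-2": 20}),
        mirna_pool=100,
        mrna_pool=50,
    )


def single_site_cell(prob: float = 1.0, n_molecules: int = 1,
                     n_mirna: int = 1):
    """One gene, one miRNA, one site with the given binding probability."""
    score = float(np.log2(1.0 - prob)) if prob < 1 else -60.0
    table = c.make_table([("mir-x", "gene-1", 100, score)])
    profile = c.CellProfile(
        mirna_counts=pd.Series({"mir-x": n_mirna}),
        mrna_counts=pd.Series({"gene-1": n_molecules}),
        mirna_pool=n_mirna,
        mrna_pool=n_molecules,
    )
    return profile, table
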