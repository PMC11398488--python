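import numpy as np
import pandas as pd
import pytest

from codonadapt import synthetic
from codonadapt.optimality import WobbleRuleSet
from codonadapt.trna_quant import AbundanceTable


@pytest.fixture(scope="session")
def rules() -> WobbleRuleSet:
    return WobbleRuleSet.default()


@pytest.fixture(scope="session")
def small_panel():
    """Default-scale tRNA panel: genes, raw counts, truth."""
    return synthetic.generate_trna_panel(seed=11)


@pytest.fixture(scope="session")
def small_library():
    """300-gene CDS library with 5 planted usage clusters."""
    return synthetic.generate_cds_library(n_genes=300, seed=7)


def make_abundance_table(values: dict, condition_of: dict) -> AbundanceTable:
    """Build a minimal normalized AbundanceTable from literal values."""
    df = pd.DataFrame(values)
    design = pd.DataFrame({"condition": pd.Series(condition_of)})
    return AbundanceTable(values=df, design=design, normalized=True)


def random_cds_strings(rng: np.random.Generator, n: int, min_len=2, max_len=120):
    """Random valid CDS nucleotide strings (sense codons only)."""
    from codonadapt.genetic_code import SENSE_CODONS

    out = []
    for _ in range(n):
        L = int(rng.integers(min_len, max_len))
        out.append("".join(rng.choice(SENSE_CODONS, size=L)))
    return out
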