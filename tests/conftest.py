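import numpy as np
import pandas as pd
import pytest

from riboscreen.annotation import AnnotationRecord
from riboscreen.quantify import PositionalProfile
from riboscreen.simulate import SimParams, simulate_transcriptome


@pytest.fixture(scope="session")
def small_sim():
    """A 150-gene spiked transcriptome shared by read-only tests."""
    return simulate_transcriptome(SimParams(n_genes=150, seed=17))


@pytest.fixture(scope="session")
def null_sim():
    """A 400-gene effect-free transcriptome shared by read-only tests."""
    return simulate_transcriptome(SimParams(
        n_genes=400, seed=29, frac_te=0, frac_s2b=0, frac_uorf=0, frac_rna=0))


@pytest.fixture
def toy_record():
    return AnnotationRecord("tx1", "g1", utr5_len=50, cds_len=300, utr3_len=120)


@pytest.fixture
def uniform_profile(toy_record):
    return PositionalProfile("tx1", np.ones(toy_record.tx_len, dtype=int))


def make_diff_table(genes, p=None, adjp=None, lfc=None, tested=None):
    """Hand-built differential table in the package's column layout."""
    n = len(genes)
    return pd.DataFrame({
        "gene_id": genes,
        "base_mean": np.full(n, 100.0),
        "log2FC": lfc if lfc is not None else np.zeros(n),
        "se": np.full(n, 0.1),
        "stat": np.zeros(n),
        "p": p if p is not None else np.ones(n),
        "adjP": adjp if adjp is not None else np.ones(n),
        "tested": tested if tested is not None else np.ones(n, dtype=bool),
        "reason": [""] * n,
    })
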