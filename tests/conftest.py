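import numpy as np
import pandas as pd
import pytest

from refgene.ingest import CtMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20190411)


def random_ct_matrix(rng, n_genes=5, n_samples=8, groups=None, efficiencies=None):
    """Random but valid Ct matrix in a realistic 15-35 cycle band."""
    base = rng.uniform(18, 30, size=n_genes)
    ct = base[:, None] + rng.normal(0, 1.5, size=(n_genes, n_samples))
    ct = np.clip(ct, 5.0, 44.0)
    return CtMatrix(
        gene_ids=[f"G{i:02d}" for i in range(n_genes)],
        sample_ids=[f"S{j:02d}" for j in range(n_samples)],
        ct_values=ct,
        groups=groups,
        efficiencies=efficiencies,
    )


def random_expression_matrix(rng, n_genes=30, n_conditions=6):
    """Random positive TPM matrix with occasional zeros."""
    log2 = rng.normal(6, 3, size=(n_genes, n_conditions))
    tpm = np.exp2(log2)
    zeros = rng.random(tpm.shape) < 0.05
    tpm[zeros] = 0.0
    return ExpressionMatrix(
        gene_ids=[f"g{i:03d}" for i in range(n_genes)],
        condition_labels=[f"C{j}" for j in range(n_conditions)],
        values=tpm,
    )
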