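import numpy as np
import pytest

from ebeqtl.data_io import ExpressionMatrix, GenotypeTable, GroupAssignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_expr():
    vals = np.arange(12, dtype=float).reshape(3, 4) / 7.0
    return ExpressionMatrix(["T1", "T2", "T3"], ["S1", "S2", "S3", "S4"], vals)


@pytest.fixture
def small_geno():
    codes = np.array([[0, 1, 2, 0], [1, 0, 0, 1]])
    return GenotypeTable(["G1", "G2"], ["S1", "S2", "S3", "S4"], codes)


@pytest.fixture
def groups_70_70():
    labels = np.zeros(140, dtype=int)
    labels[:70] = 1
    return GroupAssignment(labels)


def two_group_data(rng, n_transcripts, n1=70, n0=70, p1=0.0, de_mean=4.0, de_sd=np.sqrt(0.5)):
    """A single-SNP two-group dataset: (values, labels, truth)."""
    n = n1 + n0
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n1]] = 1
    truth = rng.random(n_transcripts) < p1
    values = rng.standard_normal((n_transcripts, n))
    carriers = labels == 1
    n_de = int(truth.sum())
    if n_de:
        values[np.ix_(truth, carriers)] = de_mean + de_sd * rng.standard_normal((n_de, n1))
    return values, GroupAssignment(labels), truth
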