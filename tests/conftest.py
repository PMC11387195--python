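import numpy as np
import pytest

from polyorigin.genotype_io import GenotypeMatrix


def make_matrix(dosage, chrom=None, pos=None, samples=None):
    """Small-matrix helper: dosage is (n_samples, n_sites) list or array."""
    d = np.asarray(dosage, dtype=np.int8)
    n, m = d.shape
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        chrom=np.array(chrom or ["chr01"] * m, dtype=object),
        pos=np.array(pos if pos is not None else range(1, m + 1), dtype=np.int64),
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["T"] * m, dtype=object),
        dosage=d,
    )


@pytest.fixture
def toy_matrix_factory():
    return make_matrix
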