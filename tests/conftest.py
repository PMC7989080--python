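import numpy as np
import pytest

from fpentropy.matrix import FingerprintMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_binary_matrix(rng, m, n, density=0.4):
    """Random m x n binary matrix with no all-zero rows or columns."""
    while True:
        A = (rng.random((m, n)) < density).astype(np.int8)
        if A.any(axis=0).all() and A.any(axis=1).all():
            return A


def as_fpm(values, scheme="test"):
    values = np.asarray(values)
    return FingerprintMatrix(
        values, [f"c{i}" for i in range(1, values.shape[0] + 1)], scheme_name=scheme
    )


def svd_entropy(A):
    """Independent oracle: entropy from the squared singular values of A."""
    s = np.linalg.svd(np.asarray(A, dtype=float), compute_uv=False)
    lam = s**2
    q = lam / lam.sum()
    q = q[q > 0]
    return float(-(q * np.log(q)).sum() / np.log(A.shape[1]))
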