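import numpy as np
import pytest

from sparsesig import CATEGORIES, load_preset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def germline():
    return load_preset("germline")


@pytest.fixture
def toy_reference():
    """Two tiny contigs with known trinucleotide contexts."""
    return {
        #          123456789012345678
        "chr1": "AACGTACGTTACGGATCCA",
        "chr2": "TTGCATGCAAGGCTANCGT",
    }


def random_signatures(rng, k, sparse_categories=12):
    """k well-separated sparse signature rows (sum 1)."""
    beta = np.zeros((k, 96))
    starts = rng.permutation(96)
    for i in range(k):
        support = starts[i * sparse_categories : (i + 1) * sparse_categories]
        beta[i, support] = rng.dirichlet(np.ones(sparse_categories))
    return beta


@pytest.fixture
def separated_signatures(rng):
    return random_signatures(rng, 3)


def assert_trace_non_increasing(trace, rtol=1e-7):
    trace = np.asarray(trace)
    drops = np.diff(trace)
    assert np.all(drops <= rtol * np.maximum(1.0, np.abs(trace[:-1]))), (
        f"objective increased: {trace}"
    )


def projected_gradient_lasso(R, alpha, beta_init, penalty, iters=200_000, tol=1e-13):
    """Independent oracle for min ||R - alpha beta||_F^2 + penalty ||beta||_1, beta >= 0.

    Plain proximal gradient with fixed step 1/L; shares no code with the
    package's coordinate-descent solver.
    """
    G = alpha.T @ alpha
    L = 2.0 * np.linalg.eigvalsh(G).max() if G.size else 1.0
    if L <= 0:
        return np.zeros_like(beta_init)
    beta = np.array(beta_init, dtype=float)
    step = 1.0 / L
    for _ in range(iters):
        grad = 2.0 * (G @ beta - alpha.T @ R)
        new = np.maximum(beta - step * (grad + penalty), 0.0)
        if np.abs(new - beta).max() <= tol * max(1.0, np.abs(new).max()):
            beta = new
            break
        beta = new
    return beta
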