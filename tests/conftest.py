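import numpy as np
import pytest

from epiblup import MarkerMatrix, Phenotypes


def make_markers(rng, n=8, p=5, levels=(0, 1, 2), prefix=""):
    """Random integer-coded marker matrix with generic labels."""
    vals = rng.choice(np.asarray(levels, dtype=float), size=(n, p))
    return MarkerMatrix(
        vals,
        tuple(f"{prefix}ind{i}" for i in range(n)),
        tuple(f"{prefix}m{j}" for j in range(p)),
        frozenset(float(v) for v in levels),
    )


def make_binary_markers(rng, n=10, p=8, freq=0.5, prefix=""):
    vals = (rng.random((n, p)) < freq).astype(float)
    return MarkerMatrix(
        vals,
        tuple(f"{prefix}ind{i}" for i in range(n)),
        tuple(f"{prefix}m{j}" for j in range(p)),
        frozenset({0.0, 1.0}),
    )


def random_phenotypes(rng, M):
    return Phenotypes(M.individual_ids, rng.normal(size=M.n_individuals))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
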