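"""Genomic relationship matrices for additive, epistasis and categorical models.

Every model considered here can be written as a kernel (relationship matrix)
between individuals, so prediction never has to touch the huge effect vectors:

* ``G = M M'`` — additive GBLUP,
* ``H = 0.5 (MM' o MM') + 0.5 (M o M)(M o M)'`` — pairwise-product epistasis
  (EGBLUP interaction terms, self-pairs included),
* ``C`` — categorical marker model: count of loci in identical genotype state,
* ``C_E = 0.5 C o C + 0.5 C`` — categorical epistasis: count of locus *pairs*
  in identical configuration (self-pairs included),
* ``exp(-b d_il)`` — Gaussian kernel on squared Euclidean distances,
* ``G_kl = (m_k m_k') o (m_l m_l')`` — the single-pair kernel used by the
  coding-adaptation procedure (``o`` is the Hadamard product).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .markers import MarkerMatrix, MarkerValidationError

__all__ = [
    "RelationshipMatrix",
    "Bandwidth",
    "load_kernel",
    "write_kernel",
    "build_gblup",
    "build_egblup",
    "build_cm",
    "build_ce",
    "median_bandwidth",
    "build_gaussian",
    "build_pair_kernel",
]


@dataclass(frozen=True)
class RelationshipMatrix:
    """An ``n x n`` symmetric kernel between individuals with a model tag."""

    values: np.ndarray
    individual_ids: tuple
    model_tag: str
    params: dict | None = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        n = len(self.individual_ids)
        if vals.shape != (n, n):
            raise ValueError(f"kernel shape {vals.shape} does not match {n} ids")
        scale = max(np.abs(vals).max(), 1.0)
        if np.abs(vals - vals.T).max() > 1e-10 * scale:
            raise ValueError("kernel is not symmetric")
        # exact symmetry downstream (factorizations assume it)
        object.__setattr__(self, "values", 0.5 * (vals + vals.T))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, ids) -> "RelationshipMatrix":
        lookup = {v: i for i, v in enumerate(self.individual_ids)}
        idx = np.array([lookup[i] for i in ids], dtype=int)
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], tuple(ids), self.model_tag, self.params)

    def min_eigenvalue_ratio(self) -> float:
        """Smallest eigenvalue divided by the largest (PSD check aid)."""
        w = np.linalg.eigvalsh(self.values)
        top = max(abs(w[0]), abs(w[-1]), 1e-300)
        return w[0] / top


@dataclass(frozen=True)
class Bandwidth:
    """Gaussian-kernel bandwidth, by default the median heuristic b = 2 / q50."""

    b: float
    q50: float | None = None

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("bandwidth must be positive")


def write_kernel(K: RelationshipMatrix, path) -> None:
    """Write a kernel as TSV with individual ids on both axes."""
    import pandas as pd

    pd.DataFrame(K.values, index=list(K.individual_ids), columns=list(K.individual_ids)).to_csv(
        path, sep="\t", float_format="%.17g", index_label=K.model_tag
    )


def load_kernel(path) -> RelationshipMatrix:
    """Read a kernel TSV written by :func:`write_kernel`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    tag = df.index.name or "loaded"
    if list(df.index) != list(df.columns):
        raise ValueError("kernel row and column ids differ")
    return RelationshipMatrix(df.to_numpy(dtype=float), tuple(df.index), tag)


def build_gblup(M: MarkerMatrix) -> RelationshipMatrix:
    """Additive relationship matrix ``G = M M'``."""
    return RelationshipMatrix(M.values @ M.values.T, M.individual_ids, "G")


def build_egblup(M: MarkerMatrix) -> RelationshipMatrix:
    """Epistasis relationship matrix of the pairwise-product model.

    ``H = 0.5 (MM' o MM') + 0.5 (M o M)(M o M)'`` sums the rank-one kernels of
    all marker pairs (j, k) with j >= k, self-interactions included.  Unlike
    ``G`` it is *not* invariant under translations of the marker coding.
    """
    G = M.values @ M.values.T
    MM = M.values * M.values
    H = 0.5 * (G * G) + 0.5 * (MM @ MM.T)
    return RelationshipMatrix(H, M.individual_ids, "H")


def _require_categorical(M: MarkerMatrix, what: str):
    if M.is_continuous:
        raise MarkerValidationError(f"{what} requires an integer-coded matrix, not a continuous one")
    if not 2 <= len(M.levels) <= 3:
        raise MarkerValidationError(f"{what} requires 2 or 3 coding levels, got {len(M.levels)}")


def build_cm(M: MarkerMatrix) -> RelationshipMatrix:
    """Categorical-marker kernel: ``C_il`` = number of loci where i and l match.

    Computed as a sum of indicator-block inner products over the genotype
    states, which covers both two- and three-level codings (for {0,1} markers
    this equals ``p - sum_j |M_ij - M_lj|``).
    """
    _require_categorical(M, "CM kernel")
    n = M.n_individuals
    C = np.zeros((n, n))
    for level in sorted(M.levels):
        B = (M.values == level).astype(float)
        C += B @ B.T
    return RelationshipMatrix(C, M.individual_ids, "C")


def build_ce(M: MarkerMatrix, include_self_pairs: bool = True) -> RelationshipMatrix:
    """Categorical-epistasis kernel ``C_E = 0.5 C o C + 0.5 C``.

    ``C_E[i,l]`` counts the marker *pairs* (k <= l) on which individuals i and
    l carry the identical two-locus configuration: 0.5 C (C + 1) including the
    pair of a locus with itself, 0.5 C (C - 1) when ``include_self_pairs`` is
    False.
    """
    C = build_cm(M).values
    sign = 1.0 if include_self_pairs else -1.0
    CE = 0.5 * C * C + sign * 0.5 * C
    return RelationshipMatrix(CE, M.individual_ids, "CE", {"self_pairs": include_self_pairs})


def median_bandwidth(M: MarkerMatrix) -> Bandwidth:
    """Median heuristic ``b = 2 / q50`` over all pairwise squared distances."""
    if M.n_individuals < 2:
        raise ValueError("need at least two individuals")
    d2 = pdist(M.values, metric="sqeuclidean")
    q50 = float(np.median(d2))
    if q50 <= 0:
        raise ValueError("median squared distance is zero (duplicate-dominated data)")
    return Bandwidth(2.0 / q50, q50)


def build_gaussian(M: MarkerMatrix, bandwidth: Bandwidth | float | None = None) -> RelationshipMatrix:
    """Gaussian kernel ``Cov_il = exp(-b d_il)`` on squared Euclidean distances.

    Translation of the coding leaves the kernel unchanged; rescaling by c is
    absorbed by using bandwidth ``b / c**2``.  Defaults to the median
    heuristic when no bandwidth is given.
    """
    if bandwidth is None:
        bandwidth = median_bandwidth(M)
    elif not isinstance(bandwidth, Bandwidth):
        bandwidth = Bandwidth(float(bandwidth))
    D2 = squareform(pdist(M.values, metric="sqeuclidean"))
    K = np.exp(-bandwidth.b * D2)
    np.fill_diagonal(K, 1.0)
    return RelationshipMatrix(K, M.individual_ids, "gaussian", {"b": bandwidth.b, "q50": bandwidth.q50})


def build_pair_kernel(M: MarkerMatrix, k, l) -> RelationshipMatrix:
    """Single-pair kernel ``G_kl = (m_k m_k') o (m_l m_l')`` (rank <= 1).

    Equals ``u u'`` with ``u = m_k o m_l`` the entrywise product of the two
    marker columns; ``k == l`` gives the self-interaction kernel.
    """
    lookup = {m: j for j, m in enumerate(M.marker_ids)}
    try:
        jk, jl = lookup[k], lookup[l]
    except KeyError as exc:
        raise KeyError(f"unknown marker id {exc.args[0]!r}") from None
    u = M.values[:, jk] * M.values[:, jl]
    return RelationshipMatrix(np.outer(u, u), M.individual_ids, "pair", {"pair": (k, l)})
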