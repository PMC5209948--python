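"""Executable theory of marker-coding effects in pairwise-product epistasis models.

A marker coding assigns numbers to the genotype states of a locus; in a model
whose interaction covariates are products ``M_ij M_ik``, the coding implicitly
fixes a *weight table*: the multiple of the interaction effect ``h_jk``
received by each two-locus genotype combination.  This module makes that
correspondence executable in both directions (coding -> weight table, three
given weights -> coding up to a global sign) and quantifies, by exact
enumeration, the expected quadratic loss incurred when the *orientation* of
each locus (which allele is the reference) is unknown.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightTable",
    "CodingSolution",
    "OrientationCase",
    "OrientationLossResult",
    "interaction_weight_table",
    "solve_coding_from_weights",
    "best_scalar_effect",
    "expected_orientation_loss",
]


@dataclass(frozen=True)
class WeightTable:
    """Grid of implicit interaction weights ``a[r, s] = coding[r] * coding[s]``.

    3x3 for three-level codings (rows/columns ordered aa, aA, AA), 2x2 for
    binary loci.  ``coding`` is the generating tuple when known.
    """

    a: np.ndarray
    coding: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        if self.a.ndim != 2 or self.a.shape[0] != self.a.shape[1] or self.a.shape[0] not in (2, 3):
            raise ValueError("weight table must be 2x2 or 3x3")


@dataclass(frozen=True)
class CodingSolution:
    """Coding recovered from three weights.

    The magnitudes are always determined; signs only up to flips that preserve
    every given product.  ``solutions`` lists all sign-consistent codings; when
    the off-diagonal positions sign-connect all three values it has exactly
    two elements (a global +/- pair, ``global_sign_only``).
    """

    coding: tuple
    solutions: tuple
    sign_ambiguity: bool
    consistent: bool
    implied: WeightTable

    @property
    def global_sign_only(self) -> bool:
        return len(self.solutions) == 2


def interaction_weight_table(coding) -> WeightTable:
    """Weight table implied by a per-locus coding (2 or 3 values).

    For a three-level coding ``(M_aa, M_aA, M_AA)`` the weights are all
    products ``a_rs = M_r M_s``; the symmetric coding (-1, 0, 1) zeroes every
    combination involving a heterozygote, while (0, 1, 2) zeroes every
    combination involving the aa homozygote.
    """
    c = np.asarray(tuple(coding), dtype=float)
    if c.size not in (2, 3):
        raise ValueError("coding must have 2 (binary) or 3 (diploid dosage) values")
    return WeightTable(np.outer(c, c), tuple(c.tolist()))


def solve_coding_from_weights(given) -> CodingSolution:
    """Recover the coding ``(M_aa, M_aA, M_AA)`` from three specified weights.

    ``given`` is an iterable of ``((r, s), value)`` with 1-based positions in
    the 3x3 table of products.  The three positions must jointly involve all
    three coding values and the values must be nonzero.  The multiplicative
    system is solved on log-magnitudes; signs are resolved by enumeration.
    Solutions come at least in a (+coding, -coding) pair; if the off-diagonal
    positions do not sign-connect all three values (e.g. two squares and one
    product) additional sign flips survive and ``solutions`` lists them all.
    A negative value at a squared position, or no sign assignment reproducing
    the given signs, marks the input inconsistent.
    """
    entries = [((int(r), int(s)), float(v)) for (r, s), v in given]
    if len(entries) != 3:
        raise ValueError("exactly three weights are required")
    positions = [tuple(sorted(pos)) for pos, _ in entries]
    if len(set(positions)) != 3:
        raise ValueError("the three weight positions must be distinct")
    covered = set(itertools.chain.from_iterable(positions))
    if covered != {1, 2, 3}:
        raise ValueError(f"positions must jointly involve all three coding values, got {sorted(covered)}")
    nan_table = WeightTable(np.full((3, 3), np.nan))
    for (r, s), v in entries:
        if v == 0:
            raise ValueError("weights must be nonzero")
        if r == s and v < 0:
            return CodingSolution((np.nan,) * 3, (), True, False, nan_table)

    # log-magnitude system: log|a_rs| = log|x_r| + log|x_s|
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for i, ((r, s), v) in enumerate(zip(positions, (v for _, v in entries))):
        A[i, r - 1] += 1
        A[i, s - 1] += 1
        b[i] = np.log(abs(v))
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("weight positions do not determine the coding (singular system)")
    mags = np.exp(np.linalg.solve(A, b))

    solutions = []
    for signs in itertools.product((1.0, -1.0), repeat=3):
        x = mags * np.array(signs)
        if all(abs(x[r - 1] * x[s - 1] - v) <= 1e-10 * max(abs(v), 1.0) for (r, s), v in entries):
            solutions.append(tuple(x.tolist()))
    if not solutions:
        return CodingSolution((np.nan,) * 3, (), True, False, nan_table)
    # representative: the solution whose first entry is largest (breaks the
    # global-sign tie; with richer ambiguity all members stay in `solutions`)
    rep = max(solutions, key=lambda x: x[0])
    return CodingSolution(rep, tuple(solutions), True, True, interaction_weight_table(rep))


def best_scalar_effect(model_table: np.ndarray, true_table: np.ndarray) -> tuple[float, float]:
    """Least-squares scalar ``h`` minimizing ``||h W - T||_F^2`` and the loss.

    Closed form ``h = <W, T> / <W, W>`` (0 when W is the zero table).
    """
    W = np.asarray(model_table, dtype=float)
    T = np.asarray(true_table, dtype=float)
    ww = float(np.sum(W * W))
    h = float(np.sum(W * T)) / ww if ww > 0 else 0.0
    loss = float(np.sum((h * W - T) ** 2))
    return h, loss


@dataclass(frozen=True)
class OrientationCase:
    flips: tuple  # which of the two loci had their orientation inverted
    probability: float
    h_opt: float
    loss: float


@dataclass(frozen=True)
class OrientationLossResult:
    expected_loss: float
    cases: tuple

    def losses(self) -> np.ndarray:
        return np.array([c.loss for c in self.cases])


def expected_orientation_loss(model_coding, true_table, flip_prob: float = 0.5) -> OrientationLossResult:
    """Expected minimal quadratic loss under random marker orientation.

    Two binary loci share the ``model_coding`` (a pair of values, ordered by
    allele).  Each locus independently has its orientation inverted with
    probability ``flip_prob``; inversion reverses which allele receives which
    coding value.  For each of the four orientation outcomes the scalar
    interaction effect best fitting ``true_table`` (2x2) in quadratic loss is
    computed in closed form, and the minimal losses are averaged with their
    probabilities.
    """
    c = np.asarray(tuple(model_coding), dtype=float)
    if c.size != 2:
        raise ValueError("model coding must have two values (binary loci)")
    T = np.asarray(true_table, dtype=float)
    if T.shape != (2, 2):
        raise ValueError("true table must be 2x2 (binary loci)")
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip probability must be in [0, 1]")

    cases = []
    expected = 0.0
    for f1, f2 in itertools.product((0, 1), repeat=2):
        c1 = c[::-1] if f1 else c
        c2 = c[::-1] if f2 else c
        W = np.outer(c1, c2)
        h, loss = best_scalar_effect(W, T)
        prob = (flip_prob if f1 else 1 - flip_prob) * (flip_prob if f2 else 1 - flip_prob)
        cases.append(OrientationCase((f1, f2), prob, h, loss))
        expected += prob * loss
    return OrientationLossResult(expected, tuple(cases))
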