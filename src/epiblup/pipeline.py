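"""Cross-validated predictive ability and the prior-driven coding adaptation.

Predictive ability is measured exactly as in standard genomic-prediction
practice: repeatedly hold out ~10% of the individuals, estimate variance
components on the training kernel only, predict everyone from the training
phenotypes with the full kernel, and record Pearson's correlation between
observed and predicted phenotypes on the held-out set.

The coding-adaptation procedure exploits that the pairwise-product epistasis
model is orientation dependent: interaction effects are back-solved once under
the original coding and once with every marker's orientation inverted, each
pair keeps whichever orientation gave it the larger absolute effect, and the
per-pair kernels (Hadamard products of the two marker outer products, in the
chosen orientation) are summed into a new relationship matrix.  Built from one
trait's records, that matrix carries prior information usable when predicting
a correlated trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import (
    RelationshipMatrix,
    build_ce,
    build_cm,
    build_egblup,
    build_gaussian,
    build_gblup,
)
from .markers import (
    MarkerMatrix,
    Phenotypes,
    invert_orientation,
    translate_coding,
    vanraden_standardize,
)
from .mixed_model import (
    VarianceComponents,
    backsolve_interaction_effects,
    estimate_variance_components,
    predict_genetic_values,
)

__all__ = [
    "CVConfig",
    "CVResult",
    "OrientationAssignment",
    "cross_validate",
    "choose_orientations",
    "adapt_coding_kernel",
    "cross_trait_predict",
    "build_model_kernel",
    "MODEL_LADDER",
]


@dataclass(frozen=True)
class CVConfig:
    """Repeated hold-out configuration (~10% test individuals, 200 repeats)."""

    test_fraction: float = 0.10
    test_size: int | None = None
    n_repeats: int = 200
    seed: int = 0
    reestimate_each_repeat: bool = True

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("need at least one repeat")
        if self.test_size is None and not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test fraction must be in (0, 1)")

    def resolve_test_size(self, n: int) -> int:
        size = self.test_size if self.test_size is not None else max(1, round(self.test_fraction * n))
        if not 0 < size < n:
            raise ValueError(f"test size {size} invalid for n = {n}")
        return size


@dataclass(frozen=True)
class CVResult:
    """Per-repeat Pearson correlations with their mean and standard error."""

    per_repeat_r: np.ndarray
    n_excluded: int = 0

    def __post_init__(self):
        object.__setattr__(self, "per_repeat_r", np.asarray(self.per_repeat_r, dtype=float))

    @property
    def mean_r(self) -> float:
        return float(self.per_repeat_r.mean())

    @property
    def se_r(self) -> float:
        r = self.per_repeat_r
        return float(r.std(ddof=1) / np.sqrt(r.size)) if r.size > 1 else np.nan


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate(K: RelationshipMatrix, y: Phenotypes, cfg: CVConfig) -> CVResult:
    """Repeated hold-out predictive ability of one kernel on one trait.

    Each repeat draws the test set without replacement, estimates the variance
    components on the training submatrix only, predicts all individuals with
    the full kernel and records the test-set correlation between observed and
    predicted expected phenotypes.  Repeats where the correlation is undefined
    (zero variance) are excluded and counted.
    """
    ids = np.asarray(K.individual_ids, dtype=object)
    yv = y.reindex(K.individual_ids).y
    n = ids.size
    size = cfg.resolve_test_size(n)
    rng = np.random.default_rng(cfg.seed)
    rs = []
    excluded = 0
    vc: VarianceComponents | None = None
    for _ in range(cfg.n_repeats):
        test_idx = rng.choice(n, size=size, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        train_ids = tuple(ids[~mask])
        if cfg.reestimate_each_repeat or vc is None:
            vc = estimate_variance_components(K.submatrix(train_ids), y)
        pred = predict_genetic_values(K, y, train_ids, vc)
        r = _pearson(yv[mask], pred.test_predictions())
        if np.isnan(r):
            excluded += 1
        else:
            rs.append(r)
    if not rs:
        raise ValueError("all repeats had undefined correlations")
    return CVResult(np.array(rs), n_excluded=excluded)


@dataclass(frozen=True)
class OrientationAssignment:
    """Per unordered marker pair: keep the original coding or invert both markers.

    ``inverted[k, l]`` (symmetric boolean matrix) is True when the pair (k, l)
    is better described with both markers' orientations inverted.
    """

    marker_ids: tuple
    inverted: np.ndarray

    def __post_init__(self):
        inv = np.asarray(self.inverted, dtype=bool)
        p = len(self.marker_ids)
        if inv.shape != (p, p):
            raise ValueError("assignment matrix shape must be (p, p)")
        object.__setattr__(self, "inverted", inv | inv.T)

    @property
    def n_inverted_pairs(self) -> int:
        return int(np.triu(self.inverted).sum())


def choose_orientations(M: MarkerMatrix, y_source: Phenotypes, vc: VarianceComponents) -> OrientationAssignment:
    """Pick per-pair orientations from already available records.

    Back-solves all interaction effects h_hat (original coding) and h_tilde
    (all orientations inverted); a pair keeps the original orientation iff
    ``|h_hat / h_tilde| >= 1``, with ties — including the 0/0 case — resolved
    in favor of the original coding.
    """
    h_orig = backsolve_interaction_effects(M, y_source, vc, "original").effects
    h_inv = backsolve_interaction_effects(invert_orientation(M), y_source, vc, "inverted").effects
    return OrientationAssignment(M.marker_ids, np.abs(h_orig) < np.abs(h_inv))


def adapt_coding_kernel(
    M: MarkerMatrix,
    assignment: OrientationAssignment,
    block_size: int = 256,
) -> RelationshipMatrix:
    """Sum of per-pair kernels with each pair in its assigned orientation.

    The pair (k, l) contributes ``u u'`` with ``u`` the entrywise product of
    marker columns k and l taken either both from the original coding or both
    from the inverted one.  With every pair assigned "original" this equals
    the pairwise-product epistasis kernel.  Accumulation is blocked over k to
    keep memory at O(n * block_size); cost is O(p^2 n) for the pair products
    plus O(p^2 n^2 / block) matmuls.
    """
    if tuple(assignment.marker_ids) != tuple(M.marker_ids):
        raise ValueError("assignment does not match the marker matrix")
    X = M.values
    Xi = invert_orientation(M).values
    n, p = X.shape
    K = np.zeros((n, n))
    for k in range(p):
        cols = np.arange(k, p)
        inv = assignment.inverted[k, cols]
        U = np.where(inv[None, :], Xi[:, [k]] * Xi[:, cols], X[:, [k]] * X[:, cols])
        for start in range(0, U.shape[1], block_size):
            B = U[:, start : start + block_size]
            K += B @ B.T
    return RelationshipMatrix(K, M.individual_ids, "pair_sum", {"n_inverted_pairs": assignment.n_inverted_pairs})


def cross_trait_predict(K_source_adapted: RelationshipMatrix, y_target: Phenotypes, cfg: CVConfig) -> CVResult:
    """Predict a target trait with a kernel whose coding was adapted on another trait.

    Variance components are re-estimated on the target trait's training folds;
    only the relationship structure is transferred.
    """
    return cross_validate(K_source_adapted, y_target, cfg)


# ---------------------------------------------------------------------------
# Model ladder: one name -> kernel constructor, as exposed by the CLI

def build_model_kernel(M: MarkerMatrix, model: str, coding: str = "as-is") -> RelationshipMatrix:
    """Build the kernel for one model of the comparison ladder.

    ``model``: gblup | egblup | cm | ce | gaussian.  ``coding`` recodes the
    matrix first: 'as-is', '012' (identity for dosage data), '-101'
    (translate by 1), '-210' (translate by 2), '-11' (binary to {-1, 1}),
    'vanraden' (center by twice the allele frequency).
    """
    recodings = {
        "as-is": lambda m: m,
        "012": lambda m: m,
        "-101": lambda m: translate_coding(m, np.ones(m.n_markers)),
        "-210": lambda m: translate_coding(m, np.full(m.n_markers, 2.0)),
        "-11": lambda m: translate_coding(scale_coding_2(m), np.ones(m.n_markers)),
        "vanraden": vanraden_standardize,
    }
    builders = {
        "gblup": build_gblup,
        "egblup": build_egblup,
        "cm": build_cm,
        "ce": build_ce,
        "gaussian": build_gaussian,
    }
    if coding not in recodings:
        raise ValueError(f"unknown coding {coding!r}; choose from {sorted(recodings)}")
    if model not in builders:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(builders)}")
    return builders[model](recodings[coding](M))


def scale_coding_2(M: MarkerMatrix) -> MarkerMatrix:
    from .markers import scale_coding

    return scale_coding(M, 2.0)


#: (model, coding) pairs of the standard comparison ladder.
MODEL_LADDER = (
    ("gblup", "as-is"),
    ("egblup", "as-is"),
    ("egblup", "-101"),
    ("egblup", "vanraden"),
    ("cm", "as-is"),
    ("ce", "as-is"),
    ("gaussian", "as-is"),
)
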