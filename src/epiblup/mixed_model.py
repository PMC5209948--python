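"""Single-kernel mixed model: REML variance components, kernel BLUP, ridge oracle.

The model is ``y = 1 mu + g + e`` with ``g ~ N(0, sigma2_g K)`` for a given
relationship matrix ``K`` and ``e ~ N(0, sigma2_e I)``.  Variance components
are estimated by restricted maximum likelihood on the training kernel via a
spectral decomposition of the intercept-projected kernel, profiling out
``sigma2_g`` and optimizing the restricted likelihood in ``log(lambda)`` with
``lambda = sigma2_e / sigma2_g``.  Prediction of genetic values for training
and test individuals uses the one dense symmetric solve

    g_hat = [T_train - s^-1 J_block + lambda K^-1]^-1 (y_train - ybar, 0)

which is the relationship-matrix form of the mixed-model equations; for
``K = M M'`` it reproduces ridge-regression BLUP of marker effects exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize_scalar

from .kernels import RelationshipMatrix, build_egblup
from .markers import MarkerMatrix, Phenotypes

__all__ = [
    "VarianceComponents",
    "PredictionResult",
    "PairEffectTable",
    "estimate_variance_components",
    "predict_genetic_values",
    "ridge_effect_solution",
    "backsolve_interaction_effects",
]

_LAMBDA_BOUNDS = (1e-5, 1e5)
_PSD_TOL = 1e-8


@dataclass(frozen=True)
class VarianceComponents:
    """Error variance, genetic variance and their ratio lambda = s2_e / s2_g."""

    sigma2_e: float
    sigma2_g: float
    at_boundary: bool = False
    degenerate: bool = False

    def __post_init__(self):
        if self.sigma2_e < 0 or self.sigma2_g < 0:
            raise ValueError("variance components must be nonnegative")

    @property
    def lam(self) -> float:
        """Ratio sigma2_e / sigma2_g (inf when the genetic variance is zero)."""
        if self.sigma2_g == 0:
            return np.inf
        return self.sigma2_e / self.sigma2_g

    @property
    def heritability(self) -> float:
        tot = self.sigma2_e + self.sigma2_g
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class PredictionResult:
    """Predicted genetic values for all individuals plus the fixed effect.

    ``g_hat`` follows the id order of the kernel the prediction was made from;
    the predicted expected phenotype of individual i is ``mu_hat + g_hat[i]``.
    """

    individual_ids: tuple
    g_hat: np.ndarray
    mu_hat: float
    ybar_train: float
    train_ids: tuple
    test_ids: tuple

    @property
    def y_hat(self) -> np.ndarray:
        return self.mu_hat + self.g_hat

    def test_predictions(self) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.individual_ids)}
        return self.y_hat[[lookup[i] for i in self.test_ids]]


@dataclass(frozen=True)
class PairEffectTable:
    """Predicted pairwise interaction effects h_hat[k, l] for all pairs k <= l."""

    marker_ids: tuple
    effects: np.ndarray  # (p, p) symmetric; entry (k, l) = h_hat for the pair
    orientation: str = "original"

    def to_frame(self) -> pd.DataFrame:
        p = len(self.marker_ids)
        iu = np.triu_indices(p)
        return pd.DataFrame(
            {
                "marker_k": [self.marker_ids[i] for i in iu[0]],
                "marker_l": [self.marker_ids[j] for j in iu[1]],
                "h_hat": self.effects[iu],
                "orientation": self.orientation,
            }
        )

    def top_pair(self):
        """(marker_k, marker_l, h_hat) of the largest |h_hat|."""
        p = len(self.marker_ids)
        masked = np.triu(np.abs(self.effects))
        k, l = np.unravel_index(np.argmax(masked), (p, p))
        return self.marker_ids[k], self.marker_ids[l], self.effects[k, l]


def _check_psd(K: RelationshipMatrix) -> np.ndarray:
    w, V = np.linalg.eigh(K.values)
    top = max(abs(w[-1]), 1e-300)
    if w[0] < -_PSD_TOL * top:
        raise ValueError(f"kernel is not PSD within tolerance (min/max eigenvalue ratio {w[0] / top:.2e})")
    return np.clip(w, 0.0, None), V


def estimate_variance_components(K_train: RelationshipMatrix, y_train: Phenotypes) -> VarianceComponents:
    """REML estimates of (sigma2_e, sigma2_g) for ``y = 1 mu + g + e``.

    Projects out the intercept, eigendecomposes the projected kernel and
    maximizes the restricted log-likelihood over ``log(lambda)`` in
    ``[1e-5, 1e5]`` by a coarse grid plus bounded refinement.  A result at the
    boundary of the search interval is flagged.
    """
    y = y_train.reindex(K_train.individual_ids).y
    n = y.size
    if n < 10:
        raise ValueError(f"need at least 10 training individuals for REML, got {n}")
    if np.var(y) < 1e-14:
        return VarianceComponents(0.0, 0.0, degenerate=True)

    # orthonormal basis of the complement of the intercept
    Qfull, _ = np.linalg.qr(np.ones((n, 1)), mode="complete")
    Q = Qfull[:, 1:]
    A = Q.T @ K_train.values @ Q
    _check_psd(K_train)
    xi, V = np.linalg.eigh(0.5 * (A + A.T))
    xi = np.clip(xi, 0.0, None)
    eta2 = (V.T @ (Q.T @ y)) ** 2
    m = n - 1

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        denom = xi + lam
        s2g = float(np.sum(eta2 / denom)) / m
        if s2g <= 0:
            return np.inf
        return m * np.log(s2g) + float(np.sum(np.log(denom)))

    lo, hi = np.log(_LAMBDA_BOUNDS[0]), np.log(_LAMBDA_BOUNDS[1])
    grid = np.linspace(lo, hi, 81)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    best = int(np.argmin(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, grid.size - 1)]
    res = minimize_scalar(neg_restricted_ll, bounds=(a, b), method="bounded")
    log_lam = float(res.x) if res.fun <= vals[best] else float(grid[best])
    lam = float(np.exp(log_lam))
    s2g = float(np.sum(eta2 / (xi + lam))) / m
    s2e = lam * s2g
    at_boundary = log_lam <= lo + 1e-6 or log_lam >= hi - 1e-6
    return VarianceComponents(s2e, s2g, at_boundary=at_boundary)


def predict_genetic_values(
    K_full: RelationshipMatrix,
    y: Phenotypes,
    train_ids,
    vc: VarianceComponents,
    jitter: bool = False,
) -> PredictionResult:
    """Kernel BLUP of genetic values for all individuals from training records.

    Solves the relationship-matrix mixed-model system with individuals ordered
    training-then-test, a 1/0 diagonal ``T_train``, the all-ones block on the
    training rows and the centered training phenotypes (padded with zeros) as
    right-hand side.  The fixed effect reported is the mixed-model intercept
    ``mu_hat = ybar_train - mean(g_hat_train)``, so that ``mu_hat + g_hat``
    reproduces the marker-effect (ridge) predictions exactly for ``K = MM'``.
    """
    train_ids = tuple(train_ids)
    all_ids = tuple(K_full.individual_ids)
    train_set = set(train_ids)
    unknown = train_set - set(all_ids)
    if unknown:
        raise KeyError(f"train ids not in kernel: {sorted(unknown)[:5]}")
    if not train_ids:
        raise ValueError("training set is empty")
    test_ids = tuple(i for i in all_ids if i not in train_set)
    order = list(train_ids) + list(test_ids)
    lookup = {v: i for i, v in enumerate(all_ids)}
    perm = np.array([lookup[i] for i in order], dtype=int)

    K = K_full.values[np.ix_(perm, perm)]
    n = K.shape[0]
    s = len(train_ids)
    y_tr = y.reindex(train_ids).y
    ybar = float(y_tr.mean())

    if vc.sigma2_g == 0 or vc.degenerate:
        g = np.zeros(n)
    else:
        if jitter:
            K = K + 1e-8 * np.mean(np.diag(K)) * np.eye(n)
        # [T - s^-1 J + lam K^-1]^-1 r, rearranged as [K (T - s^-1 J) + lam I]^-1 K r
        # so a PSD but rank-deficient kernel (e.g. G = MM' with p < n) needs no inverse
        P = np.zeros((n, n))
        P[np.arange(s), np.arange(s)] = 1.0
        P[:s, :s] -= 1.0 / s
        B = K @ P + vc.lam * np.eye(n)
        rhs = np.zeros(n)
        rhs[:s] = y_tr - ybar
        try:
            g = scipy.linalg.solve(B, K @ rhs)
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
            raise np.linalg.LinAlgError(
                "mixed-model system is singular; rerun with jitter=True to add 1e-8*mean(diag) ridge"
            ) from exc

    # map back to the kernel's id order
    g_full = np.empty(n)
    g_full[perm] = g
    mu_hat = ybar - float(g[:s].mean())
    return PredictionResult(all_ids, g_full, mu_hat, ybar, train_ids, test_ids)


def ridge_effect_solution(M: MarkerMatrix, y_train: Phenotypes, lam: float):
    """Mixed-model-equation solution (mu_hat, beta_hat) of penalized regression.

    Solves ``min ||y - 1 mu - M beta||^2 + lam ||beta||^2`` with the intercept
    unpenalized — the marker-effect form of GBLUP and the oracle used to check
    the kernel predictor and the translation/scaling invariance properties.
    """
    if lam <= 0:
        raise ValueError("penalty must be positive")
    X = M.values
    y = y_train.reindex(M.individual_ids).y
    n, p = X.shape
    lhs = np.empty((p + 1, p + 1))
    lhs[0, 0] = n
    lhs[0, 1:] = X.sum(axis=0)
    lhs[1:, 0] = lhs[0, 1:]
    lhs[1:, 1:] = X.T @ X + lam * np.eye(p)
    rhs = np.concatenate(([y.sum()], X.T @ y))
    sol = scipy.linalg.solve(lhs, rhs, assume_a="sym")
    return float(sol[0]), sol[1:]


def backsolve_interaction_effects(
    M: MarkerMatrix,
    y_train: Phenotypes,
    vc: VarianceComponents,
    orientation_label: str = "original",
) -> PairEffectTable:
    """BLUP back-solution of all pairwise interaction effects under EGBLUP.

    With ``V = sigma2_h H + sigma2_e I`` (H the pairwise-product kernel), the
    generalized-least-squares intercept ``mu_hat = (1'V^-1 y) / (1'V^-1 1)``
    and ``w = V^-1 (y - 1 mu_hat)``, the predicted effect of pair (k, l) is
    ``h_hat_kl = sigma2_h * sum_i M_ik M_il w_i``, i.e. the full table is
    ``sigma2_h * M' diag(w) M``.
    """
    y = y_train.reindex(M.individual_ids).y
    H = build_egblup(M).values
    V = vc.sigma2_g * H + vc.sigma2_e * np.eye(len(y))
    try:
        cf = scipy.linalg.cho_factor(V)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("V = s2_h H + s2_e I is singular") from exc
    ones = np.ones_like(y)
    Vi_y = scipy.linalg.cho_solve(cf, y)
    Vi_1 = scipy.linalg.cho_solve(cf, ones)
    mu = float(ones @ Vi_y) / float(ones @ Vi_1)
    w = scipy.linalg.cho_solve(cf, y - mu)
    effects = vc.sigma2_g * (M.values.T @ (w[:, None] * M.values))
    return PairEffectTable(M.marker_ids, 0.5 * (effects + effects.T), orientation_label)
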