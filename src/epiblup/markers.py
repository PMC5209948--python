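"""Marker-matrix data model, coding transformations, filters and delimited-text I/O.

Genotypes are held as an ``n x p`` numeric array (individuals x loci) together
with row/column identifiers and the set of admissible coding values (*levels*),
e.g. ``{0, 1}`` for presence/absence or haploid markers and ``{0, 1, 2}`` for
diploid allele dosages.  Recodings (translation, scaling, orientation
inversion, allele-frequency centering) are tracked in a free-text
``coding_tag`` so a kernel or prediction can always be traced back to the
coding it was computed under.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CONTINUOUS",
    "MarkerMatrix",
    "Phenotypes",
    "load_markers",
    "write_markers",
    "load_phenotypes",
    "write_phenotypes",
    "translate_coding",
    "scale_coding",
    "invert_orientation",
    "allele_frequencies",
    "vanraden_standardize",
    "maf_filter",
]

#: Sentinel used as ``levels`` once a matrix has been standardized to
#: continuous values; entry-level membership checks are suspended from then on.
CONTINUOUS = "continuous"

_ALLOWED_INTEGER_LEVELS = frozenset({-2.0, -1.0, 0.0, 1.0, 2.0})


class MarkerValidationError(ValueError):
    """Raised when a marker matrix violates its structural invariants."""


class MarkerParseError(ValueError):
    """Raised when a delimited genotype/phenotype file cannot be parsed."""


def _check_unique(labels, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise MarkerValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass(frozen=True)
class MarkerMatrix:
    """Genotype matrix with identifiers and coding metadata.

    Parameters
    ----------
    values
        ``(n, p)`` array of marker values; float dtype internally.
    individual_ids, marker_ids
        Row and column labels; must be unique.
    levels
        Admissible coding values (a frozenset) or :data:`CONTINUOUS`.
    coding_tag
        Provenance of applied recodings, appended to by every transform.
    """

    values: np.ndarray
    individual_ids: tuple
    marker_ids: tuple
    levels: object = None
    coding_tag: str = "as-loaded"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        n, p = vals.shape
        if n < 2:
            raise MarkerValidationError(f"need at least 2 individuals, got {n}")
        if p < 1:
            raise MarkerValidationError("need at least 1 marker")
        if len(self.individual_ids) != n or len(self.marker_ids) != p:
            raise MarkerValidationError("identifier lengths do not match values shape")
        _check_unique(self.individual_ids, "individual ids")
        _check_unique(self.marker_ids, "marker ids")
        if not np.all(np.isfinite(vals)):
            raise MarkerValidationError("marker values contain NaN/inf (missing data is not supported)")
        if self.levels is None:
            object.__setattr__(self, "levels", frozenset(np.unique(vals).tolist()))
        if self.levels != CONTINUOUS:
            levels = frozenset(float(v) for v in self.levels)
            object.__setattr__(self, "levels", levels)
            bad = set(np.unique(vals).tolist()) - levels
            if bad:
                raise MarkerValidationError(f"values outside declared levels {sorted(levels)}: {sorted(bad)[:5]}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def is_continuous(self) -> bool:
        return self.levels == CONTINUOUS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.individual_ids), columns=list(self.marker_ids))


@dataclass(frozen=True)
class Phenotypes:
    """Phenotype vector aligned to individuals by label."""

    individual_ids: tuple
    y: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float).ravel()
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        if len(self.individual_ids) != y.size:
            raise MarkerValidationError("phenotype ids and values differ in length")
        _check_unique(self.individual_ids, "individual ids")
        if not np.all(np.isfinite(y)):
            raise MarkerValidationError("phenotypes contain missing values")

    def reindex(self, ids) -> "Phenotypes":
        """Return phenotypes reordered to ``ids`` (label-based alignment)."""
        s = pd.Series(self.y, index=list(self.individual_ids))
        sub = s.reindex(list(ids))
        if sub.isna().any():
            missing = [i for i, v in zip(ids, sub) if np.isnan(v)]
            raise MarkerValidationError(f"no phenotype for individuals {missing[:5]}")
        return Phenotypes(tuple(ids), sub.to_numpy())


# ---------------------------------------------------------------------------
# I/O


def _sep(dialect: str) -> str:
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "," if dialect == "csv" else "\t"


def load_markers(path, dialect: str = "tsv") -> MarkerMatrix:
    """Read a genotype table (header = marker ids, first column = individual ids)."""
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise MarkerParseError(f"non-numeric cell at row {row!r}, column {col!r}") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise MarkerParseError(
            f"missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    distinct = np.unique(values)
    if not set(distinct.tolist()) <= _ALLOWED_INTEGER_LEVELS:
        raise MarkerValidationError(
            f"marker values must be integers in [-2, 2]; found {sorted(set(distinct.tolist()) - _ALLOWED_INTEGER_LEVELS)[:5]}"
        )
    for j in range(values.shape[1]):
        if np.unique(values[:, j]).size > 3:
            raise MarkerValidationError(f"locus {df.columns[j]!r} has more than 3 distinct values")
    return MarkerMatrix(values, tuple(df.index), tuple(df.columns), frozenset(distinct.tolist()))


def write_markers(M: MarkerMatrix, path, dialect: str = "tsv") -> None:
    """Write a genotype table; integer codings round-trip bit-exactly."""
    df = M.to_frame()
    if not M.is_continuous and np.allclose(M.values, np.round(M.values)):
        df = df.astype(int)
        df.to_csv(path, sep=_sep(dialect))
    else:
        df.to_csv(path, sep=_sep(dialect), float_format="%.17g")


def load_phenotypes(path, dialect: str = "tsv") -> Phenotypes:
    """Read a two-column (individual id, value) phenotype table."""
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    if df.shape[1] != 1:
        raise MarkerParseError(f"expected exactly one phenotype column, got {df.shape[1]}")
    y = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if y.isna().any():
        raise MarkerParseError(f"missing/non-numeric phenotype for {y.index[y.isna()][0]!r}")
    return Phenotypes(tuple(df.index), y.to_numpy())


def write_phenotypes(ph: Phenotypes, path, dialect: str = "tsv", name: str = "phenotype") -> None:
    pd.Series(ph.y, index=list(ph.individual_ids), name=name).to_csv(
        path, sep=_sep(dialect), float_format="%.17g", index_label="id"
    )


# ---------------------------------------------------------------------------
# Coding transformations


def translate_coding(M: MarkerMatrix, P) -> MarkerMatrix:
    """Shift the coding of locus ``j`` by ``P[j]``: entry (i,j) becomes M_ij - P_j.

    A non-zero translation generally leaves the integer-level structure, so the
    result keeps explicit levels only when every column is shifted by the same
    integer; otherwise the level set is recomputed from the data.
    """
    P = np.asarray(P, dtype=float).ravel()
    if P.size != M.n_markers:
        raise MarkerValidationError(f"translation vector length {P.size} != p = {M.n_markers}")
    vals = M.values - P[None, :]
    return MarkerMatrix(
        vals,
        M.individual_ids,
        M.marker_ids,
        CONTINUOUS if M.is_continuous else frozenset(np.unique(vals).tolist()),
        coding_tag=f"{M.coding_tag}; translated",
    )


def scale_coding(M: MarkerMatrix, c: float) -> MarkerMatrix:
    """Multiply every entry by ``c != 0``."""
    if c == 0:
        raise ValueError("scaling constant must be nonzero")
    vals = M.values * float(c)
    return MarkerMatrix(
        vals,
        M.individual_ids,
        M.marker_ids,
        CONTINUOUS if M.is_continuous else frozenset(np.unique(vals).tolist()),
        coding_tag=f"{M.coding_tag}; scaled by {c:g}",
    )


def invert_orientation(M: MarkerMatrix, loci=None) -> MarkerMatrix:
    """Swap the role of the alleles at the given loci (all loci by default).

    For {0,1} markers this substitutes 0 by 1 and 1 by 0; for {0,1,2} it swaps
    the homozygotes (0 <-> 2) and fixes the heterozygote.  Both are the map
    ``v -> max(levels) - v``.
    """
    if M.is_continuous:
        raise MarkerValidationError("cannot invert orientation of a continuous (standardized) matrix")
    if not M.levels <= {0.0, 1.0, 2.0}:
        raise MarkerValidationError(f"orientation inversion requires levels within {{0,1,2}}, got {sorted(M.levels)}")
    top = max(M.levels)
    vals = M.values.copy()
    if loci is None:
        idx = np.arange(M.n_markers)
    else:
        lookup = {m: j for j, m in enumerate(M.marker_ids)}
        try:
            idx = np.array([lookup[m] for m in loci], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown marker id {exc.args[0]!r}") from None
    vals[:, idx] = top - vals[:, idx]
    return MarkerMatrix(
        vals,
        M.individual_ids,
        M.marker_ids,
        M.levels,
        coding_tag=f"{M.coding_tag}; inverted {len(idx)} loci",
    )


# ---------------------------------------------------------------------------
# Frequencies, centering, filtering


def allele_frequencies(M: MarkerMatrix) -> np.ndarray:
    """Per-locus frequency of the counted allele.

    Three-level dosage coding: column mean / 2 (dosage counts one allele over
    2n gametes).  Binary {0,1} coding: column mean (presence/absence or
    haploid convention).
    """
    if M.is_continuous:
        raise MarkerValidationError("allele frequencies are undefined for a continuous matrix")
    if not M.levels <= {0.0, 1.0, 2.0}:
        raise MarkerValidationError(f"allele frequencies require levels within {{0,1,2}}, got {sorted(M.levels)}")
    means = M.values.mean(axis=0)
    return means / 2.0 if 2.0 in M.levels else means


def vanraden_standardize(M: MarkerMatrix, scale_by_variance: bool = False) -> MarkerMatrix:
    """Center each column by (twice) its allele frequency.

    Subtracts ``2 * freq_j`` per column for {0,1,2} dosages (``freq_j`` for
    binary markers), i.e. the matrix ``1 P'`` of column means.  The optional
    global divisor ``sqrt(sum 2 p_j (1 - p_j))`` is off by default: a global
    scalar is absorbed by the variance-component ratio and is irrelevant to
    the coding comparisons this package is about.
    """
    if M.is_continuous:
        raise MarkerValidationError("matrix is already continuous")
    freqs = allele_frequencies(M)
    center = 2.0 * freqs if 2.0 in M.levels else freqs
    vals = M.values - center[None, :]
    tag = "vanraden-centered"
    if scale_by_variance:
        denom = np.sqrt(np.sum(2.0 * freqs * (1.0 - freqs)))
        if denom <= 0:
            raise MarkerValidationError("all loci monomorphic: variance divisor is zero")
        vals = vals / denom
        tag += " (variance-scaled)"
    return MarkerMatrix(vals, M.individual_ids, M.marker_ids, CONTINUOUS, coding_tag=f"{M.coding_tag}; {tag}")


def maf_filter(M: MarkerMatrix, threshold: float) -> MarkerMatrix:
    """Drop loci whose minor allele frequency is below ``threshold``."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    freqs = allele_frequencies(M)
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = maf >= threshold
    if not keep.any():
        raise MarkerValidationError(f"MAF filter at {threshold} removed all {M.n_markers} loci")
    return MarkerMatrix(
        M.values[:, keep],
        M.individual_ids,
        tuple(m for m, k in zip(M.marker_ids, keep) if k),
        M.levels,
        coding_tag=f"{M.coding_tag}; maf>={threshold:g} ({int(keep.sum())}/{M.n_markers} kept)",
    )
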