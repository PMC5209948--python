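"""Synthetic genotypes and quantitative traits for the three architecture scenarios.

Genotypes: a founder population with Beta(0.5, 0.5)-distributed allele
frequencies evolves through a configurable number of discrete random-mating
generations; gametes recombine within chromosomes at Haldane rates derived
from the centimorgan lengths, so nearby markers stay in linkage
disequilibrium.  This is a light-weight stand-in for a forward simulator: it
emulates the presence of LD and a minor-allele-frequency floor, not any
particular demography.

Traits: purely additive (dosage x effect), purely dominant (heterozygote
indicator x effect) or purely epistatic (indicator that a marker pair is in
one specific two-locus configuration x effect), with effects drawn N(0, 1).
Genetic values are standardized to mean 0 / variance 1 and independent normal
errors with variance ``(1 - h2) / h2`` are added, so the target broad-sense
heritability (0.8 by default, giving error variance 0.25) is met in
expectation; phenotypes are then re-standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markers import MarkerMatrix, Phenotypes

__all__ = [
    "PAPER_CHROMOSOMES",
    "GenotypeSimConfig",
    "QTLPool",
    "TraitArchitecture",
    "SimulatedTrait",
    "simulate_genotypes",
    "sample_qtl_pool",
    "sample_architecture",
    "simulate_trait",
    "drop_qtl_markers",
]

#: Five chromosomes: (length in cM, number of markers), 10 000 markers total.
PAPER_CHROMOSOMES = ((140.0, 3500), (110.0, 2750), (80.0, 2000), (50.0, 1250), (20.0, 500))


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Parameters of the founder + random-mating drift genotype generator."""

    n_individuals: int = 1000
    chromosomes: tuple = PAPER_CHROMOSOMES
    n_generations_drift: int = 5
    n_founder_haplotypes: int = 100
    maf_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if not self.chromosomes or any(m < 1 or l < 0 for l, m in self.chromosomes):
            raise ValueError("chromosomes must be nonempty (length_cM, n_markers) pairs")
        if not 0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")

    @property
    def n_markers(self) -> int:
        return int(sum(m for _, m in self.chromosomes))

    @classmethod
    def scaled(cls, n_individuals: int, n_markers: int, seed: int = 0, **kw) -> "GenotypeSimConfig":
        """Five chromosomes with the standard cM lengths, marker counts scaled."""
        total = sum(m for _, m in PAPER_CHROMOSOMES)
        counts = [max(1, round(n_markers * m / total)) for _, m in PAPER_CHROMOSOMES]
        counts[0] += n_markers - sum(counts)
        chroms = tuple((l, c) for (l, _), c in zip(PAPER_CHROMOSOMES, counts))
        return cls(n_individuals=n_individuals, chromosomes=chroms, seed=seed, **kw)


def _recombination_rates(length_cm: float, n_markers: int) -> np.ndarray:
    """Haldane recombination probability per adjacent-marker interval."""
    if n_markers < 2:
        return np.zeros(0)
    d = length_cm / (n_markers - 1)
    return np.full(n_markers - 1, 0.5 * (1.0 - np.exp(-2.0 * d / 100.0)))


def _interval_lengths_cm(rates: np.ndarray) -> np.ndarray:
    """Invert Haldane's map function back to interval lengths in cM."""
    if rates.size == 0:
        return rates
    return -50.0 * np.log(1.0 - 2.0 * rates)


def _drift_chromosome(rng, n: int, n_markers: int, rates: np.ndarray, gens: int, n_founders: int) -> np.ndarray:
    # population haplotypes are copies of a finite founder pool; founder
    # haplotypes carry along-chromosome LD from a Gaussian-copula AR process
    # whose correlation decays with map distance (scale 10 cM), and drift +
    # recombination reshape that decay
    freqs = rng.beta(0.5, 0.5, size=n_markers)
    d_cm = _interval_lengths_cm(rates)
    z = np.empty((n_founders, n_markers))
    z[:, 0] = rng.standard_normal(n_founders)
    eps = rng.standard_normal((n_founders, n_markers))
    a = np.exp(-d_cm / 10.0)
    for j in range(1, n_markers):
        z[:, j] = a[j - 1] * z[:, j - 1] + np.sqrt(1.0 - a[j - 1] ** 2) * eps[:, j]
    from scipy.stats import norm

    founders = (z < norm.ppf(freqs)[None, :]).astype(np.int8)
    haps = founders[rng.integers(0, n_founders, size=(n, 2))]
    for _ in range(gens):
        new = np.empty_like(haps)
        for slot in range(2):
            parents = rng.integers(0, n, size=n)
            start = rng.integers(0, 2, size=n)
            if rates.size:
                switches = rng.random((n, rates.size)) < rates
                track = (start[:, None] + np.cumsum(switches, axis=1)) % 2
                track = np.concatenate([start[:, None], track], axis=1)
            else:
                track = start[:, None]
            ph = haps[parents]  # (n, 2, p)
            new[:, slot, :] = np.where(track == 0, ph[:, 0, :], ph[:, 1, :])
        haps = new
    return haps.sum(axis=1).astype(np.int8)


def simulate_genotypes(cfg: GenotypeSimConfig) -> MarkerMatrix:
    """Simulate a diploid {0,1,2} marker matrix with within-chromosome LD.

    Marker ids encode the chromosome (``chr<i>:<j>``) so downstream code can
    stratify QTL draws per chromosome.  Columns whose minor allele frequency
    falls below ``cfg.maf_floor`` after drift are resampled independently from
    a binomial with a uniform frequency above the floor (these few columns
    lose their linkage; the alternative of dropping them would change p).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    blocks, ids = [], []
    for ci, (length, m) in enumerate(cfg.chromosomes, start=1):
        rates = _recombination_rates(length, m)
        blocks.append(_drift_chromosome(rng, n, m, rates, cfg.n_generations_drift, cfg.n_founder_haplotypes))
        ids.extend(f"chr{ci}:{j + 1}" for j in range(m))
    geno = np.concatenate(blocks, axis=1).astype(float)

    freq = geno.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    bad = np.flatnonzero(maf < cfg.maf_floor)
    for j in bad:
        for _ in range(1000):
            f = rng.uniform(max(2.0 * cfg.maf_floor, 0.1), 0.5)
            col = rng.binomial(2, f, size=n).astype(float)
            fr = col.mean() / 2.0
            if min(fr, 1.0 - fr) >= cfg.maf_floor:
                geno[:, j] = col
                break
        else:  # pragma: no cover - binomial resampling essentially always succeeds
            raise RuntimeError("could not resample a polymorphic column")
    return MarkerMatrix(
        geno,
        tuple(f"ind{i + 1}" for i in range(n)),
        tuple(ids),
        frozenset({0.0, 1.0, 2.0}),
        coding_tag=f"simulated (seed={cfg.seed})",
    )


@dataclass(frozen=True)
class QTLPool:
    """Fixed pool of candidate QTL with pre-drawn additive and dominance effects.

    The pool is drawn stratified per chromosome; traits of increasing
    complexity select nested subsets of it and share the pooled effects, so a
    10-QTL trait is exactly the restriction of the 100-QTL trait.
    """

    marker_indices: np.ndarray
    additive_effects: np.ndarray
    dominance_effects: np.ndarray

    @property
    def size(self) -> int:
        return self.marker_indices.size


def _chromosome_groups(M: MarkerMatrix) -> dict:
    groups: dict = {}
    for j, mid in enumerate(M.marker_ids):
        groups.setdefault(str(mid).split(":")[0], []).append(j)
    return groups


def sample_qtl_pool(M: MarkerMatrix, pool_size: int, seed: int = 0, stratify: bool = True) -> QTLPool:
    """Draw the QTL pool, by default equally from each chromosome."""
    rng = np.random.default_rng(seed)
    groups = _chromosome_groups(M)
    if stratify and len(groups) > 1 and pool_size % len(groups) == 0:
        per = pool_size // len(groups)
        idx = np.concatenate(
            [rng.choice(np.asarray(js), size=per, replace=False) for js in groups.values()]
        )
    else:
        idx = rng.choice(M.n_markers, size=pool_size, replace=False)
    idx = np.sort(idx)
    return QTLPool(idx, rng.standard_normal(pool_size), rng.standard_normal(pool_size))


@dataclass(frozen=True)
class TraitArchitecture:
    """One trait's causal structure: QTL (A/D) or pair configurations (E)."""

    scenario: str  # 'additive' | 'dominance' | 'epistasis'
    target_h2: float = 0.8
    seed: int = 0
    qtl_indices: np.ndarray | None = None
    effects: np.ndarray | None = None
    pool_indices: np.ndarray | None = None
    pairs: np.ndarray | None = None  # (q, 2) marker indices
    configurations: np.ndarray | None = None  # (q, 2) genotype values, ordered (M_ij, M_ik)

    def __post_init__(self):
        if self.scenario not in ("additive", "dominance", "epistasis"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 < self.target_h2 <= 1.0:
            raise ValueError("target heritability must be in (0, 1]")

    @property
    def error_variance(self) -> float:
        """Noise variance giving the target h2 on unit-variance genetic values."""
        return (1.0 - self.target_h2) / self.target_h2


def sample_architecture(
    M: MarkerMatrix,
    scenario: str,
    n_qtl_or_pairs: int,
    seed: int = 0,
    pool: QTLPool | None = None,
    parent: TraitArchitecture | None = None,
    target_h2: float = 0.8,
) -> TraitArchitecture:
    """Draw a trait architecture.

    Additive/dominance traits select ``n`` QTL from a :class:`QTLPool`
    (nesting: pass the simpler trait as ``parent`` and its QTL are kept with
    their effects, only the difference is drawn).  Epistatic traits draw
    ``n`` marker pairs uniformly with replacement and give each one randomly
    chosen ordered two-locus configuration an N(0, 1) effect.
    """
    rng = np.random.default_rng(seed)
    if scenario in ("additive", "dominance"):
        if pool is None:
            raise ValueError("additive/dominance architectures require a QTL pool (sample_qtl_pool)")
        if n_qtl_or_pairs > pool.size:
            raise ValueError(f"requested {n_qtl_or_pairs} QTL from a pool of {pool.size}")
        pool_pos = np.arange(pool.size)
        if parent is not None:
            if parent.pool_indices is None or not np.array_equal(parent.pool_indices, pool.marker_indices):
                raise ValueError("parent architecture was not drawn from this pool")
            prev = np.flatnonzero(np.isin(pool.marker_indices, parent.qtl_indices))
            if prev.size > n_qtl_or_pairs:
                raise ValueError("parent has more QTL than requested for the nested trait")
            extra = rng.choice(np.setdiff1d(pool_pos, prev), size=n_qtl_or_pairs - prev.size, replace=False)
            sel = np.sort(np.concatenate([prev, extra]))
        else:
            sel = np.sort(rng.choice(pool_pos, size=n_qtl_or_pairs, replace=False))
        eff = pool.additive_effects[sel] if scenario == "additive" else pool.dominance_effects[sel]
        return TraitArchitecture(
            scenario,
            target_h2,
            seed,
            qtl_indices=pool.marker_indices[sel],
            effects=eff.copy(),
            pool_indices=pool.marker_indices.copy(),
        )

    pairs = rng.integers(0, M.n_markers, size=(n_qtl_or_pairs, 2))
    dup = pairs[:, 0] == pairs[:, 1]
    while dup.any():  # pairs are between distinct loci; duplicates across draws are allowed
        pairs[dup, 1] = rng.integers(0, M.n_markers, size=int(dup.sum()))
        dup = pairs[:, 0] == pairs[:, 1]
    levels = sorted(M.levels) if not M.is_continuous else [0.0, 1.0, 2.0]
    configs = np.column_stack(
        [rng.choice(levels, size=n_qtl_or_pairs), rng.choice(levels, size=n_qtl_or_pairs)]
    )
    return TraitArchitecture(
        scenario,
        target_h2,
        seed,
        pairs=pairs,
        configurations=configs,
        effects=rng.standard_normal(n_qtl_or_pairs),
    )


@dataclass(frozen=True)
class SimulatedTrait:
    """Phenotypes plus the standardized genetic values they were built from."""

    phenotypes: Phenotypes
    genetic_values: np.ndarray
    errors: np.ndarray
    architecture: TraitArchitecture

    @property
    def realized_heritability(self) -> float:
        """Sample Var(g) / Var(g + e) before the final re-standardization."""
        g, e = self.genetic_values, self.errors
        return float(np.var(g) / np.var(g + e))


def genetic_values(M: MarkerMatrix, arch: TraitArchitecture) -> np.ndarray:
    """Raw (unstandardized) genetic value of each individual under ``arch``."""
    X = M.values
    if arch.scenario == "additive":
        return X[:, arch.qtl_indices] @ arch.effects
    if arch.scenario == "dominance":
        return (X[:, arch.qtl_indices] == 1.0) @ arch.effects
    g = np.zeros(M.n_individuals)
    for (j, k), (cj, ck), eff in zip(arch.pairs, arch.configurations, arch.effects):
        g += eff * ((X[:, j] == cj) & (X[:, k] == ck))
    return g


def simulate_trait(M: MarkerMatrix, arch: TraitArchitecture, seed: int | None = None) -> SimulatedTrait:
    """Build a phenotype with broad-sense heritability ``arch.target_h2``.

    Genetic values are standardized to mean 0 / variance 1, errors are drawn
    N(0, (1 - h2)/h2) — variance 0.25 at the default h2 = 0.8 — and the sum is
    re-standardized to mean 0 / variance 1.
    """
    g = genetic_values(M, arch)
    sd = g.std()
    if sd == 0:
        raise ValueError("genetic variance is zero (no causal locus segregates)")
    g = (g - g.mean()) / sd
    rng = np.random.default_rng(np.random.SeedSequence([arch.seed if seed is None else seed, 7]))
    e = rng.normal(0.0, np.sqrt(arch.error_variance), size=g.size) if arch.target_h2 < 1 else np.zeros_like(g)
    y = g + e
    y = (y - y.mean()) / y.std()
    return SimulatedTrait(Phenotypes(M.individual_ids, y), g, e, arch)


def drop_qtl_markers(M: MarkerMatrix, arch: TraitArchitecture) -> MarkerMatrix:
    """Remove the QTL-pool columns before building relationship matrices.

    Additive/dominance scenarios drop the whole pool the trait was drawn from;
    epistatic traits keep all markers (in expectation every marker takes part
    in some causal combination, so there is nothing meaningful to remove).
    """
    if arch.scenario == "epistasis" or arch.pool_indices is None:
        return M
    keep = np.setdiff1d(np.arange(M.n_markers), arch.pool_indices)
    return MarkerMatrix(
        M.values[:, keep],
        M.individual_ids,
        tuple(M.marker_ids[j] for j in keep),
        M.levels,
        coding_tag=f"{M.coding_tag}; dropped {arch.pool_indices.size} QTL-pool markers",
    )
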