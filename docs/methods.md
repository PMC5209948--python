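# Methods

## Models

All models are linear mixed models `y = 1μ + g + ε` with `g ~ N(0, σ²_g K)`
and `ε ~ N(0, σ²_ε I)`, differing only in the relationship matrix `K` built
from the `n × p` marker matrix `M` (individuals × loci, integer codings such
as {0,1} or {0,1,2}):

- **GBLUP** (additive): `G = M M′`. Equivalent to ridge regression on marker
  effects with penalty `λ = σ²_ε / σ²_β`; predictions are invariant under
  translations of the coding at fixed `λ`, and under rescaling by `c` when
  `λ` is multiplied by `c²`.
- **EGBLUP** (pairwise-product epistasis): the interaction covariates are
  `M_ij M_ik` for all pairs `j ≥ k` (self-pairs included, which lets the
  model absorb dominance). The equivalent kernel is
  `H = 0.5 (MM′ ∘ MM′) + 0.5 (M∘M)(M∘M)′` (`∘` = Hadamard product).
  Scaling invariance survives with the ratio adapted by `c⁴`; translation
  invariance does **not** — the coding choice changes the effect model, which
  is the central phenomenon this package makes executable. The only coding
  indifferent to which allele is counted is the symmetric one
  ({−c, c} binary, {−c, 0, c} three-level).
- **CM** (categorical marker): genotype states are dummy variables with i.i.d.
  normal effects; the kernel `C` counts loci in identical state. For binary
  markers in {−1, 1} coding, `C = 0.5 (MM′ + J p)`, so CM's predictions
  coincide with GBLUP's there (the implementation counts state matches via
  indicator blocks, which also covers three-level data; the
  `p − Σ|ΔM|` form is kept as a test oracle for {0,1} input).
- **CE** (categorical epistasis): dummy variables for two-locus configuration,
  kernel `C_E = 0.5 C∘C + 0.5 C` (self-pairs included; an option excludes
  them, giving `0.5 C (C−1)`). Orientation-free by construction.
- **Gaussian kernel**: `exp(−b d_il)` on squared Euclidean distances with the
  median heuristic `b = 2/q₀.₅` by default; translation invariant, and scale
  invariant when `b` is divided by `c²`.

Kernels are not trace-normalized: global kernel scale is absorbed by the
variance-component ratio, and normalizing would only obscure the coding
effects under study.

## Estimation and prediction

Variance components are estimated by REML on the **training kernel only**:
the intercept is projected out with an orthonormal complement basis, the
projected kernel is eigendecomposed once, and the restricted likelihood —
profiled over `σ²_g` — is maximized over `log λ` on `[1e−5, 1e5]` by an
81-point grid plus bounded refinement. Results at the search boundary are
flagged; a constant phenotype vector returns a degenerate (0, 0) result.

Prediction uses the relationship-matrix form of the mixed-model equations,
with individuals ordered training-then-test, the 1/0 diagonal `T_train`, the
all-ones training block, and the centered training phenotypes padded with
zeros as right-hand side. The system is rearranged as
`[K (T − s⁻¹J) + λI]⁻¹ K r`, algebraically identical to the form with `K⁻¹`
but defined also for PSD singular kernels (e.g. `G = MM′` with `p < n`);
an optional jitter of `1e−8 · mean(diag K)` exists for genuinely singular
systems. The reported fixed effect is the mixed-model intercept
`μ̂ = ȳ_train − mean(ĝ_train)`, which makes `μ̂ + ĝ` agree with the
marker-effect (ridge) predictions to numerical precision — the equivalence
the test suite asserts at 1e−8.

Pairwise interaction effects are recovered by the standard BLUP back-solution
`ĥ_kl = σ²_h z′_kl V⁻¹ (y − 1μ̂)` with `z_kl = M_{·,k} ∘ M_{·,l}`,
`V = σ²_h H + σ²_ε I` and the GLS intercept; the whole table is one
`M′ diag(w) M` product. The full mixed-model-equation solve with the explicit
pairwise design is the test oracle.

## Coding theory as code

`interaction_weight_table` maps a coding to the implicit weight grid
`a_rs = c_r c_s`. `solve_coding_from_weights` inverts three prescribed
weights: magnitudes from a 3×3 log-linear solve, signs by enumeration. The
sign analysis is sharper than "unique up to a global flip": flips that
preserve every given product survive, so the solution set has exactly two
elements only when the off-diagonal positions sign-connect all three coding
values (e.g. {a₁₁, a₁₂, a₂₃}); with two squares and one product (e.g.
{a₁₁, a₃₃, a₁₂}) four codings satisfy the inputs and all are reported.

`expected_orientation_loss` enumerates the (here 2² = 4) orientation outcomes
of two binary loci exactly — enumeration is cheap and reproduces printed
arithmetic without Monte-Carlo noise. The minimizing scalar effect for model
table `W` against true table `T` is the closed form `⟨W,T⟩/⟨W,W⟩` (zero when
`W = 0`), guarded in the tests by a dense grid search.

## Coding adaptation from prior records

Given records of a source trait: back-solve all `ĥ_kl` under the original
coding and all `h̃_kl` with every marker's orientation inverted
(0↔1, or 0↔2 with the heterozygote fixed); keep the original orientation for
a pair iff `|ĥ_kl / h̃_kl| ≥ 1` (ties, including 0/0, keep the original);
rebuild the kernel as the sum of per-pair kernels
`(M_{·,k} M′_{·,k}) ∘ (M_{·,l} M′_{·,l})` with both columns of each pair in
its assigned orientation. Only the two all-or-nothing orientations per pair
are compared — mixing one original with one inverted marker would couple the
decision across pairs. Each pair kernel is `u u′` with `u = m_k ∘ m_l`, so
the sum is accumulated blockwise in O(p²n) memory-bounded matmuls; with every
pair "original" it equals the EGBLUP kernel exactly. Variance components for
the adapted kernel are re-estimated on the target trait's training folds.

## Synthetic data

The genotype generator is a deliberately simple stand-in for a forward
simulator. Founder haplotypes are drawn from a Gaussian-copula AR process
along each chromosome (correlation `exp(−d/10 cM)`, thresholded at
Beta(0.5, 0.5)-distributed allele frequencies), a finite founder pool
(default 100 haplotypes) seeds the population, and a small number of
random-mating generations (default 5) recombine at Haldane rates derived from
the map lengths. Default chromosomes are five, of 140/110/80/50/20 cM with
3500/2750/2000/1250/500 markers; `GenotypeSimConfig.scaled` shrinks the
marker counts proportionally. Columns falling below the MAF floor
(default 0.05) are resampled independently. The generator emulates LD decay
with map distance and a MAF floor — not any specific demography, mutation
process or replacement scheme; passing model-comparison tests therefore
speak to the statistical structure (linkage, architecture, heritability),
not to any particular population history.

Traits: a fixed QTL pool (default: equal numbers per chromosome) carries
pre-drawn N(0,1) additive and dominance effects so traits with 10 ⊂ 100 ⊂ ...
QTL are exactly nested; dominance values are `effect · 1[heterozygote]`
(the canonical purely dominant parameterization, keeping the scenarios
maximally distinct); epistatic traits give each of a set of random marker
pairs one uniformly chosen ordered two-locus configuration with an N(0,1)
effect (pairs drawn with replacement; duplicates simply add). Genetic values
are standardized to mean 0/variance 1, errors are N(0, (1−h²)/h²) — variance
0.25 at the default h² = 0.8 — and phenotypes are re-standardized. For
additive/dominance traits the whole QTL pool is removed before kernels are
built (prediction must run through LD); epistatic traits keep all markers.

## Study sizes used by the tests

The desk-scale model comparison uses ten independent populations of n = 500
with p = 2000 markers, a 200-QTL pool, 100-QTL additive and dominance traits,
a 500-pair epistasis trait, and 10 hold-out repeats (10% test sets) per
kernel — a proportional shrink of the full design (n = 1000, p = 10 000,
1000-QTL pool, 200 repeats, 20 populations) chosen so the whole ladder runs
in about two minutes. The directional outcomes (categorical models ahead on
dominance/epistasis, GBLUP ≈ EGBLUP on additive, frequency-standardized
EGBLUP last) are stable at this size; absolute correlations are lower than a
full-scale run would give, and no numeric equality with full-scale results is
asserted. Heritability calibration uses one population of n = 10 000.

## Numerical choices and edge cases

- PSD checks tolerate smallest eigenvalues down to −1e−8 of the largest;
  kernels are symmetrized exactly on construction.
- REML requires ≥ 10 training individuals; eigenvalues are clipped at zero.
- Orientation inversion is `v ↦ max(levels) − v`, forcing the heterozygote
  fixed for three-level codings; it rejects continuous (centered) matrices.
- Binary {0,1} markers use the column mean as allele frequency
  (presence/absence convention); three-level dosages use mean/2.
- Allele-frequency centering subtracts `2p_j` only; the optional global
  variance divisor is off by default since a global scalar is absorbed by
  the variance ratio.
- Loaders reject missing values outright; imputation is out of scope.
- Degenerate cross-validation repeats (zero test-set variance) are excluded
  and counted, never silently averaged.

## Known limitations

- One kernel at a time: no multi-kernel (additive + epistasis) REML, which
  is prone to confounding when the kernels are similar.
- The intercept is the only fixed effect; covariates must be pre-corrected.
- O(p²n²)-flavored pair accumulation makes per-pair adapted kernels
  impractical beyond a few thousand markers (the CLI warns above 2000).
- The genotype generator's LD is qualitative; linkage phase, mutation and
  demography are not modeled.
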