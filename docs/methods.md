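# Methods

## The model

`dairyfert` estimates genetic parameters for dairy-cattle fertility traits
with the pedigree-based animal model

```
y = Xb + Z_hy u_hy + Z_ss u_ss + Z_a a + e

a    ~ N(0, A  σ²_a)      additive genetic effects, one per pedigree animal
u_hy ~ N(0, I  σ²_hy)     herd × birth-year contemporary groups
u_ss ~ N(0, A_ss σ²_ss)   service-sire effects (GL and NRR only)
e    ~ N(0, I  σ²_e)
```

`A` is the numerator relationship matrix implied by the pedigree
(diagonal `1 + F`, `F` the inbreeding coefficient) and `A_ss` its
restriction to the service sires, computed through the full pedigree.
Heritability is reported as

```
h² = σ²_a / (σ²_a + σ²_hy + σ²_ss + σ²_e)
```

with every fitted random component in the denominator — this is the
denominator that reproduces the published heritability values from their
printed variance components to four decimals, so it is adopted throughout.

The two-trait (heifer/cow) model stacks the stage records with 2×2
covariance blocks: `Var(a1, a2) = G ⊗ A`, herd-year `H ⊗ I`, service sire
`S ⊗ A_ss`, and a residual that is correlated only within animals carrying
a record at both stages.  The genetic correlation is
`r_g = G12 / √(G11·G22)`.

Nine traits are supported: calving interval (CI), days open (DO), calving
to first insemination (CTFS), first insemination to conception (FSTC),
gestation length (GL), age at first service (AFS), age at first calving
(AFC), number of services (NS), and the 56-day non-return rate (NRR).
NRR and NS are binary/count traits but are fitted with the same linear
model as the intervals; for non-extreme binary traits the difference from
a threshold model is small, and the linear analysis is what the
heritability magnitudes here refer to.

## Data editing and trait derivation

Records arrive as one event record per cow × parity (parity 0 is the
heifer episode).  The editing order is fixed: merge/deduplicate →
derive traits → match to pedigree → outlier filter → effect classes.

- **Deduplication** collapses exact duplicate cow × parity rows;
  duplicates that disagree in any field are treated as recording errors
  (one cow number attached to inconsistent information) and *all* copies
  are dropped.
- **Intervals** are day counts anchored on the calving that opens the
  episode: CI = calving − previous calving, DO = conception − previous
  calving, CTFS = first insemination − previous calving,
  FSTC = conception − first insemination (0 when conception occurs at
  first service), GL = calving − conception, AFS/AFC = first
  insemination/first calving − birth.  NS counts inseminations up to and
  including conception.
- **NRR** codes 1 when no further insemination falls within 56 days of
  the anchor. The anchor is configurable — first insemination (default,
  the conventional definition) or the opening calving — and so is the
  success value, because the field literature states the trait both ways.
- **Outlier filter**: a single two-sided pass keeping
  `|y − mean| ≤ 4·SD` (SD with n−1), applied per trait × stage.  Sidedness
  and `k` are configurable; the one-pass two-sided version is the
  deterministic default.
- **Effect classes** are string-joined composites (region × birth year ×
  birth month; previous-calving age class × month × parity; etc.), with
  calving-age classes binned in whole months.  Fixed-effect classes with
  fewer than 3 observations (configurable) merge into a per-effect
  `OTHER` level so the mixed-model equations stay well conditioned.

The per-trait fixed/random layout (which traits carry which composite
effects and whether the service sire is fitted) ships as
`dataprep.DEFAULT_SPECS`.

## Pedigree algebra

Inbreeding coefficients use the Meuwissen–Luo path recursion, which also
yields the within-family (Mendelian-sampling) variance coefficients
`d_i = 0.5 − 0.25(F_s + F_d)` (1 for founders, `0.75 − 0.25F` with one
parent known).  `A⁻¹` is built directly by Henderson's rules with the
inbreeding (Quaas) adjustment — contributions `1/d_i · {1, −½, ¼}` — and
`log|A| = Σ log d_i` falls out for free, which REML needs.  Unknown
parents are unrelated, non-inbred founders; no genetic groups are fitted.
Dense `A` (tabular method) is guarded at 5,000 animals; estimation never
needs it.  Service-sire submatrices are extracted exactly through the
full pedigree via the factorization `A = (I−P)⁻¹ D (I−P)⁻ᵀ` (two sparse
triangular solves per sire), then inverted densely — sire sets are small.

## REML

The restricted likelihood is evaluated through Henderson's mixed-model
equations, never forming the dense phenotypic covariance:

```
−2ℓ_R = (n−p)·log 2π + log|R| + log|G| + log|C| + y'Py
```

with `C` the coefficient matrix on the R⁻¹ scale and
`y'Py = (y'y − sol'·rhs)/σ²_e`.  Residual variance is profiled out, so the
single-trait optimization runs over log variance *ratios* only.

The optimizer is staged:

1. **EM warm start** — exact expectation–maximization updates using the
   prediction-error covariance from a dense inverse of `C`.  Monotone by
   construction, but the traces cost a dense inverse, so this stage only
   runs while the system has ≤ 600 equations (configurable).
2. **Nelder–Mead** on the profiled likelihood over log ratios — cheap,
   derivative-free globalization (each evaluation is one sparse
   refactorization).
3. **Newton polish with the average-information (AI) matrix** — the AI
   matrix needs only extra MME solves with the current factorization;
   the score comes from central finite differences.  Convergence is
   declared on relative parameter change < 1e−8 or likelihood
   improvement below 1e−9·(1+|−2ℓ|); a Newton step that cannot improve
   the likelihood at finite-difference resolution also terminates.

Components that collapse are pinned at a floor of 1e−8 × phenotypic
variance and flagged (`floored`), never allowed negative — so a trait
with no usable genetic signal reports `h² = 0.0000` with a standard
error, exactly the behavior real fertility analyses show for NS in cows.
Standard errors come from the inverse AI matrix evaluated at the optimum
(floored components included); the heritability SE uses the delta method
on the variance-ratio gradient.  Fixed effects are made full rank by
keeping all levels of the first effect and dropping the first level of
each subsequent one; REML is invariant to that choice.  Default starting
values give each random component 10% of the phenotypic variance.

### Sparse linear algebra

REML iterates factor/solve on a matrix whose sparsity pattern never
changes — only the variance ratios scaling the `K⁻¹` blocks move.  The
package therefore carries a small sparse LDLᵀ kernel
(`dairyfert._sparse_ldl`): the up-looking algorithm of Davis's LDL,
JIT-compiled with numba, with the symbolic analysis (elimination tree,
column counts) done once per pattern and an elimination order taken from
one multiple-minimum-degree analysis.  All coefficient-matrix components
(cross-products and padded `K⁻¹` blocks) are pre-aligned onto the union
pattern, so one likelihood evaluation is a vector combination plus an
`O(nnz(L))` numeric refactorization — a few milliseconds at 5,000–12,000
equations, where a from-scratch factorization costs tens of
milliseconds.  The kernel is verified against SuperLU log-determinants
and solves in the test suite.

## Two-trait estimation

Parameters are the unique elements of the 2×2 blocks (`G`, `H`, `S` when
the trait carries a service-sire effect, and `R`).  Estimation is
AI-REML: Newton steps with the average-information matrix (working
variates need only solves against the current factorization), central
finite-difference scores, a Marquardt damping ladder when the raw AI
step fails, and after every accepted update a projection of each block
back to the PSD cone by eigenvalue clipping at 1e−8 of its
geometric-mean variance.

Two behaviors specific to near-degenerate fertility traits:

- **Residual covariance identifiability.**  Heifer and cow records of the
  same animal are sequential in life; `R12` is estimable only through
  double-recorded animals.  With fewer than 30 of them (configurable)
  `R12` is fixed at 0 and the result flagged `residual_cov_fixed`.
- **Boundary handling.**  With per-mille heritabilities the likelihood is
  nearly flat in `r_g` and the PSD projection pins `G` to the `|r_g| = 1`
  boundary; Newton steps then degenerate into slow creep along the cone.
  When the projection has been active for three consecutive iterations
  and the likelihood improves by less than 0.2, iteration stops and the
  solution is flagged `near_boundary`.  Delta-method `r_g` standard
  errors at such solutions are huge — which is precisely what published
  two-trait NRR analyses show (an `r_g` near 1 with an SE in the
  thousands of percent) — so the flag, not the SE, is the signal to read.

Single-trait fits supply the starting diagonals, floored at 0.1% of the
stage phenotypic variance so that a floored single-trait component cannot
hand the two-trait fit a degenerate start.  `merge_traits` concatenates
the stages with stage as an extra fixed effect, for traits whose stage
correlation is high enough to treat as one trait.

## Synthetic data

The generator replaces the proprietary herd data at every scale of
verification.

- **Pedigrees**: discrete generations, heavy sire reuse (AI half-sib
  families), configurable founder counts and sex ratio.  A separate
  unstructured `random_pedigree` stresses the matrix algebra.
- **Breeding values** by the Mendelian-sampling recursion
  `a_i = ½(a_s + a_d) + m_i`, `Var(m_i) = d_i σ²_a` — exact under `A` in
  linear time (no dense Cholesky); the bivariate version draws Mendelian
  terms with covariance `d_i G`.  Equivalence with the covariance-matrix
  route is checked empirically in the tests.
- **Trait datasets** drawn directly from the linear model for
  estimator-recovery studies, with uniform herd-year and fixed-class
  assignment.
- **Event timelines** for pipeline tests: inseminations, conceptions and
  calvings are placed so the date arithmetic reproduces the drawn
  interval values exactly (intervals are integers ≥ their biological
  floor); NS comes from a capped geometric conception draw; the 56-day
  non-return outcome is decided on a standardized liability whose
  variance shares follow the trait's components, then realized
  deterministically in the dates (early return 18–45 d, late 57–90 d; a
  return forces a re-insemination).  Duplicate and corrupted-duplicate
  records are injected at configurable rates to exercise deduplication.

Default variance magnitudes sit at the published Holstein fertility
values (`simulate.TRAIT_TRUTH_DEFAULTS`): AFC-like h² ≈ 0.19, CI-like
≈ 0.012, NRR at per-mille heritability with service-sire variance an
order of magnitude above the genetic variance.

What the generator does **not** emulate: culling and open cows (every
female conceives eventually), seasonal heat-stress patterns, herd
demography drift, pregnancy loss, and recording-system quirks beyond
duplicate rows.  Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to real-data model
violations.

## Replicate studies and problem sizes

`studies.recovery_study` fits 50 replicates of 5,000 phenotyped females
(two generations from 500 founders, 25 sires per generation, 200
herd-year classes, 12 fixed classes).  `studies.nrr_bivariate_study`
fits 20 replicates of 10,000 records (5,000 heifer + 5,000 cow, 20% of
animals double-recorded, 12 sires per generation, 40 service sires).
Replicates share one pedigree and one design (class assignments, record
layout) and re-draw every random effect — a conditional-on-design
simulation, which is the standard way to study an estimator's sampling
behavior for a given data structure and what allows the symbolic
factorization to be reused across replicates.  At these sizes the full
single-trait study runs in under a minute and the two-trait study in a
few minutes on one core.

## Numerical choices

- Likelihood constants are kept, so values are comparable with textbook
  dense-V formulas to ~1e−9 relative (tested).
- Log-determinants come from LDLᵀ pivots; a non-positive pivot raises
  (or returns +∞ inside optimizers) rather than silently continuing.
- Finite-difference scores use central differences with steps of 1e−4 ×
  a per-parameter scale (`√(P_ii·P_jj)` for covariance elements); the
  AI matrix, not the FD Hessian, provides curvature.
- Ties in topological sorting break by input order; effect levels sort
  lexicographically — estimates are invariant to record order and level
  relabeling (tested).
- Dates are ISO-8601; all interval arithmetic is integer days.

## Known limitations

- No threshold-model REML for the categorical traits; the linear model is
  the deliberate scope.
- No genetic groups for unknown parents, no genomic relationships.
- The two-trait engine assumes at most one record per animal per stage.
- `r_g` standard errors at the PSD boundary are delta-method
  extrapolations and should be read only through the `near_boundary`
  flag.
- Heat-stress covariates (temperature–humidity index) are out of scope.
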