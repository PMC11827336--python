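# Methods

This note documents the statistical models in `cloneval`, the choices the
implementation makes where several defensible options exist, and what the
synthetic data generator does and does not emulate.

## The cloned progeny trial model

A CPT plants every candidate genotype (ortet) as several vegetative
copies (ramets) in alpha-lattice sub-trials replicated across sites. The
observation model behind both the simulator and the fitted analyses is

    y = site/trial structure + a + d + aE + dE + spatial residual,

where `a` is the additive (breeding) value, `d` the dominance deviation,
`aE`/`dE` their site-specific interactions, and the residual field within
a sub-trial is correlated across the planting grid.

All genetic covariances are kernel-based: `a ~ N(0, σ²_A G*)` with
`G* = α Ga + (1−α) A22`, `d ~ N(0, σ²_D Gd)`, and the interaction terms
use the same kernels block-diagonally per site (kernel ⊗ identity over
environments). Clones enter through the kernels: ramets of one ortet map
to a single kernel row, so their genetic effects are identical by
construction.

### Relationship matrices

- `A` by the tabular method over the corrected pedigree; unknown parents
  contribute zero, so non-inbred founders have diagonal exactly 1.
- `Ga = ZZ'/(2Σ p_j(1−p_j))` with `Z` the dosage matrix centred at
  `2p_j`; the counted allele is anchored to the second most frequent one
  (columns with `p > 0.5` are re-coded `d → 2−d`).
- `Gd = SS'/(4Σ (p_j(1−p_j))²)` with the centred dominance coding
  `S(0) = −2p²`, `S(1) = 2p(1−p)`, `S(2) = −2(1−p)²`, which has mean zero
  under Hardy–Weinberg proportions.
- Missing calls: per-marker mean imputation before centring for `Ga`; a
  missing call contributes its zero expectation to `S`. Allele
  frequencies are estimated once per ortet (clones are not re-counted per
  ramet) unless supplied.
- Blending weight α defaults to 0.98 and is applied to `Ga` only — the
  singularity problem the blend addresses (clones, markers ≪ genotypes)
  concerns the additive kernel; a flag allows blending `Gd` if wanted.

## REML engine

Variance components maximise the restricted likelihood of
`y = Xb + Σ_k Z_k u_k + e` computed densely:

    ℓ_R = −½ [ log|V| + log|X'V⁻¹X| + y'Py + (n−p) log 2π ].

- **Updates.** Average-information (AI) steps with an active set:
  components pinned at the lower floor (1e−8 × phenotypic variance) whose
  gradient points outward are fixed there and the reduced AI system is
  solved for the rest, with step halving against the likelihood. A naive
  clamped AI step is *not* an ascent direction near the boundary and was
  observed to stall the fit; the active-set variant converges in under
  ~15 iterations on all problems in the test suite. When no AI step
  improves the likelihood, an EM-type scaled-gradient step
  `σ² ← σ² + (σ⁴/q)(y'PQPy − tr(PQ))` with step halving is taken; the
  restricted log-likelihood is non-decreasing along these fallback steps.
- **Convergence.** Relative log-likelihood change < 1e−8 *and* relative
  component change < 1e−6; at most 200 iterations, after which the last
  iterate is returned with `converged=False` and a warning.
- **Starting values.** Equal split of the phenotypic variance across
  components unless supplied.
- **AR1×AR1 residuals.** The spatial correlations (ρ_col, ρ_row) are
  profiled by Nelder–Mead over (−0.99, 0.99)² with inner component
  updates warm-started between evaluations — slower than joint AI updates
  but robust for the small per-sub-trial problems it is used on. No sign
  constraint is imposed (estimates near zero, slightly negative, are
  legitimate outcomes).
- **BLUP/PEV.** At the final components, `û = σ² K Z'Py` and
  `PEV = diag(σ²K − σ⁴ K Z'PZ K)`, clipped to `[0, σ²K_ii]`. Accuracy
  uses the mean PEV diagonal, `r = √(1 − PEV̄/σ²)`; per-clone reliability
  is `1 − PEV_i/σ²` without the square root.

Everything is dense (LAPACK Cholesky + `dpotri`), sized for thousands of
observations on one core, which covers the per-sub-trial and
across-environment models at the scales this package targets.

## Stage-wise evaluation

**Stage 1**, per sub-trial × site: genotype fixed; replication and
incomplete block random (identity covariance); residual
`σ²_ξ · AR1(ρ_col) ⊗ AR1(ρ_row)` over the planting grid. The design
matrix is the genotype incidence itself, so the BLUEs are directly the
adjusted genotype means on the trial scale. Rows with missing phenotypes
(mortality) are dropped, not imputed.

**Stage 2**, on the stacked adjusted means: site fixed;
trial-within-environment, additive (`G*`), dominance (`Gd`),
additive×site and dominance×site random; iid residual. Adjusted means are
passed unweighted (an optional precision weighting is a user choice, not
the default). Non-genotyped clones are dropped with a logged count —
single-step evaluation of ungenotyped trees is out of scope.

Genetic parameters: `σ²_P = σ²_A + σ²_D + σ²_t + σ²_aE + σ²_dE + σ²_e`;
`h² = σ²_A/σ²_P`; `δ² = σ²_D/σ²_P`; `H² = h² + δ²`. Selection response:
genotypes are ranked by predicted genotypic value `a + d` (ties broken by
identifier); `S = x̄_s − x̄_0` on the phenotypic scale, `i = S/σ_P`,
`ΔR = S·H²`, reported also as `100·ΔR/x̄_0`. Whether `σ_P` refers to the
dm³ scale or the z-scale is a reporting choice; both the raw differential
and the intensity are returned so either convention can be applied.

## Replicate-reduction study

For each k from the number of available replicates down to 1, all
C(total, k) replicate combinations are refit with the single-stage model:
site, sub-trial-within-site and replication-within-sub-trial fixed
(encoded as the finest nested cells, which span the same space);
incomplete block random; additive and dominance kernel terms; residual
variance heterogeneous by site (direct-sum block diagonal). Its
phenotypic variance is `σ²_a + σ²_d + σ²_b + (σ²_e1 + σ²_e2)/2`.
Per-combination rankings by `a + d` are aggregated by the Mulamba–Mock
rank sum (ties broken by clone identifier, so aggregated positions are a
full permutation); coincidence `R(%) = 100·C/S` compares the aggregated
top-n with the full-replication reference, and the minimum selection size
is the worst aggregated position among the reference top-10.

## The synthetic generator

Defaults reproduce the structure of the motivating study: 48 founders, 47
open-pollinated (half-sib) + 11 controlled-cross (full-sib) families × 60
progeny (3,480 genotypes, 3,142 surviving), 5 ramets per ortet, 16×16
alpha-lattice sub-trials of 256 treatments (250 progeny + 6 shared
unrelated control clones), 11 and 12 sub-trials at two sites, ~80% of
clones genotyped, and true variance components equal to the published
stem-volume estimates (additive 250.76, dominance 365.14, trial 796.16,
a×E 37.47, d×E 6.28, residual 200.39 per site; trait mean 52.36 dm³).
Spatial autocorrelations default to the averages of the reported per-site
estimates (−0.01 columns, −0.085 rows); the nugget defaults to zero
because the fitted first-stage model carries no nugget term.

Generator choices where the design was open:

- **Marker model.** Founder genotypes are Hardy–Weinberg draws at
  frequencies uniform on the configured MAF range; progeny by Mendelian
  gene dropping (no linkage, no LD, no selfing). Additive/dominance
  marker effects are i.i.d. normal on the centred dosage and dominance
  codings, then rescaled so the realized genotype-level variance equals
  the configured component exactly — parameter-recovery tests therefore
  test the estimator, not the generator's sampling noise.
- **Hidden pollen parents** of half-sib progeny are drawn uniformly from
  the founders and recorded only in the truth pedigree; the declared
  pedigree masks them, creating exactly the undeclared relationships the
  pedigree-correction step must recover.
- **Layout.** Each replicate is a block_size × block_size grid; replicates
  are tiled side by side; treatments are placed uniformly at random per
  replicate and each grid column is one incomplete block (a uniform
  random partition — a resolvable alpha-design generator is out of
  scope). Spacing is 2.5 m within and 3.6 m between rows.
- **Field measurements.** Heights are drawn N(20, 2.5²) m; CBH is back-
  computed so the volume formula `VOL = (CBH²π/40000)·TH·ST` (ST = 0.45)
  reproduces the simulated volume exactly, with a 0.5 dm³ floor.
- **Genotyping artifacts.** Missing calls and dosage flips are i.i.d.;
  markers split into a shared fraction plus platform-private remainders;
  a fraction of panel-B markers is re-coded on the opposite reference
  allele to exercise harmonization.

What the generator does **not** emulate: linkage/LD and recombination
hotspots, inbreeding depression, platform-specific clustering artifacts,
soil/terrain covariates, or non-random mortality. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every feature of real field data.

## Problem sizes in the test suite

The test and acceptance suites run the same machinery at reduced scale,
chosen for statistical stability of each check: genomic-matrix and REML
oracles at n ≤ 20; parameter recovery on 500–1,000 genotypes over 30
seeds; the replicate-reduction sweep on ~200 genotypes (two sub-trials
per site, 64 treatments) over 10 seeds — at ~90 genotypes the additive/
dominance split is too unstable to show the expected monotone trends;
design-count checks run the full study-scale layout with a thinned marker
panel, since the counts do not involve markers.

## Known limitations

- Dense algebra bounds practical problem size (~5,000 observations).
- The Mendelian-error threshold is applied per pair, not per marker.
- Stage-2 passes unweighted adjusted means; heteroscedastic stage-1
  precision is ignored unless the optional weighting is enabled.
- No multi-trait models, factor-analytic G×E, spatial splines, or
  single-step (H-matrix) evaluation.
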