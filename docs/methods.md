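# Methods

## Model

A cell's TF-IDF-normalized accessibility profile **y**ⱼ ∈ ℝᵖ is modeled
as Gaussian around a low-rank mean:

    y_j | λ_j ~ N_p(λ_j, σ² I_p)
    λ_j = β x_j + W₁ h_j1 + W₂ h_j2 + W₃ h_j3

with covariates **x**ⱼ ∈ ℝ^q (all-ones intercept first; additional rows
one-hot donor/batch indicators), coefficients β (p × q), and three latent
blocks:

| block | loadings | score prior | role |
|---|---|---|---|
| shared | W₁ (p × K₁), **fixed** PCA loadings of the reference | h ~ N(0, 1) | variation shared with bulk / pseudo-bulk reference |
| unique | W₂ (p × K₂), w_k ~ N(0, α_k⁻¹I) | h &#124; γ ~ (1−γ)N(0, τ₀²) + γN(0, τ₁²), γ ~ Bern(θ) | distinct, typically rare subpopulations the reference lacks |
| other | W₃ (p × K₃), w_k ~ N(0, α_k⁻¹I) | h ~ N(0, 1) | residual structured/technical variation (discarded downstream) |

Assumptions worth stating plainly: noise is homoscedastic and Gaussian
(TF-IDF values are neither, but the approximation holds up for cell-level
analysis); the reference spans the *shared* biological variation after a
transform that matches the single-cell normalization; rare-subpopulation
structure is axis-aligned in the W₂ block with at most ~θ of cells active
per component.

### Scale semantics

The priors give the model an absolute scale: shared scores are meant to
be O(1), and a slab activation under the defaults requires a squared
score above

    E(h²) ≥ (2 log(τ₁/τ₀) + 2 log((1−θ)/θ)) / (τ₀⁻² − τ₁⁻²) ≈ 6.55,

i.e. |score| ≳ 2.6. The pipeline therefore rescales Y by a single global
scalar so that the cells' scores on the reference basis have unit
standard deviation. Raw TF-IDF entries (~10⁻³) would put every score in
the spike; an over-wide scale makes the standard-normal prior shrink the
shared scores and the slab then absorbs the leftover shared variation
cell by cell — both failure modes were observed directly while
calibrating, and both disappear under score-scale standardization.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| τ₀ | 0.9 | spike sd (< 1): inactive unique scores |
| τ₁ | 5 | slab sd (> 1): active unique scores |
| θ | 0.1 | prior slab probability ≈ expected rare fraction |
| K₁ | m − 1, capped at 30 | reference components (m = reference samples) |
| K₂, K₃ | 5 | unique / other components |
| rel_tol | 1e-6 | relative objective change at convergence |
| max_iter | 500 | iteration cap (pipeline experiments use 400) |
| alpha_max | 1e8 | cap on loading precisions (see pruning, below) |

## Fitting

EM with the scores **H** as missing data. The E-step posterior for cell
*j* is Gaussian with covariance (σ⁻²WᵀW + D_j⁻¹)⁻¹, where D_j holds the
prior variances implied by the cell's indicator column; cells sharing an
indicator pattern share one covariance solve. The M-step is iterative
conditional modes in the order Γ → W* → A → β → σ², each block set to its
conditional optimum given the posterior moments and previously updated
blocks.

- The Γ update is an exact two-point maximization per entry; ties break
  toward the spike.
- The W* update uses the cross term E(H₁)E(H*)ᵀ by default. The exact
  posterior cross moment (adding the summed covariance cross-block) is
  available as `HyperParams(exact_cross_moment=True)`; it is the form
  under which the update is exactly stationary, and the stationarity
  tests use it.
- The expected complete log-likelihood Q uses the *linear* diagonal
  second moment E(h_jh_jᵀ)_kk in the score-prior term — the form under
  which the closed-form updates are stationary.
- The **objective trace** records the EM evidence lower bound, Q plus the
  posterior entropy of H. Q alone is not monotone across E-steps (an
  E-step may trade expected complete log-likelihood for entropy; dips of
  ~10⁻² relative were measured), while the bound is monotone to machine
  precision and is what the convergence test and the monotonicity checks
  use. `compute_objective` still returns plain Q.
- **Relevance pruning:** a W₂/W₃ column the data do not support shrinks
  toward zero while its precision α_k = p/‖w_k‖² runs away
  super-exponentially. Precisions are capped at `alpha_max` (the cap sits
  on the concave increasing branch of Q, so monotonicity is unaffected)
  and exactly-zero columns are treated as pruned components rather than
  errors.
- Posterior precision solves use Cholesky with an escalating diagonal
  jitter (10⁻¹⁰ → 10⁻⁶) before failing with the condition number.

### Initialization

W₂ warm-starts at the top-K₂ PCA loadings of the residual
Y − W₁W₁ᵀY, rotated by the varimax rotation of the PC scores — varimax
seeks directions on which few cells score extremely, mimicking the slab.
σ starts at the sd of the residual after removing the combined [W₁, W₂]
projection; A = I, β = 0, slab indicators = 0. W₃ starts at seeded random
Gaussian columns of ~unit norm: starting it at entry-variance 1 (norm
≈ √p) lets the free Gaussian block capture the rare direction before the
spike-and-slab block does, and EM then stays in that local optimum (this
exact failure was observed on one seed in five; unit-norm columns, the
same scale as the warm-started W₂, removed it).

## Preprocessing and reference

- Peaks detected in < 3% of cells are removed (inclusive threshold).
- TF-IDF: the matrix is binarized to accessibility indicators by
  default; TF(i,j) = b(i,j)/(number of accessible peaks in cell j),
  IDF(i) = log(1 + n/df(i)), natural log. Binarization reflects the
  near-binary nature of per-cell accessibility and removes the heavy
  count-noise tail that otherwise feeds spurious slab components; the
  count-based dialect TF = count/depth remains available
  (`binarize=False`). Both preserve zeros and are invariant to per-cell
  depth scaling.
- References: bulk counts scaled by total mapped reads; BED peak files
  counted by ≥1 bp overlap on half-open intervals (strand ignored); or
  pseudo-bulk per-type *averages* of labeled cells (averages, not sums,
  so abundant types carry no extra weight). The pipeline depth-normalizes
  reference rows and weights them by the single-cell IDF before PCA so
  the basis spans the space the model is actually fit in; with an
  unmatched basis, shared variation leaks into the residual and is
  absorbed by the spike-and-slab block (measured as large clustering
  losses). `learn_projection` itself is plain mean-centered PCA with
  K₁ = min(m − 1, p, cap); the full basis is stored so the cap can be
  changed without recomputation.
- Peak-space mismatches are re-binned by ≥1 bp overlap, duplicating (not
  splitting) counts into every overlapping target peak.

## Post-processing and clustering

Each row of E(H₂) is tested against zero mean (two-sided one-sample
t-test, level 0.05, no multiple-testing correction — K₂ is small); rows
failing to reject are dropped, as are numerically dead rows (sd < 10⁻⁸
and |mean| < 10⁻⁶, the residue of pruned components). Surviving rows are
winsorized at their own 5th/95th percentiles (linear-interpolation
percentiles), damping the few noisy low-depth cells that can dominate a
component. The downstream representation is [E(H₁); E(H₂)-post].

Clustering builds an undirected, unweighted 15-nearest-neighbor graph
(Euclidean) and runs Leiden community detection on the
modularity-with-resolution objective (the seedable equivalent of
resolution-tuned Louvain), binary-searching the resolution in
[10⁻³, 10] (≤ 30 halvings, first hit wins) to match a target cluster
count. Row scaling before the metric: the model's latent uses `"cap"`
(center, divide by max(sd, 1)) — components share a unit prior scale, so
slab-activated rows are compressed back to it while rows the model itself
judges weak are *not* inflated into noise dimensions; generic embeddings
(PCA scores, bulk projections) use plain z-scoring, since their component
scales are arbitrary.

Evaluation: ARI, NMI (geometric normalization), AMI (arithmetic
normalization, permutation-model expected MI) and homogeneity via
scikit-learn, verified in the tests against an independent
implementation of the contingency-table formulas; Gini is the population
mean-absolute-difference dialect (one-hot of length m scores (m−1)/m);
RAGI = mean marker-gene Gini over per-cluster mean activities minus the
housekeeping equivalent, with gene activity a transparent windowed sum of
normalized peak values over the gene body ± 50 kb — a documented
simplification whose comparisons are internally consistent even where
absolute values differ from model-based gene scoring.

## Synthetic data

`simulate_gaussian_from_model` draws directly from the generative model
with an orthonormal combined frame and unit-norm free loadings, so
per-direction signal is on the prior's scale. A planted rare
subpopulation loads *coherently* on one W₂ direction (offset 12 ≈ 2.4
slab sd, one shared sign — zero-mean slab draws would cancel across
cells); the offset keeps the planted eigenvalue safely above the
spiked-covariance detection edge (1 + √(p/n))², below which no method
could find the direction, and makes the 15° subspace-recovery check
achievable (the oracle estimation error at this offset is ≈ 12.5°).

`simulate_counts_with_rare_subpopulation` emulates the raw-data regime:
multinomial counts over per-type peak-weight profiles (shared background
plus a private 5%-of-peaks block per common type, boosted 8×), lognormal
depth (median 1000 reads over 2000 peaks ≈ 0.5 reads/peak, the sparsity
regime of real scATAC panels; sd 0.3 on the log), and a pseudo-bulk
reference of per-peak detection rates built from independently simulated
cells of every type *except* the rare one. The rare type shares a common
type's profile except for a private 4%-of-peaks block boosted 12×: under
binarization its extra accessible peaks barely move the cell's total, so
the rare type is nearly invisible to the reference basis, while the
block is individually strong enough that its slab score survives 50%
dropout. `add_donor_effect` thins a donor-specific random peak subset
binomially (keep 1/(1 + effect)) — an accessibility bias that survives
binarization; the covariate A/B experiment plants a severe effect
(7-fold thinning on half the peaks), since milder effects are absorbed
by the W₃ block without any covariates, which is the model working as
designed rather than a test of adjustment.

What the generator does **not** emulate: fragment-level artifacts (Tn5
bias, duplicates, doublets), realistic peak length/GC structure,
continuous differentiation trajectories, or nonlinear manifold
structure. Passing the end-to-end tests therefore shows the
implementation recovers planted linear structure under multinomial
sparsity and dropout — not that the method attains any particular
performance on real tissue atlases.

## Experiment sizes

The packaged experiments use n = 1000 cells × p = 2000 peaks (5 types,
8% rare) for the recovery and dropout studies, n = 600 × p = 1200
(4 types, 2 donors) for the covariate study, and n = 200 × p = 100 for
the EM monotonicity battery; fits cap at 400 iterations and typically
converge in 40–200. These sizes give stable medians across seeds while
keeping the full suite fast on a single CPU.

## Known limitations

- The homoscedastic Gaussian likelihood makes spare slab components
  attracted to heavy-tailed or heteroscedastic noise directions; with
  count-dialect TF-IDF on deeply sequenced data this can fragment a
  common type (the binarized default largely removes the tail, and
  winsorization handles the remainder when extreme cells are < 5%).
- Slab activation has a hard threshold, so rare-type detection degrades
  as a cliff, not a slope, when signal falls with dropout or depth.
- K₁ is bounded by the number of reference samples; with very few
  samples the shared subspace may be too small to carry all common-type
  contrasts, and residual contrasts then compete for slab slots.
- ICM + EM finds local optima; the warm start makes the intended optimum
  typical but not guaranteed (seed-dependent races were observed and are
  mitigated, not eliminated, by the initialization scales above).
- Posterior means, not uncertainty, are propagated downstream.
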