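# Methods

## Model

A chromosome is a chain of `N` spherical beads of diameter `a`; each bead
represents a fixed genomic length (the resolution, default 500 kb). Bead
size follows from an assumed chromatin density of 12 Mb/µm³: the bead
volume is `resolution / density`, giving a radius of ≈215 nm at 500 kb and
≈100 nm at 50 kb. Internally all lengths are expressed in units of `a`
(`a = 1`); conversion to microns happens only at I/O.

The conformational prior is a canonical ensemble
`Pr(X) ∝ exp(−k_nb E_nb − k_bb E_bb)` with

- **backbone**: `E_bb = Σ_i θ(d_{i,i+1} − a)(d_{i,i+1} − a)²`, an
  upper-limit restraint with `k_bb = 250/a²`. Consecutive beads may
  approach freely but pay a harmonic penalty for separating beyond `a`.
- **excluded volume**, one of two choices applied to *all* pairs `i < j`
  (bonded pairs included):
  - *quartic repulsion* `Σ θ(a − d)(a − d)⁴` with `k_nb = 5/a⁴` — a soft,
    purely repulsive overlap penalty;
  - *piecewise Lennard-Jones* with linear asymptotes: a linear core below
    `0.6a` (continuing the 12-6 value and slope), the plain
    `(d/a)⁻¹² − 2(d/a)⁻⁶` between `0.6a` and `1.25a` (minimum −1 at
    `d = a`), a linear ramp to zero at the cutoff `1.375a`, and zero
    beyond. This term enters with unit weight.

Both terms depend on distances only, so every prior and likelihood factor
is invariant under rigid motions and reflection — the source of the
mirror-image degeneracy in the posterior.

## Likelihoods

Contacts are unique unordered bead pairs `(i, j)` with multiplicity
`n_ij ≥ 1`; a multiplicity-`k` record counts as `k` independent copies of
the same restraint in every model.

- **Logistic contact model** (default): per contact
  `log σ(−α(d_ij − d_c))` with cutoff `d_c = 1.5a` and steepness
  `α = 200/a`, evaluated overflow-safely via `log1p(exp(·))`. With large
  `α` this approaches a step function; multiplicities simply duplicate the
  term.
- **Gaussian with flat plateau**: a contact is read as a noisy distance
  measurement `δ = a/γ`; the residual of `γ·d_ij` against the plateau
  `[0.8a, 1.2a]` is penalized by `1/(2σ²)`, with normalizer
  `√(2π)σ + 0.4a`. Default fixed weight `w = 1/σ² = 100`.
- **Lognormal**: `−log(√(2π)σa) − log²(a/(γ d_ij))/(2σ²)`, default
  `w = 500` (the softer shape tolerates a larger weight).
- **FISH size restraint**: `M` territory-size measurements with mean `s̄`
  and spread `Δs` enter as a Gaussian in `s̄ − 2.58·R_g(X)` with error
  `σ_FISH`; the `Δs²` term is constant in `X` but kept so model-evidence
  comparisons see the full density. `σ_FISH` defaults to `Δs` (0.3 µm for
  the X chromosome) because no separate value is published. The size
  relation is linear (`2.58·R_g`) by default; the power law
  `1.21·R_g^1.11` is available for compact structures.
- **Diploid (ambiguous) restraints**: with two copies `X₁, X₂`, each
  contact is evaluated on the r⁻⁶ average
  `(d₁⁻⁶ + d₂⁻⁶)^(−1/6) ≤ min(d₁, d₂)` — a soft logical OR: the contact is
  satisfied if either copy forms it. No inter-copy restraints are used and,
  by default, no inter-copy excluded volume (homologs are assumed to occupy
  separate territories); a flag enables inter-copy repulsion.

## Sampling

Coordinates are drawn with Hamiltonian Monte Carlo: unit mass matrix,
250-step leapfrog trajectories by default, and a Robbins–Monro adaptation
of the log-timestep toward 50% acceptance during burn-in (frozen
afterwards, so the chain is a valid Markov chain from then on). Non-finite
trajectory energies reject automatically. Nuisance parameters use their
conditional posteriors inside a Gibbs sweep: under the lognormal model the
distance scale γ (Jeffreys prior) is conjugate — `log γ` is Gaussian — and
the weight `w = σ⁻²` is Gamma with shape `n/2`; under the plateau model
both use short Metropolis random walks on the log scale (the plateau
normalizer depends on σ, so no conjugate form exists).

Multimodality (mirror images, alternative folds) is handled by replica
exchange over tempered posteriors `prior × likelihood^λ`, default geometric
schedule λ ∈ [10⁻⁴, 1] with K = 50 at production scale (desk-scale runs in
the tests use 6–14 replicas). Swaps are proposed deterministically on
even/odd adjacent pairs in alternating transitions with the Metropolis
criterion on the λ-weighted likelihood difference; θ-conditionals use the
tempered likelihood. Each replica owns a deterministically derived RNG
stream, so results are independent of execution order and exactly
reproducible from the seed. The default initialization is the fully
extended chain; for prior-equilibrium studies a freely-jointed random-walk
chain is provided, which starts near typical prior configurations instead
of ~10 standard deviations into the extended tail.

The same machinery drives prior-compactness exploration with a biased
target `exp(−λ R_g − k_bb E_bb − k_nb E_nb)`, λ up to 500 over 64 replicas
at production scale.

## Evidence and density of states

The model evidence `log Pr(D|I) = log Z(1) − log Z(0)` is estimated from
all replicas by a binless self-consistent multiple-histogram estimator
(MBAR-type): with pooled samples and free energies `f_k = −log Z_k`, iterate
`f_k = −log Σ_n e^{λ_k ℓ_n}/D_n`, `D_n = Σ_j N_j e^{λ_j ℓ_n + f_j}` to a
fixed point (tolerance 10⁻⁸ on the free energies, at most 10⁴ iterations);
`log Z` at unsampled λ (0 and 1 included) follows by reweighting the pooled
mixture. Neighbor overlap is checked up front via the effective sample size
of pairwise importance weights; a broken chain raises an error naming the
gap. The R_g density of states uses binned WHAM over R_g (default bin width
`a/2`), from which the unbiased prior mean and tail fractions
`Pr(R_g < r)` are read off. Correctness anchors: a constant likelihood, the
conjugate-Gaussian closed form, shift covariance, and a two-bead system
against 1D quadrature.

## Ensemble analysis

Distance-matrix mean/SD are entry-wise over members (population SD).
Matrix agreement uses Pearson correlation of the upper triangle with a
*diagonal permutation test*: the null shuffles entries only within each
off-diagonal band, preserving the genomic-distance structure; p-values use
the add-one estimator, so p = 1/(n_perm + 1) is the smallest attainable.
Superposition is least-squares (SVD/Kabsch, verified against a quaternion
oracle), with optional reflection, optional isotropic scale (Umeyama) and a
bead mask for unmappable regions. Clustering is spectral, on similarities
`exp(−β·RMSD)` with `β = 1/a`, choosing K by silhouette; RMSDs here use
proper rotations only, so a structure and its mirror image land in
different clusters; the cluster center is the medoid. RMSF is the per-bead
RMS deviation after superposing members onto the center. Violation counts
use tolerance `a/8` and are per-member by default (ensemble-mean mode
available). Contact probability P(s) counts (pair, member) events with
`d < d_c` per genomic separation. Precision is the mean RMSD of members to
the ensemble-average structure; accuracy the RMSD of that average to the
ground truth (reported against the truth and, where relevant, its mirror).

## Synthetic ground truths

3D Hilbert curves (Skilling's algorithm) provide self-avoiding,
space-filling lattice conformations with `8^order` beads; for lattice
benchmarks the lattice spacing equals one bead *radius*, the unique
convention under which the 1.5-lattice-unit contact cutoff captures exactly
distances {1, √2} and yields 3696 contacts for the order-3 curve (24 for
the order-1 cube). Contact extraction is a brute-force pair scan at a
cutoff; sparsification is uniform without replacement and seeded. Raw locus
pairs are binned with half-open bins (`bead = floor(pos/bin)`), dropping
intra-bead self-contacts and merging duplicates into multiplicities. Cα
fixtures turn a protein trace into distance (< 10 Å style) or contact
restraints, and restraint sets of equal-length structures can be pooled —
with duplicates kept — for ambiguous-restraint tests. The diploid mixture
fixture pools the contact sets of two conformations and retains the
generating labels privately for evaluation only. A caution from building
the demixing tests: under the *soft quartic* repulsion the diploid
posterior can legitimately prefer compressing one copy into a dense ball
that satisfies every pooled contact (the overlap penalty is small against
the steep contact reward), so planted-demixing studies use the
Lennard-Jones term, whose stiff core blocks that shortcut, and ground
truths whose pooled contact sets are geometrically unsatisfiable by a
single copy (two box-filling lattice paths in different visiting orders).
Because the diploid posterior is symmetric under exchanging the copies, a
well-mixed sampler label-switches; contact classification therefore
relabels each draw against the running per-copy mean of restrained
distances (standard mixture-model relabeling) before ensemble averaging. Read-level Hi-C noise,
false positives and mappability biases are *not* simulated: every observed
contact is treated as correct, so passing tests say nothing about
robustness to experimental artifacts.

## ShRec3D baseline

Contacts and backbone adjacency form a graph with unit edge lengths;
all-pairs shortest paths complete the distance matrix (a metric by
construction), and classical MDS (double-centered Gram matrix, top-3
eigenpairs, eigenvalues clipped at zero) embeds it in 3D. Because a graph
metric fixes neither scale nor chirality, benchmark RMSDs are computed
after optimal similarity alignment (rotation, translation, isotropic
scale, reflection allowed). The published accuracy figure for this
baseline depends on unstated edge-weight conventions, so it is treated as
an order-of-magnitude anchor; the monotone degradation with contact
sparsity is the sharper check.

## Numerical choices

- Heaviside at equality: θ(0) = 1 (the penalty factor vanishes there
  anyway).
- Energy/gradient kernels are O(N²) pair loops, JIT-compiled with numba
  when available; a vectorized numpy path is the reference and the two are
  asserted to agree to float tolerance. N ≤ ~4000 is practical on one core.
- Plateau-boundary gradients are one-sided (zero on the plateau side); the
  boundary is measure-zero and HMC tolerates the kink.
- Logistic terms use `−logaddexp(0, z)`; `α = 200/a` makes naive
  exponentials overflow.
- MDS eigenvalues below `max(10⁻¹⁰, 10⁻¹² λ_max)` are treated as zero and
  reported through the embedding rank.
- Degenerate clustering inputs (all members identical) report K = 1.

## Prior compactness at production conditions

Sampling the 333-bead prior (the X chromosome at 500 kb, `a = 430` nm)
with seeded HMC from both a fully extended start and a random-walk start
converges to a mean `R_g ≈ 9.5a ≈ 4.1 µm` for the quartic repulsion — the
equilibrium is bracketed from above and below. This sits between the ideal
chain (≈3.2 µm) and the athermal tangent-hard-sphere limit (≈5.6 µm), as
it must for a soft excluded volume. The piecewise Lennard-Jones prior
*collapses* (`R_g ≈ 3.55a ≈ 1.5 µm`): its unit-depth attractive well at
thermal energy puts the chain below the theta point. Published
prior-ensemble sizes for this system are several-fold larger than any
equilibrium average of these potentials at this chain length can produce;
the acceptance script reports the honest computed means, and the
corresponding checks are expected to disagree with the published figures.
The sizes used (2000 HMC transitions, 150 leapfrog steps, mean over the
second half, random-walk start) keep the running-mean standard error well
below the published spreads.

## Limitations

- Homopolymer fiber only: no persistence length, no hetero/euchromatin
  distinction, no strings-and-binders dynamics.
- Single chromosome per run; no trans-chromosomal or inter-copy restraints.
- The synthetic generator emulates contact lists, not sequencing reads; all
  contacts are assumed true.
- Replica exchange is evaluated serially; wall-clock at the published
  production scale (50 replicas × 1000 transitions × 10 HMC × 250 leapfrog
  ≈ 1.25 × 10⁸ gradient evaluations) requires parallel hardware. Desk-scale
  analogues of every production result are what the test suite verifies.
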