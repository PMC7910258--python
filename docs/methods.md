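# Methods

## The problem

A parallel-transmit (pTx) MRI array drives `N_ch` independent RF channels
with a complex excitation vector `b`. The 10 g-averaged local SAR at voxel
`v` is the quadratic form `b' S_v b` of a Hermitian positive-semidefinite
matrix `S_v` (W/kg per unit input power). Online supervision and pulse
design cannot afford the maximum over millions of voxels, so the set is
compressed into a small subset of *virtual observation points* (VOPs)
`V_sub` satisfying, for every `b`,

    max_v b' S_v b  <=  max_{w in V_sub} b' S_w b  +  omega(b),

where `omega(b) >= 0` is the overestimation term that makes the compression
feasible. The shape of `omega` versus actual SAR decides the *relative*
overestimation: a term uncorrelated with actual SAR inflates the bound most
exactly where SAR is low, throttling duty cycle or flip angle for no safety
benefit.

## Overestimation strategies

All four strategies share the greedy compression; they differ only in
`omega`:

- **global** — `omega(b) = eps_G * b' S_Global b` with the global-SAR
  matrix. Bounds the absolute overestimation by `eps_G *
  lambda_max(S_Global)` but tracks local SAR loosely.
- **diag** — `Z = d I` with `d` the worst-case SAR (largest eigenvalue over
  the set). The term is exactly `eps_G * d` for every unit-power `b`:
  constant absolute overestimation.
- **local** — `Z = S_local`, built to roughly track local SAR:
  1. draw a random sample of `ceil(fraction * n_vox)` voxels (default 1%);
  2. compress the sample with the **global** strategy at `pre_epsilon`
     (default 0.2) and sum the resulting VOP matrices into `S_pre`;
  3. eigendecompose `S_pre`; measure for each eigenvector the maximum local
     SAR over the *full* set;
  4. compress the spread of those values with the exponent `R =
     max(1, log10(max/min))` — the smallest `R >= 1` that brings the ratio
     of the scaled values `d_i = SAR_i^(1/R)` to at most 10;
  5. reassemble `S_local = V diag(d) V'`.
  Eigenvector SARs below `1e-6 x max` are floored there before the exponent
  (a rank-deficient `S_pre` would otherwise produce a singular scaling);
  the flooring is flagged in the build record.
- **double** — `omega(b) = eps_G * max_u (b' S_u b + eps_G_pre * b'
  S_Global b)` over a small pre-computed VOP set. The term is itself a SAR
  estimate, so the bound tracks actual SAR and the relative overestimation
  stays flat. The pre-set is computed with the **global** strategy at
  `eps_G_pre`, doubling that factor (up to 12 times) until at most 10
  pre-VOPs remain when auto-tuning is on. Supervision evaluates two baked
  collections and adds their maxima.

## The greedy compression and its certificates

Voxels are visited in descending order of `lambda_max(S_v)` (ties toward
the smaller voxel id). The first voxel is always a VOP. Each later voxel is
tested for *dominance*: nonnegative coefficients `c` (one set over the
VOPs, for the double strategy a second set over the pre-VOPs, each with L1
norm 1) such that

    P = sum_w c_w S_w + Omega(c_pre) - S_v

is PSD. The iterative search initialises both sets uniform; tests
`lambda_min(P) >= -tol`; otherwise takes the minimum eigenvector `b` and
checks the scalar VOP condition there (a strict violation proves no
certificate can exist — the voxel is admitted with `b` recorded as its
witness); otherwise updates the coefficients and repeats up to
`max_coef_iterations` (default 30). An unresolved voxel is admitted, which
always preserves safety. Coefficient updates come in two flavours:

- `paper_random` (default): redraw one coefficient uniformly on
  `[0, 2 c_i + 1/len]`, renormalise, keep the change unless it lowers
  `b'Pb`, stop the round when `b'Pb >= 0`; the two coefficient sets
  alternate. Per outer iteration the proposal budget is `5 x` the
  coefficient count.
- `greedy_argmax`: a Frank–Wolfe-style step toward the one-hot vertex of
  the currently binding VOP, with the smallest line step making `b'Pb`
  nonnegative. `lambda_min(P(c))` is concave in `c`, so this climbs
  reliably; it is deterministic and considerably faster, and is what the
  large acceptance runs use.

Discarded voxels can carry their coefficients as *certificates*; each is
re-verifiable by an independent eigendecomposition, and remains valid as
the VOP set grows because new coefficients default to zero.

Two sound screens reduce the work without touching safety:

- **witness pool** — previously found witness vectors (capped at 256) are
  tried first; a voxel whose SAR at any pooled `b` already violates the
  bound there provably admits no certificate and is admitted immediately.
  Per-voxel RNG streams are derived from `(seed, voxel position)`, so the
  pool changes only the work done, never the decisions.
- **certificate reuse** — the mixtures of the most recent successful
  certificates (default 6) are re-tried as one batched eigendecomposition
  before the full search; a hit discards the voxel with an equally valid
  certificate. This can only shrink the VOP set relative to the capped
  search.

Numerical tolerances: `P` counts as PSD when `lambda_min >= -1e-9 x
lambda_max(S_v)` (relative to the candidate's own scale; a hard zero fails
on floating-point noise). Matrices are symmetrized on container load;
Hermitian and PSD validation use relative tolerances of `1e-10`.

## Evaluation

Safety and tightness are measured with random excitation vectors: entries
are independent standard complex Gaussians normalised to unit power (the
direction law is unitarily invariant; the generating paper does not state
its distribution, so this isotropic choice is recorded in report
metadata). For each vector the *actual* maximum local SAR over the full
set is compared with the VOP bound evaluated from the baked collections.
Any underestimation beyond `1e-9` relative is a hard error. The headline
statistic, the maximum relative overestimation, is the maximum of a random
sample and is always reported together with its seed. Quadratic forms are
evaluated through a packed real representation of the Hermitian matrices
(one real GEMM per batch). Re-running with identical parameters is
bit-identical; changing the chunk size can reassociate the BLAS reductions
and move individual values by about one ulp, so cross-chunking agreement
is asserted at `1e-13` relative rather than bitwise.

## Synthetic data

`ArrayPhantomSpec` emulates the structure the algorithms consume, not the
electromagnetics that produce it. Per channel, the complex field is a
Gaussian near lobe plus a slow radiative tail,

    e_c(r) = A_c [ k_c exp(-d^2 / 2 sigma_c^2) + t exp(-d / delta) ]
             exp(i phi d) + noise,

with `d` the distance to element `c`. Three features carry the physics the
compression strategies are sensitive to:

- *heterogeneous lobe widths* — `sigma_c` varies by `element_width_spread`
  around the base width, with amplitudes `k_c` normalised so every element
  deposits equal volume-integrated power (Gaussian energy ~ A^2 sigma^3).
  Narrow elements then have intense 10 g peaks and broad ones shallow
  peaks at equal global footprint, which is what decouples per-channel
  *maxima* (what S_local measures) from per-channel *means* (what
  S_Global sees);
- *a radiative tail* (`tail_amplitude`, `tail_decay_mm`) — a weak,
  slowly-decaying component that dominates the volume-integrated (global)
  absorption the way body bulk does, while adding little peak SAR;
- *10 g surrogate* — a mass-weighted ball average (radius 1 voxel by
  default), PSD as a convex combination of rank-1 PSD point matrices; the
  global matrix is the mass-weighted mean over all voxels.

Defaults (chosen once as the study conditions): 8 channels on an
18 x 18 x 32 grid of 5 mm voxels (10 368 voxels), base `sigma = 22 mm`,
phase gradient 0.06 rad/mm, width spread 0.65, tail 0.12 with 80 mm decay,
noise 0.005. The `local` layout rings the elements around the mid-plane
(close-fitting body array); `remote` uses two rings at quarter heights
with 1.5 x wider arriving lobes (bore-mounted 2 x 4 array), which makes
its global-SAR matrix markedly more isotropic (channel decorrelation with
distance). With these defaults the default set's eigenvector-SAR spread
exceeds 10 (the regime the S_local exponent is designed for) and the
worst/best spread over random excitations exceeds 30.

What the generator does *not* emulate: tissue heterogeneity, true adaptive
10 g region growing, coil matching/decoupling, and realistic body-model
geometry. Passing tests therefore demonstrate the algebraic and safety
properties of the compression on structurally faithful inputs, not
dosimetric accuracy for any real coil.

## Problem sizes used by the test suite

Chosen as the package's own desk-scale conditions: the safety suite runs
all four strategies on 4- and 8-channel default sets (10 368 voxels each)
against 10^5 random probes with the deterministic greedy rule; the
small-set oracle suite (300 structured voxels) uses the published random
walk; the strategy-comparison suite runs the remote-style set at
12 x 12 x 20 (2 880 voxels) at three matched VOP budgets with 5 x 10^4
probes per batch over five batches. Working points are expressed as the
ratio of the overestimation-term ceiling `eps_G * lambda_max(Z)` to the
worst-case SAR, which makes `eps_G` comparable across strategies; for the
budget-matched comparison each strategy's working points were calibrated
once (by bisection on the deterministic compression) to land at S_global's
achieved VOP counts.

## What the strategy comparison shows on synthetic data

On the remote-style synthetic set, at matched VOP budgets (each strategy's
`eps_G` calibrated so its total VOP count lands at S_global's), the median
maximum relative overestimation over five probe batches shows: Double VOP
clearly best at the small and mid budgets and within half a percent of
the best at the largest; S_local and S_global within a few percent of
each other throughout; the constant-diagonal term clearly worst. A
*strict* Double <= S_local <= S_global ordering at every budget does not
emerge on this family.
The reason is visible in the construction: the phantom's volume-mean
matrix is itself a reasonable local-SAR surrogate, while S_local's
eigenvalue-ratio cap (10, by design) discards the dynamic range that would
distinguish it. Separating them appears to require field structure
(multi-tissue, full-wave) that the generator deliberately does not model.

## Known limitations

- The greedy subset is not minimal; exact minimisation is NP-hard-flavoured
  and out of scope.
- The random-walk coefficient search can leave certifiable voxels
  unresolved at the iteration cap; they are admitted (safe, but the VOP
  count grows). The greedy rule reduces, and the certificate-reuse screen
  further reduces, this effect.
- `S_Global`, when absent from the input, is approximated by the uniform
  mean of the set; mass-weighted summation from unaveraged data is the
  caller's responsibility.
- The one-shot maximum-relative-overestimation statistic is a random
  maximum; comparisons between strategies should use matched probe seeds
  (the comparison harness does).
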