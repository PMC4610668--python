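# Methods

This note records the model assumptions, numerical choices and known
limitations behind the package. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is taken
on faith.

## The measurement model

We define the heritable states of a dynamical system as its distinct
long-time attractors that can be made to win a population competition
under *some* environment. Because competitive exclusion lets only one
state dominate any single long run, the repertoire is probed with an
ensemble of selection pressures: each pressure is an independent random
perturbation of the system's rates, each run contributes one final-state
row to the observation matrix **P** (N_P rows × N_f features).

Assumptions this rests on:

- the pressure distribution actually re-orders which state wins (pressures
  that never touch a state leave it invisible);
- features are comparable in scale (binary features, or scalars normalized
  by the investigator — `normalize_columns` exists but is off by default);
- features directly driven by the pressure itself are excluded by the
  investigator, since externally forced variance masquerades as heritable
  variance;
- N_f and N_P comfortably exceed the number of states: the metric can
  never report more states than min(N_P, N_f), and degrades before that
  bound is reached (see the operating limits below).

## Gap detection

PCA eigenvalues λ₁ ≥ … ≥ λ_N of the centered matrix are computed by SVD
(squared singular values over N_P − 1; the spectrum sum then equals the
total column variance, a conservation law the tests assert at 1e-8).
The iterative threshold is

    λ_> = (1/j) Σ_{ranks j+1..2j+1} λ  (zero beyond the spectrum),
    T   = α (λ₁ − λ_>) + λ_>,
    j ← #{λ > T},

from j = N_eigs until j repeats. Numerical choices, in the order they
bite:

- **Window and divisor.** The tail window spans the j+1 ranks immediately
  below the current candidate set but is divided by j. We keep that
  asymmetric divisor as the definition of λ_>; the threshold only shifts
  by O(1/j) relative to a true mean and every downstream result is
  insensitive to it.
- **Ties.** Eigenvalues exactly equal to T count as below (strict
  inequality).
- **Cycles.** The update can 2-cycle; we stop on any repeated j and keep
  the smallest member of the cycle.
- **Gapless spectra.** If even the full-width pass leaves every eigenvalue
  above T — the spectrum's top-to-bottom ratio is smaller than 1/α — there
  is no resolvable drop. We report j = 0 (one state, nothing
  distinguishable) and set `gapless=True` so diagnostics can tell "no
  structure resolvable" apart from "one resolved state". This situation is
  real, not hypothetical: it is the data-starved regime of the convergence
  curve (below).
- **α default 0.1.** Dimensionless; smaller values resolve finer gaps but
  over-count when states are many, larger values saturate early. All
  shipped experiments use 0.1. Sensitivity of a result to α is itself a
  warning sign; inspect a convergence curve before trusting a count.

Scale equivariance (all λ, λ_>, T scale by c² under feature scaling by c;
j unchanged) and rotation invariance of the spectrum are asserted as
property tests.

## Regularization: the conditional subtract-one

Appending 10 exact copies of one randomly chosen data row creates an
artificial zero-variance species drawn from the data's own distribution.
The classic prescription is to subtract one from the final count. Direct
inspection of spectra shows the artificial state does **not** always
register: on data with genuine multi-state structure the duplicate block
merges into existing state directions (its residual eigenvalue sits at the
within-state noise scale, below the gap), and unconditional subtraction
under-counts by exactly one; on structureless data the block is the lone
resolved state and must be subtracted. We therefore subtract one **only
when the artificial state registered**, decided by recounting the
unaugmented spectrum at the converged threshold T: if augmentation pushed
at least one extra eigenvalue above T, the extra state is artificial.
This single rule reproduces, with no per-case tuning: exact recovery of
planted species counts, exact cluster-count recovery in the
transition-matrix model, the count of exactly k on k noiseless clusters
with or without regularization, and a count of 1 on isotropic noise in
≥ 9/10 seeds (all asserted in the suite). Cost: one extra SVD per fit.

## Operating limits (and the shape of failure)

- **Data-limited boundary.** With ample features (easy case, f1 = 0.5,
  m = 0.05) the 50%-relative-error boundary scales with rows at about
  0.25·N_P — roughly 4 rows per species are needed. Measured by scanning
  the species grid with 5 replicates per point and reporting the last grid
  point whose median relative error stays below 0.5 (grid step 25 at
  N_P = 400; the step, not the replication, limits the resolution).
- **Single-state saturation.** With one heritable state and no
  regularization, the count first *tracks the data volume* (every
  eigenvalue of the short noise spectrum sits above threshold — the
  gapless regime) and decouples at the row count where the
  Marchenko–Pastur edge ratio (1+√q)²/(1−√q)², q = N_f/N_P, falls below
  1/α. At α = 0.1 that happens at N_P ≈ N_f/3.7, where the count is
  ≈ 0.27·N_f — the familiar "about 30% of the number of features"
  saturation level. `saturation_level` reports the count at the first
  non-gapless convergence of the curve; beyond it the count keeps creeping
  upward slowly (the noise spectrum is continuous, not gapped), and at
  very large N_P (q < 0.27) the spectrum becomes too uniform to show any
  drop and the search returns to the gapless state. Regularization
  suppresses this entire failure mode, at the price of inserting its
  artificial state.

## Simulators: what they emulate, and what they do not

**Species populations** (`heredity.species`). Binary prototypes with a
fraction f1 of bits set, observed through independent per-bit mutation m.
Expected squared distances — 2f1(1−f1)N_f(1−2m(1−m)) + 2m(1−m)N_f between
species, 2m(1−m)N_f within — give the calibration values ≈ 22 and ≈ 10 at
the base configuration (f1 = 0.5, m = 0.05, N_f = 1000). The "uniform"
abundance mode allocates rows to species in equal proportion (balanced,
shuffled); multinomial and geometric modes are provided for abundance-
fluctuation studies, and per-feature f1/m arrays (contiguous blocks via
`heterogeneous_config`) for heterogeneous-feature studies. Balanced
allocation is deliberate: with i.i.d. multinomial occupancy the rarest of
150 species in 1000 rows receives 1–2 rows, and no threshold of the form
α(λ₁ − λ_>) + λ_> retains eigenvalues that small at α = 0.1 — occupancy
imbalance, not cluster geometry, then dominates the error. The geometric
mode (p_i = (1−1/N_S)^{i−1}/N_S, last species (1−1/N_S)^{N_S−1};
most/least common ratio exactly N_S − 1) exists precisely to study that
regime. No phylogenetic structure among prototypes: species are i.i.d.

**Clustered transition matrices** (`heredity.network`). Each of n nodes
receives N_L targets sampled with replacement among the other nodes
(duplicates summed, no self-links), weight (1+γ)/2 within its cluster and
(1−γ)/2 across, rescaled so node i's outgoing weights sum to
r_i = r₀ + δr·η_i, η_i ~ U[−1,1]. Convention: `weights[i, j]` is j → i, so
p ← Wp and column sums are the replication rates (pinned by test).
Selection pressure scales all outgoing weights of a random half of the
nodes by 0.99 ("about 1%" implemented as exactly 0.01, configurable);
iteration noise multiplies each node's outgoing scale by 1 + U(−0.01, 0.01)
resampled every step. Runs are advanced as one batched dense matrix
product per iteration (the per-run column scalings commute with W), with
renormalization to sum 1 purely for numerical stability. Cluster
assignment is uniform-multinomial per the construction; a balanced mode
exists for tests. At the standard parameters (1000 nodes, N_L = 200,
r₀ = 1.1, δr = 0.03, γ = 0.999, 250 iterations) the 250-step runs have
*not* fully collapsed onto one cluster — final vectors are partial
mixtures over cluster profiles — which is part of the protocol being
reproduced, and is why detection degrades gradually (not sharply) as the
cluster count grows; the detected count matches N_C exactly up to ≈ 8 and
its median over replicate networks falls below half the truth by
N_C ≈ 24–32, with very wide variation across network realisations.

**GARD** (`heredity.gard`). Affinity matrix β with i.i.d. lognormal
entries, log-mean −4 and log-sd 4 (the canonical lipid-world choice; the
spread of β is what makes compositional attractors possible, so these are
study conditions, exposed in `beta_law` but not to be nudged per
experiment). Growth: the propensity to add a lipid of type i to a vesicle
of composition n is 1 + (β n)_i / N — catalysed incorporation over a
uniform ambient supply; lipid-loss events are omitted (no backward rates
are part of this protocol) but the event loop leaves an obvious hook.
Division at N_max splits the lipids multivariate-hypergeometrically into
two exact halves; both children enter and one uniformly random member of
the P + 1 candidates is culled, holding the population at P while letting
lineages competitively exclude one another (P = 1 reduces to serial
transfer). Events are chosen across the population proportional to total
addition propensity (Gillespie-style selection; absolute time never enters
the observables). A generation is one division per capita; runs last 100
generations, comfortably past the ~30-generation equilibration the
trajectory tests check. Selection pressure multiplies row i of β by
(1 + σ t_i) with σ = 50 and targets t drawn from a symmetric Dirichlet(1)
(a sparse-target mode exists); the metric observes only the
population-mean normalized composition, one row per target. The event
loop is numba-compiled (pure-Python fallback with identical semantics);
vesicle splits inside the loop use sequential urn draws, which realise
exactly the multivariate hypergeometric distribution of the public
`divide`.

## Problem sizes in the shipped experiments

`scripts/acceptance.py` runs the full study conditions: base-case sweeps at
N_P = N_f = 1000 up to 150 species; boundary scan at N_P = 400 with 5
replicates; gap-closure scan over N_C ∈ {4, 8, 16, 24, 32, 48} with 5
replicate 1000-node networks × 300 runs and a median-below-0.5 collapse
rule; GARD means over 8 β matrices × 150 pressures; saturation curve to
N_P = 5000. The pytest acceptance tests mirror each experiment at reduced
grids/replicates (e.g. 4 β matrices, 3 networks, 4-point sweeps) so the
whole suite stays inside a few minutes; the reductions change statistical
resolution, not protocol.

## Known limitations

- The metric counts states the pressure ensemble can excite; pressures
  orthogonal to a state leave it uncounted by construction.
- Passing the synthetic benchmarks shows the estimator recovers planted
  structure under these generative models (independent features, i.i.d.
  pressures, equilibrated dynamics); real data with correlated features,
  drifting baselines or unequilibrated runs can fail in ways these tests
  do not probe — the convergence-curve and gapless diagnostics are the
  first line of defence there.
- Unlimited-heredity systems (combinatorial genotype spaces) defeat a
  direct count: with N_P, N_f far below the state count the metric reports
  a small number or 1. Scaling studies over system size are the intended
  workaround and are out of scope here.
- The GARD β matrices are regenerated from their distribution, not the
  historical realisations, so GARD numbers are reproducible in
  distribution only; the decreasing trend of heritable states with N_max
  and the ≈ 3-state mean at N_max = 50 are the stable observables.
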