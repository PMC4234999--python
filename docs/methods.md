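# Methods

## Model

The package analyses closed populations of identical individuals (molecules,
channels) hopping on a finite directed graph with constant per-capita rates
α_k — a first-order (monomolecular) reaction network. Three levels of
description are implemented and linked:

1. **Jump process.** Occupancy counts N(t) driven by independent Poisson
   clocks, one per reaction, with propensity α_k N_{i(k)}. Simulated exactly
   by the direct (Gillespie-type) method in `population_sim.exact_ctmc`.
2. **Discrete-time multinomial chain.** All individuals at node i are
   redistributed each step of length h by one multinomial draw over
   destinations (stay probability 1 − Σ_j α_ij h). This preserves counts
   exactly and cannot produce negative occupancies, unlike independent
   binomial draws per edge, which require resampling. Conditional moments are
   the multinomial ones; cross-destination covariances are O(h²).
3. **Ornstein–Uhlenbeck diffusion.** For large populations the centred
   occupancies follow dX = LX dt + B dW with L = (A − D)ᵀ and noise columns
   σ_k ζ_k. At stationarity σ_k² equals the stationary propensity
   α_k N̄_{i(k)} (chemical-Langevin scaling: the variance of a Poisson count
   equals its mean). For a closed monomolecular network this OU covariance is
   exact at every population size, which the tests exploit.

**Shielding.** A reduced process zeroes the noise columns of a subset E′ of
edges while keeping the drift; full and reduced processes share the same
Wiener paths on kept edges. The deficiency U = X̃ − X obeys
dU = LU dt + (B̃ − B) dW, and the stationary variance of MᵀU decomposes
additively into per-edge importance values R_k (the spectral double-sum over
non-null eigenpairs; biorthogonal left/right eigenvectors in the
non-symmetric case). At the population level, shielding replaces the
per-step count fluctuation δN_ij by zero on E′ while both runs share the
fluctuations drawn from the full run — so an empty E′ reproduces the full
run bitwise, and shielded occupancies become real-valued.

## Numerical choices

* **Spectral decomposition.** Symmetric Laplacians use the real symmetric
  solver; non-symmetric ones use the general solver with left eigenvectors
  taken as rows of the inverse right-eigenvector matrix, enforcing
  biorthogonality. Eigenvalues are sorted by decreasing real part (zero
  first); eigenvector signs are fixed by making the first nonzero component
  positive — R_k is invariant to this, the convention only stabilises
  round-trips. A decomposition is rejected when the right-eigenvector matrix
  has condition number above 1e8 (near-defective) or when an eigenvalue has
  positive real part beyond 1e-9 of the spectral radius. Complex arithmetic
  is carried throughout; final imaginary parts must fall below 1e-9 relative
  and are discarded.
* **Zero eigenvalue.** Identified as the largest real part and asserted to
  be zero within 1e-9 of the spectral radius, never assumed exactly zero.
  A repeated zero signals a reducible graph; `per_component_importance`
  evaluates each weakly connected component with M and ζ_k restricted to it.
* **Importance contraction.** R_k is evaluated as a dense contraction over
  precomputed projections a_i = Mᵀv_i and w_iᵀζ_k — O(m n²) after the
  decomposition. The regimes of interest (n up to ~1000 dense) make clarity
  preferable to anything faster.
* **OU integrator.** Euler–Maruyama evaluated in the Laplacian eigenbasis:
  each modal coordinate is a scalar linear recursion run by a compiled
  filter, so million-step paths cost fractions of a second while preserving
  the shared-noise coupling (subsets mask noise columns; increments are
  drawn once, never redrawn). Defaults: dt = 1e-3 and T = 1e3 relaxation
  times of the slowest nonzero mode, burn-in 10 relaxation times; stationary
  estimates use a single long path with 20-batch means. An exact
  transition-density sampler (matrix exponential on the zero-sum subspace,
  per-step innovation covariance C∞ − ΦC∞Φᵀ) is available for variance
  checks; it is not pathwise-coupled across subsets.
* **Removable singularities.** The HH rate factor x/(1 − e^{−x}) switches to
  a 4th-order Taylor branch for |x| < 1e-4, keeping machine-precision
  continuity at V = −55 mV (α_n) and V = −40 mV (α_m).
* **HH noise scale.** σ_k(V) = sqrt(r_k(V) N̄_{i(k)}(V)) with N̄ = π(V)·N_tot
  and N_tot = 1 by default ("per-channel" units): any other population size
  scales every R_k by the same factor, leaving rankings, crossovers and the
  current-variance argmax unchanged. Rates are per millisecond, voltages in
  mV.
* **Na⁺ edge numbering.** Reversible pairs are numbered (2p−1, 2p) with the
  forward (upward) direction first: the three m-transitions of the h=0
  chain, then of the h=1 chain, then the four h-transitions — placing edges
  11/12 at state 7 ↔ conducting state 8 and 19/20 at state 4 ↔ 8.
* **Ties and degeneracies.** Edge rankings break ties by ascending edge
  index. Degenerate eigenspaces are handled implicitly: the double sum only
  depends on invariant subspaces, verified by random within-eigenspace
  rotations.
* **Parallel edges** are rejected by default (the reaction index must be
  unambiguous); an explicit merge flag sums their rates.

## Ensemble experiments

Erdős–Rényi samples are symmetric: each unordered pair appears with
probability p as two unit-rate directed edges. Disconnected samples are
redrawn (probability ≤ n²/2·(1−p)^{n−1}, about 2.2e-12 at n=50, p=0.5); a
per-component mode covers reducible inputs. Binary measurements place n₁
ones uniformly at random, independent of the edges. Eigenvector moment
estimates randomise each eigenvector's sign so odd moments are unbiased, and
compute the per-eigenvector averages over distinct index tuples exactly from
power sums. The fourth-moment exponent q is the negated least-squares slope
of log E[v⁴] against log n; the coefficient (~2) of the empirical
2 n^{−5/3} law is reported but not asserted — only the exponent band is.
The important-class reference is 1/(nC) with C = 2p (which coincides with
1/n exactly at p = 1/2, the case usually quoted).

## What the synthetic generators do and do not cover

The generators produce the study conditions themselves: the 3-state chain,
the two HH channel graphs across [−100, 100] mV, and ER ensembles at the
stated (n, p). They do not emulate time-varying rates (current clamp),
nonlinear (non-monomolecular) kinetics, degree-heterogeneous or weighted
random graphs, or open systems; passing tests therefore say nothing about
those regimes. The OU layer is exact in covariance for these linear networks,
so simulation tests probe the estimators and the coupling, not an
approximation gap — except the population-level comparisons, where the
discrete-time step contributes an O(h) bias kept below the assertion
tolerances.

## Design decisions on open points

* The master equation is used in the column convention throughout
  (dX = LX dt, L N̄ = 0); the row form that appears in some discrete-time
  derivations is not used.
* The population-to-OU "correspondence improves with N_tot" property is
  measured as the Kolmogorov–Smirnov distance between the scaled occupancy
  fluctuation Mᵀ(N − N̄)/√N_tot and the OU Gaussian. The scaled *variance*
  carries no N_tot trend here (the OU covariance is exact for monomolecular
  networks), so variance agreement is asserted at a fixed tolerance and the
  distributional distance carries the trend: lattice discreteness keeps it
  away from zero at small N_tot. Problem sizes: 2·10⁵ steps at h = 0.05 for
  N_tot ∈ {100, 1000, 10000}.
* Population-level shielding of the 3-state chain *reduces* the observable
  variance by R₁+R₂ / ΣR = 12.5% — "almost identical" holds for systems
  whose unimportant edges are genuinely negligible (the HH channels), not
  for this minimal chain. The tests assert the closed-form ratio 0.875
  rather than near-equality.
* The Na⁺ maximal-pair crossover computed under the chemical-Langevin noise
  scale sits at −28.3 mV (confirmed independently by a Lyapunov-equation
  solve). Figure-level descriptions of this system usually quote the
  boundary as −25 mV; the discrepancy traces to the coarse voltage
  resolution of such descriptions, not to the pairing or ranking structure,
  which is reproduced exactly.

## Limitations

* Dense eigensolvers only — no sparse/iterative path for very large n.
* Weak connectivity semantics; strongly-connected refinements are out of
  scope (the ensembles are bidirectional).
* Voltage is always clamped; rates never vary in time.
* The graded-measurement quadratic law and the 2 n^{−5/3} fourth-moment
  coefficient are empirical regularities, reported with reference curves but
  not derived.
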