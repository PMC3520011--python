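# Methods

## Model

Activity q_i(t) (mean depolarisation of region i) on a weighted
connectivity matrix κ obeys the Langevin equation

    dq = (−τ q + Δ κ f̃(q)) dt + √ε dW,

a spatially discretised stochastic neural field: postsynaptic filtering at
decay rate τ, afferent drive given by the kernel-weighted sigmoid rate of
the source regions (the integral over the cortical manifold is approximated
by the matrix product times the grid step Δ), and spatially uncorrelated
white noise of intensity ε.  The sigmoid is the increasing logistic
f(q) = 1/(1+exp(−a(q−θ))) with gain a and threshold θ; inside the dynamics
we use the centred rate f̃(q) = f(q) − f(u₀), so the fixed point of the
deterministic system is u₀ = 0 exactly and the linearised gain is
h = f′(u₀) (a/4 at threshold).  Nodes live on a one-dimensional grid
x_i = i·Δ, 0-based; kernel-derived matrices are plain truncations (no
wraparound), which realises zero-flux boundaries for a discrete matrix
model.  A circulant boundary option exists because it makes sinusoidal
eigenmodes exact, which is invaluable for testing.

Assumptions: fixed-point (non-oscillatory) mean-field dynamics; no
conduction delays (the model is restricted to the regime where the
non-oscillatory instability is delay-independent); noise small enough that
the system stays in the linear neighbourhood of u₀.

## Linearisation, criticality and eigenmodes

The Jacobian at the fixed point is J = Δ·κ·diag(h) − τI, so for uniform
gain the eigenvectors of κ are exactly the modes of the dynamics and each
connectivity eigenvalue L_l maps to a dynamical rate λ_l = h·Δ·L_l − τ with
decay time constant τ_l = −1/Re λ_l.  `critical_scaling` multiplies κ by
s = (τ−δ)/(h·Δ·max Re L) so the slowest mode sits exactly at Re λ = −δ;
δ defaults to 0.01·τ as the operationalisation of "approaching"
criticality.  Near criticality the slowest mode carries far more stationary
variance than the rest (its variance is ε/(2δ)), which is why the principal
eigenvector of the sample covariance — the functional connectivity — aligns
with the principal anatomical eigenvector.

Eigenvalues are sorted by descending real part (slowest decay first), the
ordering the centre-manifold argument requires; conjugate pairs are kept
adjacent with the +Im member first.  Each eigenvector is unit-norm and
rotated so its largest-magnitude entry is positive real, making mode
comparisons reproducible; similarities are |⟨v₁,v₂⟩|/(‖v₁‖‖v₂‖), invariant
to the residual sign/phase freedom.  For complex rates, the time constant
uses the real part (the decay envelope) and |Im λ| is reported as the
oscillation frequency.

## Simulation

Euler–Maruyama with step dt (default 0.01 s) over n_samples time bins
(default 2001): q ← q + dt·(−τq + Δκf̃(q)) + √(ε·dt)·η.  All randomness
flows through one seeded NumPy generator, so identical configurations give
bit-identical trajectories.  ε defaults to 1e−3 ("low noise": r.m.s.
fluctuations a few percent of the activity scale).  The random initial
condition is uniform on u₀ ± 0.1 per node.  Trajectories exceeding a
configurable ceiling abort with the offending step index.  Functional
connectivity is the sample covariance over time; its leading eigenvector
(sign-fixed) is the principal functional mode.

Parameter defaults and units: τ (1/s) defaults to 1, which makes the drift
match the conventional unit-decay form of the Langevin equation.  For the
*resting-state experiment* specifically we use τ = 10 s⁻¹ — a 100 ms
population time constant, the standard order of magnitude in neural-field
modelling.  This is not cosmetic: with 2001 samples at dt = 0.01 s the
recording spans 20 s, and the slowest mode (relaxation time 1/(0.01·τ))
must revisit its stationary range *within* the window for the sample
covariance to see its variance.  At τ = 10 s⁻¹ that relaxation time is
10 s and the centre-manifold alignment is observable in a single run; at
τ = 1 s⁻¹ it would be 100 s and the window-mean subtraction would suppress
the very mode the experiment is about.

The centre-manifold experiment ships with a 66-node exponential footprint
at σ = 15 grid units, giving a scaled spectral gap of ≈ 4.2 — comfortably
above the 10·δ = 1 the property requires.  With these study conditions the
anatomical–functional cosine similarity exceeds 0.95 on all ten seeds
(0..9) exercised by the tests.

## Ornstein–Uhlenbeck benchmark

In the linear regime the model is a multivariate OU process whose
stationary covariance Σ solves JΣ + ΣJᵀ + εI = 0; `stationary_covariance`
solves this Lyapunov equation directly (SciPy) as an analytic benchmark
that never touches the integrator.  The equivalence test runs a 20-node
footprint scaled to δ = 0.5·τ (brisk mixing), integrates 2000 s, and
compares node variances using batch means: 20 batches, each batch variance
computed about the *global* mean.  Computing batch variances about their
own batch means would bias each estimate low by ≈ 2τ_c/T_batch (the usual
short-window covariance shrinkage) — with 100-s batches and a 2-s
correlation time that bias is several standard errors, so the global-mean
form is the statistically honest comparison.  Remaining Euler bias is
O(λ·dt/2) ≲ 1%, below the Monte-Carlo resolution at this run length.

## Graph measures

Weighted clustering follows the triangle-intensity convention: the binary
clustering γ_a = 2δ_a/(p_a(p_a−1)) (p_a the number of strictly positive
neighbours, δ_a the triangle count) times the mean geometric-mean intensity
(ŵ_ab·ŵ_bc·ŵ_ca)^(1/3) over the node's triangles, with weights normalised
by the global maximum.  It is computed via the diagonal of (W^(1/3))³,
equivalent to explicit triangle enumeration (tested against one).  Nodes of
degree < 2 score 0.

Modularity uses weight fractions rather than binarised edges (the matrices
of interest are weighted; a user can binarise beforehand if desired):
ζ_aa is the within-community fraction of total edge weight, ζ_aβ the full
between-pair fraction, and C = Σ_a(ζ_aa − (ζ_aa + ½Σ_{β≠a}ζ_aβ)²), which
equals the classic Newman weighted modularity (cross-checked against
networkx in the tests).  C ≥ 0.3 is reported as significant community
structure.

The optimiser is deliberately deterministic: greedy agglomeration from
singletons on the exact ΔC, then rounds of leading-eigenvector bisection,
single-node moves, and pairwise swaps until the cost stops improving, with
lowest-index tie-breaking throughout.  Pairwise swaps matter: single-node
moves alone stall one swap short of the optimum on some small dense graphs.
An exhaustive set-partition search (N ≤ 12) serves as the oracle; the
heuristic matches it on every shipped small fixture.  Community reordering
sorts communities by size (descending, ties by smallest member) and nodes
within a community by strength (descending, ties by index); the permutation
is returned so labels and mode vectors can be co-reordered.

## Dispersion analytics

For kernels with rational Fourier transform K(k) = num(k)/den(k), m > n,
the dispersion relation den(k)(λ+τ) − num(k)h = 0 is built symbolically as
a coefficient vector and solved by the companion matrix, so all m roots are
found with multiplicity.  A root counts as propagating when
|Re k| > 1e−9·(1+|Im k|); spatial periods are 2π/|Re k|.  λ is treated as
real (the validated non-oscillatory regime); the exponential footprint's
closed form ±σ⁻¹√(h/(λ+τ)−1) is kept as an independent check and agrees
with the polynomial solver to 1e−12 across parameter sweeps.

The discrete–continuum match takes a circulant footprint matrix, maps each
eigenvalue to its analytic wavenumber root, and compares with the mode's
dominant DFT wavenumber.  The comparison is restricted to the
long-wavelength band k·σ ≤ 2 (configurable): by Poisson summation the
transform of the *sampled* kernel departs from 1/(1+k²σ²) by an O(1)
relative factor near the grid Nyquist wavenumber, so the continuum relation
simply makes no prediction there.  Within the band the maximum discrepancy
is far below one DFT bin at N = 256 and does not grow with N.  For this
diagnostic the matrix keeps its self-connection term (generator option), so
the circulant eigenvalues Riemann-sum the continuum transform; zeroing the
diagonal (the default graph convention everywhere else) would offset the
k ≈ 0 modes by O(√(Δ/σ)/σ).

## Homogeneity diagnostics

Per mode: dominant wavenumber (DFT bin of largest energy after mean
removal), spectral concentration (energy fraction in that ± bin pair), and
the inverse participation ratio Σ|v|⁴/(Σ|v|²)² ∈ [1/N, 1].  Summary
verdicts operationalise what is otherwise a visual judgement: a *full
periodic spectrum* requires every concentration ≥ 0.9 with wavenumbers
covering the DFT grid (true for circulant footprints, where concentrations
are 1 up to round-off); *localised modes present* requires some IPR above
3/N.  Both thresholds are package-defined conventions.  The uniform
(zero-wavenumber) mode has no spatial frequency content and is assigned
k = 0 with concentration 1 rather than treated as an error.

## Synthetic fixtures: what they emulate and what they do not

The generators reproduce the *classes* of connectivity the analyses
distinguish: translationally invariant exponential footprints (Toeplitz,
optionally circulant), footprints perturbed by heterogeneous two-point
connections, asymmetric variants with reciprocal excitatory (+w one way)
and inhibitory (−w the other) connections between two local cliques, and
planted modular block matrices.  The E/I clique exemplar is constructed so
its physics is transparent: the clique-uniform pattern sees a 2×2 block
[[(n_c−1)p, n_c w], [−n_c w, (n_c−1)p]], so the leading eigenvalue pair is
≈ (n_c−1)p ± i·n_c·w — complex with positive real part, which a symmetric
matrix can never produce — and the imaginary-part clique oscillates a
quarter cycle (π/2) behind the real-part clique.  The exact-quadrature
fixture used for the phase-lag check is a pure antisymmetric two-point pair
on a zero base (eigenvalues ±i exactly).

These fixtures are regular and noiseless.  Real tractography matrices are
sparse, heavy-tailed, bi-hemispheric and measured with error; passing tests
on the fixtures shows the machinery is correct and that the
homogeneity/heterogeneity signatures behave as the theory predicts, not
that any particular brain dataset will show them.  A user-supplied matrix
(e.g. a 66-node DSI matrix, values on an arbitrary 0–1 scale) can be run
through the identical pipeline via `connfield report`; no such dataset is
bundled.

## Numerical choices and degenerate inputs

- Fixed points: centred rate gives u₀ = 0 exactly; the uncentred path uses
  damped fixed-point iteration with a hybrid-Powell fallback, tolerance
  1e−10 on the max-norm defect.
- Undirectedness means exact transpose equality; generator symmetry is
  enforced by construction (elementwise min with the transpose kills
  floating-point asymmetry).
- Degenerate eigenvalues (circulant ± pairs): the Hermitian solver returns
  an orthonormal basis of the eigenspace; diagnostics (concentration, IPR)
  are well defined on any basis vector of the pair.
- Zero covariance (noise-free runs), zero vectors, constant vectors:
  explicit degenerate-input errors rather than NaNs; pipeline code catches
  the functional-mode case and reports it instead of failing.
- Non-diagonalisable (defective) inputs flag the ModeSet rather than raise.

## Known limitations

One-dimensional manifolds only (no 2-D cortical sheets or wavevectors); no
conduction delays, so oscillatory delay-induced instabilities are out of
reach by design; Euler–Maruyama is first-order (fine at the dt·|λ| ≤ 0.1
regimes used here, and the OU benchmark quantifies the residual bias); the
modularity optimiser is a deterministic heuristic — exact only where the
exhaustive oracle can confirm it (N ≤ 12), though it recovers all planted
structures shipped with the package.
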