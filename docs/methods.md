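# Methods

## Model

Each of n cells occupies a point **x**ᵢ in a periodic rectangle
[0, Lx) × [0, Ly) (µm) and moves as a continuous-time Markov process. The
per-cell movement rate is

ψᵢ = max(0, m + Σⱼ≠ᵢ w(**x**ⱼ − **x**ᵢ)),  w(**z**) = α e^(−|z|²/2σ_w²),

so m (h⁻¹) is the intrinsic event rate and α (h⁻¹) scales how neighbours
within ~σ_w (µm) modulate it; the clamp keeps rates non-negative. When a cell
moves it jumps instantaneously: the step length is normal with mean 1/λ_µ and
spread σ_µ, truncated to [0, ∞); the direction θ follows a von Mises density
with mean arg **b** and concentration |**b**| built from the bias vector

**b**(**x**) = Σⱼ ∇v(**x**ⱼ − **x**),  v(**z**) = β e^(−|z|²/2σ_v²),

where the gradient is taken with respect to the displacement argument — the
sign convention that makes β > 0 bias movement *away* from close neighbours
(the summed gradient of the crowding surface points downhill) and β < 0
towards them. |**b**| = 0 reduces the directional law exactly to the uniform
density 1/2π. The step law used everywhere (simulator and moment model) is
the factorized product "length ~ truncated normal, angle ~ von Mises" with
integrals over steps taken in (dr, dθ): the alternative reading of the 2-D
displacement density (a Cartesian normalization, which would tilt the length
marginal by a factor r) is *not* used, guaranteeing the stochastic and
continuum descriptions share one displacement law.

Displacements between cells use the minimum image convention, components in
(−L/2, L/2]. There is no birth or death, so the first moment Z₁ = n/(LxLy)
is constant; the interesting dynamics is in the pair density.

## Event-driven simulation

The Gillespie algorithm is exact: waiting time ~ Exponential(Σψᵢ), mover
chosen ∝ ψᵢ, position wrapped modulo the domain. Interaction sums
Sᵢ = Σⱼ w(**x**ⱼ − **x**ᵢ) are maintained incrementally across events (the
mover's row is rebuilt, every other cell gets the old kernel value swapped
for the new one); neighbour sums are evaluated exactly over all cells rather
than within a cutoff — at the population sizes of interest (n ≤ ~320) the
exact O(n) update costs microseconds in the compiled (numba) event loop and
avoids truncation bias. A from-scratch recomputation is kept as a test
oracle and agrees with the incremental sums to 10⁻¹⁰ after ~10⁴ events.
Snapshots record the state after the last event not exceeding each requested
output time (the process is right-continuous). If the total rate reaches
zero the configuration is frozen, remaining snapshots repeat it, and the run
is flagged. A replicate is fully determined by its integer seed; replicate r
of an ensemble uses base_seed + r.

A pure-Python single-event implementation (`gillespie_step`) exposes the
same transition law; the compiled loop was cross-checked against it on the
strong-interaction regime (α = 1000 h⁻¹ at the fibroblast-scale geometry):
both give the same relaxation of the high-rate tail.

## Pair-correlation estimation

All ordered pairs (i ≠ j) contribute one distance each (each cell serves as
reference once). Distances are binned into half-open annuli ((k−1)δr, kδr]
with centers r_k = (k−½)δr; values exactly on an edge go to the lower bin.
Bin k's count is normalized by n(n−1)·2π r_k δr/(LxLy) — the bin-center
radius, not the exact annulus area — so a conditioned-Poisson pattern has
expectation 1 in every bin. Periodic estimation (minimum image) is used for
simulation output, with r_max capped at min(Lx, Ly)/2 where the minimum
image is valid. Coordinate tables from microscopy are analysed
non-periodically with **no edge correction**: corrections can bias
structured patterns in uncontrolled ways, so raw pair distances are
reported, and the estimate consequently falls below 1 at separations
comparable to the image size (visible in a 4500 × 450 µm strip beyond a few
hundred µm). Replicate averaging is bin-wise arithmetic, with the
between-replicate standard error recorded.

## Moment dynamics

For a spatially homogeneous population the pair density depends only on the
displacement ξ. Substituting the Kirkwood closure into the pair-level rate
and bias and rewriting in displacement space gives

M₂(ξ) = m + (1/Z₁³) ∫ w(z) Z₂(z) Z₂(z−ξ) dz + w(ξ)
b₂(ξ) = (1/Z₁³) ∫ ∇v(z) Z₂(z) Z₂(z−ξ) dz + ∇v(ξ)
dZ₂(ξ)/dt = −2 M₂(ξ) Z₂(ξ) + 2 ∫ f_L(r) g(θ; b₂(ξ+s)) M₂(ξ+s) Z₂(ξ+s) dr dθ,

where s = (r cos θ, r sin θ) is the step of the moving pair member (a step s
carries a pair from displacement ξ+s to ξ), f_L the truncated-normal length
density and g the von Mises density. Evenness of Z₂ makes the out/in terms
of the two pair members coincide pairwise, hence the factors 2. Following
the regime in which the continuum model is valid, no max(0, ·) clamp is
applied to M₂; a negative expected rate anywhere triggers a warning that the
parameters are outside the model's validity. The derivation is certified
operationally: the solver's steady state reproduces replicate-averaged
simulation PCFs within Monte-Carlo error for regular patterns (see tests).

### Discretization

* ξ-grid: square, symmetric, spacing Δ, half-width ξ_max (odd point count);
  Z₂ = Z₁² (and b₂ = 0, M₂ at its far-field value) beyond the grid.
* The z-integrals are discrete cross-correlations, evaluated spectrally
  (zero-padded FFT convolution against the deviation field Z₂ − Z₁², plus
  the closed flat-field contribution) or by direct summation; both paths
  agree to 10⁻⁸ and the direct path doubles as the quadrature oracle.
* Step integral: radial nodes are Gauss–Legendre points mapped through the
  inverse CDF of the truncated-normal length law (they track the density's
  peak for any parameters), with weights normalized to unit mass so the
  discrete step law is exactly a probability law — otherwise the ~10⁻⁷
  truncation deficit shows up as a spurious source at flat states. Angles
  are a uniform grid whose size grows as ~6√κ_max + 8 with the largest bias
  concentration present (the aliasing error of the periodic trapezoid rule
  on e^{κ cos θ} is ~I_N(κ)/I₀(κ)); `n_theta` is a floor, 32 by default.
  Each (r, θ) node shifts the whole pair-flux field G = g·M₂·Z₂ by one
  constant offset, so the integral is a weighted sum of uniformly shifted,
  bilinearly blended copies of G — the entire right-hand side is vectorized
  array arithmetic.
* Time stepping: explicit RK4 from the uncorrelated state Z₂ ≡ Z₁², with
  dt = 0.4/max M₂ (the dominant eigenvalues are the out-rates −2M₂; RK4 is
  stable to |λ|dt ≈ 2.8, so this keeps a 3–4× margin). Convergence is
  declared when max|dZ₂/dt|/Z₁² < tol (default 10⁻⁶ h⁻¹). After the physical
  transient the residual is dominated by wide, slowly diffusing modes, so
  once it falls below `switch_res` (10⁻²) the solve is finished by a
  Jacobian-free Newton–Krylov root solve; if that fails or returns a
  negative root the solver falls back to pure marching. Negative Z₂ values
  are clamped to zero and counted — persistent clamping marks closure
  breakdown (strong clustering) and is logged.
* C_SM(r) is reported as the annular average of Z₂/Z₁² in rings of width Δ
  (the converged field is radially symmetric; the axis section agrees with
  the annular average to < 1%, and a diagnostic test checks this).

The closure is known to be accurate for Poisson and regular patterns and to
under-predict pair densities for strong clustering; the solver makes no
attempt to correct this, it only reports it (clamp counts, comparison tests
allow the under-prediction for the strongly attractive parameter set).

## Structure metrics and fitting

∫₀ᴿ(1 − C) dr and ∫₀ᴿ|1 − C| dr are evaluated as bin sums (rectangle rule,
consistent with the PCF bins) over bins with centers ≤ R; R defaults to
80 µm and should align with a bin edge. Positive signed area = regular,
negative = clustered. The density–structure relationship is an ordinary
least-squares regression of metric on average density (cells/µm², per-image
count divided by image area) with the standard two-sided t-test p-value.
β is estimated from a target PCF by grid search, scoring each candidate by
the sum of squared differences between the model PCF (steady-state moment
solution, or replicate-averaged simulation) interpolated onto the target's
bins, below a separation cap (default 150 µm). Least squares replaces visual
curve matching; the discrepancy profile over the grid is returned so the
flatness of the objective (the fit's sensitivity) can be inspected.

## Synthetic patterns

Test fixtures are generated, never stored: conditioned Poisson (n uniform
points), Matérn cluster (uniform parents, Poisson-distributed offspring
uniform in a disc, toroidal wrap) and sequential hard core (dart throwing
with the periodic metric, packing feasibility checked, bounded retries).
They provide the known-answer patterns — C ≡ 1, short-range excess,
short-range exclusion — against which the estimators are validated.

### What the generators do and do not emulate

The synthetic patterns and the simulator itself represent cells as points:
there is no hard volume exclusion (crowding is soft, through w and v), no
cell shape, no proliferation or death, and the domain is a homogeneous
torus. Passing tests therefore demonstrate the estimators and the
moment-closure machinery on populations matching these assumptions; real
microscopy data additionally contain finite cell areas, density gradients
across the field of view and non-periodic boundaries, of which only the last
is addressed (by the uncorrected non-periodic estimator).

## Problem sizes used in the test suite

Replicate ensembles in the tests use 40–300 patterns or 100 simulation
replicates, chosen so Monte-Carlo standard errors are a few ×10⁻² on PCF
values — small enough to resolve every qualitative claim being tested while
keeping the full suite in the minutes range. The moment solver's comparison
runs use the production grids (Δ = 0.1, ξ_max = 4 µm; Δ = 5, ξ_max = 150 µm)
at tol = 10⁻⁵–10⁻⁴, where the residual contributes ≲10⁻³ to C.

## Known limitations

* The Kirkwood closure under-predicts clustering; for strongly attractive
  parameters the moment model is a lower bound on short-range pair density.
* Expected-rate clamping is absent from the continuum model by construction;
  parameter sets that drive M₂ negative are flagged, not solved.
* The high-motility-tail summary (share of cells with ψ > 100 h⁻¹ under
  α = 1000 h⁻¹) is evaluated on Poisson-seeded configurations: the
  interaction itself dissolves close pairs within minutes of model time, so
  after relaxation almost no cells remain above the threshold (~1%); the
  seeded-configuration share (~19%) is the meaningful measure of how often
  randomly placed cells would exceed a biologically plausible speed.
* Heterogeneous (spatially varying Z₁) moment dynamics, anisotropic or
  non-Gaussian kernels, and birth–death processes are out of scope.
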