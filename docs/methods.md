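# Methods

This note records the modelling conventions, defaults, and numerical
choices behind `mlpot`, and what the toy-potential test bed does and does
not demonstrate about real molecular data.

## Units and constants

Internal units are Å (length), fs (time), Da (mass), hartree (energy),
kelvin (temperature).  All conversions live in `mlpot.constants` (CODATA
2018 / exact SI values): hartree ↔ kcal/mol = 627.5094740631, bohr =
0.529177210903 Å, k_B = 3.1668×10⁻⁶ hartree/K, and the
force-to-acceleration factor hartree/(Da·Å²/fs²) ≈ 0.26255.  A *reduced*
unit mode (k_B = 1, conversion factors 1) is available in the dynamics
module for textbook checks such as the unit-frequency oscillator.

## Kernels

Seven families with the hyperparameters σ (length scale), n (Matérn
order, non-negative integer), p (period), σ_p (periodic length scale).
The Gaussian uses the 1/(2σ²) convention; distances are Euclidean except
the Laplacian (L1).  The Matérn normalization
`exp(−d/σ) Σ_k (n+k)!/(2n)! C(n,k) (2d/σ)^{n−k}` collapses exactly to the
exponential kernel at n = 0, which the tests verify.  The periodic
families apply sin² to the Euclidean *norm* of the difference; on
multivariate inputs this is symmetric but **not guaranteed positive
semidefinite** — the linear solver therefore backs up its Cholesky path
(jitter escalation 0 → 10⁻¹² → 10⁻¹⁰ → 10⁻⁸) with a symmetric-indefinite
LDLᵀ solve, and raises with advice to increase λ only when the system is
genuinely singular.

Kernel derivatives (needed for gradient training) are analytic for the
Gaussian; every other family uses central finite differences (default
step 10⁻⁶ on descriptor coordinates), with a warning when differencing
the non-smooth Laplacian near a coincident coordinate.

## Descriptors

Pair ordering is (i < j) in atom-index order.  The equilibrium-normalized
descriptor is r_eq,ij / r_ij (value > 1 for a compressed pair); its
reference defaults to the lowest-energy training geometry.  The Coulomb
matrix uses bohr for internuclear distances (the convention of the
original descriptor literature), 0.5 Z^2.4 diagonals, optional row-norm
sorting (stable sort, ties keep atom order) for permutation invariance,
and zero-padding to a fixed size.  Jacobians are analytic for all three
kinds; for the sorted Coulomb matrix the Jacobian is taken at the fixed
sorted order, i.e. the descriptor is differentiated piecewise and is not
differentiable exactly at sorting ties.

## Regression

Labels are shifted by their training mean before solving (conditioning;
restorable on prediction).  The shift is a modelling choice, not a
necessity — for the linear kernel, whose span contains no constant, it
must be disabled to reproduce linear data exactly (`shift_labels=False`).

Gradient-augmented training follows the Gaussian-process-with-derivatives
construction: the kernel matrix over N geometries with 3M Cartesian
coordinates each is the (N(1+3M))² block matrix of kernel values,
first derivatives (chain-ruled through descriptor Jacobians), and mixed
second derivatives; energy rows carry λ_E and gradient rows λ_G on the
diagonal.  Two regularizers are deliberate: energies and gradient
components live on different scales.  Defaults λ_E = λ_G = 10⁻¹⁰.

Grid search splits training data into subtraining and validation
(default 80/20, seeded permutation), evaluates the full Cartesian product
of the grids, breaks exact loss ties toward smaller σ then smaller λ, and
retrains the winner on the whole training set — kernel models have a
closed-form solution, so the retrain is cheap and uses all data.
Gradient RMSE in combined losses pools gradient components across
molecules (rather than per-molecule norms); this is an assumption the
loss spec makes explicit.

## Composite models

Model-tree nodes combine child evaluations element-wise by sum or
weighted average; averaging nodes with ≥ 2 children report the population
standard deviation of the children's energies as `energy_uncertainty`
(the usual ensemble-spread convention).  Δ-learning trains the correction
on residuals `target − baseline` over the training geometries and returns
`sum(baseline, correction)`, so `composite − baseline − correction = 0`
holds identically at every query point.  Self-correcting stacks fit each
layer to the residual left by the sum of previous layers.

**When Δ-learning helps — an empirical finding from this test bed.**  With
noise-free labels, a 1-D diatomic, and a curvature-matched harmonic
baseline under a Morse target, the composite consistently *loses* to
direct ML regardless of σ and λ: the direct fit benefits from systematic
error cancellation between the quadratic and anharmonic components (both
prediction errors are governed by the same extrapolation-toward-the-mean
structure and carry opposite signs in the sparsely sampled tails), while
the correction inherits a diverging −½kΔr² tail that a stationary kernel
extrapolates badly.  The packaged demonstration therefore uses the regime
the method is actually for — data scarcity on a multidimensional surface
with a baseline whose residual is genuinely small: an equilateral
H₃-like cluster under pairwise Morse (De = 0.17 hartree, a = 0.6 Å⁻¹,
r₀ = 0.95 Å), harmonic baseline with k = 2De·a², Gaussian displacement
sampling (σ_disp = 0.03 Å), 15 training geometries, Gaussian kernel
σ = 1, λ = 10⁻¹⁰.  Under these conditions the composite beats direct ML
by a factor ≈ 2–3 across seeds.

## Simulation

Finite differences default to a 5.29×10⁻⁴ Å step (≈ 10⁻³ bohr); gradients
are central differences (6N energy calls), Hessians either differences of
model gradients (semianalytical) or second differences of energies, both
symmetrized as (H + Hᵀ)/2.

Geometry optimization wraps scipy's L-BFGS-B on Cartesian coordinates and
re-checks convergence against a max-abs gradient tolerance of
4.5×10⁻⁴ hartree/Å; non-convergence is reported explicitly, never
silently.  The optimizer inherits the usual ML-potential hazard: outside
the sampled region the model extrapolates toward its label mean and can
fabricate spurious minima, so optimizations should start inside the
training distribution (the README example shows both behaviors).

Normal-mode analysis mass-weights the Hessian, projects out the 3
translations and the 2 or 3 rotations (a molecule is linear when its
smallest principal moment of inertia is below 10⁻⁸ Da·Å²), diagonalizes,
and discards the projected near-zero eigenvalues by magnitude.  Negative
curvature is reported as a negative wavenumber and excluded (with a
warning) from thermal functions.  ZPVE = ½Σ hcν̃ over real modes.

Thermochemistry is ideal-gas RRHO at T and p (default 298.15 K, 1 atm):
E_trans = 3/2 k_BT; E_rot = 0 / k_BT / 3/2 k_BT for atoms / linear /
nonlinear; vibrational thermal energy Σ hcν̃/(e^{hcν̃/k_BT} − 1) with ZPVE
kept separate; S from Sackur–Tetrode, classical rigid-rotor, and harmonic
oscillator partition functions; symmetry number and electronic degeneracy
default to 1 (configurable).  The absolute enthalpy is

    H_T = E_tot + ZPVE + E_trans + E_rot + E_vib,thermal + k_BT,

with the single trailing k_BT the ideal-gas pV term, and a free atom gets
H_T(A) = E(A) + 5/2 k_BT.  Heats of formation follow the atomization
route, ΔH_f = Σ_A ΔH_f(A) − ΔH_at, with shipped reference tables of
fitted free-atom energies (two variants) and the conventional
experimental atomic ΔH_f values for H, C, N, O (52.102, 170.89, 113.00,
59.559 kcal/mol).

## Dynamics

Velocity Verlet, one force evaluation per step; any model returning
energy gradients works, conservative or not.  N_dof defaults to 3N with
no COM correction, matching T = 2E_kin/(N_dof·k_B).  Maxwell–Boltzmann
initialization draws each component from N(0, k_BT/m_i) with optional COM
momentum removal; one generator is seeded per run.

The Andersen thermostat resamples each atom's velocity after the Verlet
step with probability vΔt per step (configuration error if vΔt > 1),
drawing atoms in fixed index order for reproducibility.  The Nosé–Hoover
thermostat is a single-variable chain with mass Q = N_dof·k_B·T·τ²
(default coupling time τ = 20 fs), integrated as symmetric half-steps
around the Verlet update; the extended energy
E + ½Q·v_ξ² + N_dof·k_B·T·ξ is recorded every step as the conservation
diagnostic.  Integrator checks in the suite use the reduced-unit
oscillator with dt = 0.0015 (energy-drift bound; the Verlet energy error
for this system oscillates with amplitude ≈ dt²/4 of the total energy,
so this step keeps a comfortable margin under 10⁻⁶) and dt = 0.002 for
the thermostat conservation runs.

## Spectra

The autocorrelation C(τ) averages x(t)·x(t+τ) over the N−τ available
origins (so a constant series gives |c|² at every lag), summed over
vector components, computed via FFT and verified against the direct
O(N²) sum.  Spectra apply a Hann window to the one-sided ACF, zero-pad to
the next power of two, and report FFT magnitudes on a wavenumber grid
ν̃ = f/c with resolution 1/(n_fft·Δt·c); the zero bin is dropped and the
grid truncated at 5000 cm⁻¹ by default.  IR spectra subtract the
time-mean dipole first — the permanent dipole belongs entirely to the
zero-frequency bin and would otherwise leak through the window into the
low-frequency region.  No thermal/quantum prefactor is applied by
default; a multiplicative hook takes any user-supplied correction.

## Synthetic data

The toy potentials (harmonic bond, Morse, Lennard-Jones, double well —
all pairwise over atoms — plus independent harmonic wells for uncoupled
3-D oscillators) have closed-form energies, exact gradients, and an
optional per-atom-charge linear dipole.  Diatomic toys use two explicit
atoms in 3-D so descriptors, optimization, MD and frequencies all run
unchanged.  The generator samples bond lengths uniformly or displaces all
Cartesians normally, attaches exact labels, and optionally adds Gaussian
label noise; everything is reproducible by seed.

What passing on this bed shows: the algebra and calculus of the pipelines
are right (interpolation, derivative consistency, conservation laws,
closed-form limits).  What it does not show: behavior under realistic
label noise and model-form error, conformational diversity,
many-body/permutational structure beyond three atoms, or descriptor
scalability — global pairwise descriptors grow as N² and the
gradient-trained kernel matrix as (N_tr(1+3M))², which is the practical
size limit of this implementation.

## Known limitations

- Global descriptors require a fixed element sequence; heterogeneous
  databases are accepted as containers but rejected by descriptor models.
- No periodic boundary conditions, constraints, barostats, or
  transition-state search.
- Kernel derivative blocks for non-Gaussian kernels use finite
  differences and are an order of magnitude slower and less precise than
  the analytic Gaussian path.
- The L-BFGS optimizer targets minima only and trusts the model
  everywhere; see the extrapolation caveat above.
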