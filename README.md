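# mlpot

Kernel-method interatomic potentials and the simulation tasks built on top
of them — training, geometry optimization, harmonic frequencies and
thermochemistry, heats of formation, molecular dynamics, and infrared /
power spectra — in one tested Python package.  Everything is exercised on
analytic toy potentials with exact gradients, so every result can be
checked against a closed form.

## Who this is for

Computational chemists and method developers who want a transparent,
dependency-light implementation of the machinery behind machine-learned
potential-energy surfaces: how gradient-augmented kernel ridge regression
is assembled, how a Δ-learning composite is wired, how a Nosé–Hoover
thermostat conserves its extended energy, or how an IR spectrum falls out
of a dipole autocorrelation.

## The models

**Kernel ridge regression (KRR).** Given training inputs **x**_j and labels
y_j, the prediction is

    f(x) = Σ_j α_j k(x, x_j; h) + shift,      (K + λI) α = y − shift,

with kernel families linear, Gaussian `exp(−‖d‖²/2σ²)`, exponential,
Laplacian (L1), Matérn of integer order n, periodic, and decaying periodic.
Hyperparameters **h** (σ, n, p, σ_p) and the regularizer λ are tuned by
exhaustive grid search against a hold-out validation loss (energy RMSE,
the geometric mean √(RMSE_E · RMSE_G), a weighted sum, or a custom
callable), with k-fold and leave-one-out cross-validation and learning
curves as diagnostics.

**Molecular potentials (KREG-style).** Geometries enter through a global
descriptor — inverse internuclear distances 1/r_ij, their
equilibrium-normalized form r_eq,ij/r_ij (the default), or the Coulomb
matrix — and a Gaussian kernel.  Training can include Cartesian energy
gradients: the kernel matrix is extended with first- and second-derivative
blocks through the descriptor Jacobian chain rule, with separate
regularizers λ_E and λ_G, and the fitted model predicts both the energy
and its exact Cartesian gradient.

**Composite model trees.** Leaves are any objects that evaluate a molecule;
internal nodes combine children by sum or (weighted) average, with the
population standard deviation of an averaging ensemble reported as an
uncertainty.  Δ-learning (`baseline + correction trained on residuals`)
and self-correcting stacks are built from the same node type.

**Simulation.** Any energy/force model — a fitted potential, a composite
tree, or an analytic toy — drives batch single points, L-BFGS geometry
optimization, semianalytical or fully numerical Hessians, mass-weighted
normal-mode analysis with rigid-body projection, ideal-gas RRHO
thermochemistry (ZPVE, H_T, S, G_T), atomization-based heats of formation,
velocity-Verlet MD in NVE or NVT (Andersen or single-chain Nosé–Hoover),
and spectra from trajectory autocorrelations.

Internal units: Å, fs, Da, hartree, K.

## Worked example

Fit a gradient-trained potential to ten samples of a Morse diatomic
(De = 0.17 hartree, a = 1.9 Å⁻¹, r₀ = 0.95 Å), then optimize and analyze
on the learned surface:

```python
import numpy as np
import mlpot as mp
from mlpot.kernels import KernelSpec

pot = mp.ToyPotential("morse", De=0.17, a=1.9, r0=0.95)
eq = mp.make_diatomic(0.95)
train = mp.generate_database(pot, eq, 10, seed=1,
                             mode="uniform_bond", bond_range=(0.75, 1.4))
model = mp.train_kreg(train, kernel=KernelSpec("gaussian", sigma=0.5),
                      lambda_E=1e-12, lambda_G=1e-12, use_gradients=True)

test = mp.generate_database(pot, eq, 40, seed=7,
                            mode="uniform_bond", bond_range=(0.75, 1.4))
pred = np.array([model.predict_energy(m) for m in test])
print(mp.error_statistics(pred, test.energies()))

opt = mp.optimize_geometry(model, mp.make_diatomic(1.05), gradient_tol=1e-6)
r = np.linalg.norm(opt.molecule.coordinates[1] - opt.molecule.coordinates[0])
print(f"optimized bond length: {r:.6f} A   energy: {opt.energy:.8f} hartree")
analysis = mp.harmonic_frequencies(mp.numerical_hessian(model, opt.molecule),
                                   opt.molecule)
print(f"harmonic wavenumber: {analysis.wavenumbers[0]:.2f} cm^-1")
```

prints

```
RMSE                3.27110590e-08
MAE                 2.93187250e-08
mean signed error  -2.33171745e-09
Pearson r           1.00000000
R^2                 1.00000000
...
optimized bond length: 0.950000 A   energy: -0.17000004 hartree
harmonic wavenumber: 4245.07 cm^-1
```

Ten gradient-labelled points reproduce held-out energies to 3×10⁻⁸ hartree
RMSE; the minimum of the learned surface sits at the true r₀ = 0.95 Å with
E = −De, and its harmonic wavenumber matches the one computed on the
analytic surface (4245.06 cm⁻¹) to 0.01 cm⁻¹.

## Command line

A keyword front end mirrors the library for shell use:

```sh
mlpot geomopt initxyz=init.xyz potential=morse de=0.17 a=1.9 r0=0.95 optxyz=opt.xyz
mlpot createmlmodel xyzfile=train.xyz yfile=y.dat kernel=gaussian sigma=0.5 \
      lambda=1e-10 mlmodelout=model.json
mlpot md initxyz=opt.xyz potential=morse dt=0.25 nsteps=8192 trajout=traj.json
mlpot spectrum trajin=traj.json kind=power specout=spectrum.dat
```

`mlpot --help` documents the grammar (one task word, then `key=value`
pairs, inline or in a file).

## Layout

```
src/mlpot/
  data.py         molecules, databases, XYZ/JSON/npz I/O, splits, statistics
  descriptors.py  inverse-distance / RE / Coulomb-matrix descriptors + Jacobians
  kernels.py      the kernel family and its derivatives
  models.py       KernelRidge & KREG (model -> fit() -> results), model trees,
                  grid search, cross-validation, learning curves
  simulate.py     single points, FD derivatives, optimization, frequencies,
                  RRHO thermochemistry, heats of formation
  dynamics.py     velocity-Verlet MD, Andersen & Nosé–Hoover thermostats
  spectra.py      autocorrelation, power & IR spectra
  toys.py         analytic toy potentials + synthetic database generator
  cli.py          keyword-file front end
docs/methods.md   modelling assumptions, defaults, numerical choices
```
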