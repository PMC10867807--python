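"""Single points, numerical derivatives, geometry optimization, harmonic
frequencies, RRHO thermochemistry and heats of formation.

Every routine takes a *model*: any object implementing
``evaluate(molecule, gradients=...) -> dict`` with an ``energy`` in hartree
and, when available, ``energy_gradients`` in hartree/angstrom.  Models that
only provide energies fall back to central finite differences for
gradients and Hessians.

Thermochemistry uses the ideal-gas rigid-rotor harmonic-oscillator (RRHO)
partition functions at temperature T and pressure p.  The absolute enthalpy
convention is

    H_T = E_tot + ZPVE + E_trans,T + E_rot,T + E_vib,T(thermal) + k_B T

(the trailing k_B T is the ideal-gas pV term; per-molecule units, hartree),
and for a free atom H_T(A) = E(A) + (5/2) k_B T.  Heats of formation follow
the atomization route: DH_at,T = sum_A H_T(A) - H_T(molecule), then
DH_f,T = sum_A DH_f,T(A) - DH_at,T using experimental atomic heats of
formation (52.102, 170.89, 113.00, 59.559 kcal/mol for H, C, N, O).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from . import constants as const
from .data import Molecule, MolecularDatabase

__all__ = [
    "single_point_batch",
    "numerical_gradient",
    "numerical_hessian",
    "optimize_geometry",
    "OptimizationResult",
    "harmonic_frequencies",
    "HarmonicAnalysis",
    "thermochemistry",
    "ThermoResult",
    "AtomicReferenceTable",
    "ANI1CCX_REFERENCE",
    "AIQM1_REFERENCE",
    "heat_of_formation",
]

#: default displacement for finite differences, ~1e-3 bohr in angstrom
FD_STEP = 5.29e-4


def _energy(model, mol: Molecule) -> float:
    return float(model.evaluate(mol, gradients=False)["energy"])


def model_gradients(model, mol: Molecule, step: float = FD_STEP) -> np.ndarray:
    """Gradients from the model, or finite differences when unavailable."""
    try:
        out = model.evaluate(mol, gradients=True)
    except TypeError:
        out = model.evaluate(mol)
    if "energy_gradients" in out:
        return np.asarray(out["energy_gradients"], dtype=float)
    return numerical_gradient(model, mol, step)


def single_point_batch(
    model, db: MolecularDatabase, properties: tuple[str, ...] = ("energy",)
) -> list[tuple[int, str]]:
    """Attach requested properties to every molecule of a database.

    Per-molecule failures are recorded and the batch continues; the list of
    ``(index, message)`` failures is returned.  Gradients are computed by
    finite differences when the model does not provide them natively.
    """
    failures: list[tuple[int, str]] = []
    for i, mol in enumerate(db):
        try:
            want_grad = "energy_gradients" in properties
            if want_grad:
                out = {"energy": _energy(model, mol),
                       "energy_gradients": model_gradients(model, mol)}
            else:
                out = model.evaluate(mol, gradients=False)
            for key in properties:
                if key == "hessian":
                    mol.set_property("hessian", numerical_hessian(model, mol))
                elif key in out:
                    mol.set_property(key, out[key])
                else:
                    raise KeyError(f"model does not provide {key!r}")
        except Exception as exc:  # noqa: BLE001 — batch must continue
            failures.append((i, str(exc)))
    if failures and len(failures) == len(db):
        raise RuntimeError(f"all {len(db)} single points failed: {failures[0][1]}")
    return failures


def numerical_gradient(model, mol: Molecule, step: float = FD_STEP) -> np.ndarray:
    """Central-difference Cartesian gradient (6 N energy evaluations)."""
    if step <= 0:
        raise ValueError("step must be > 0")
    coords = mol.coordinates
    grad = np.zeros_like(coords)
    probe = mol.copy(copy_properties=False)
    for i in range(mol.natoms):
        for c in range(3):
            xyz = coords.copy()
            xyz[i, c] += step
            probe.coordinates = xyz
            ep = _energy(model, probe)
            xyz[i, c] -= 2 * step
            probe.coordinates = xyz
            em = _energy(model, probe)
            grad[i, c] = (ep - em) / (2 * step)
    return grad


def numerical_hessian(
    model, mol: Molecule, step: float = FD_STEP, from_gradients: bool | None = None
) -> np.ndarray:
    """3N x 3N Hessian: semianalytical (differences of gradients) when the
    model provides gradients, otherwise second differences of energies.
    The result is symmetrized as (H + H^T)/2."""
    if step <= 0:
        raise ValueError("step must be > 0")
    n3 = 3 * mol.natoms
    coords = mol.coordinates.ravel()
    probe = mol.copy(copy_properties=False)
    if from_gradients is None:
        try:
            from_gradients = "energy_gradients" in model.evaluate(mol, gradients=True)
        except Exception:
            from_gradients = False
    H = np.zeros((n3, n3))
    if from_gradients:
        for a in range(n3):
            x = coords.copy()
            x[a] += step
            probe.coordinates = x
            gp = model_gradients(model, probe).ravel()
            x[a] -= 2 * step
            probe.coordinates = x
            gm = model_gradients(model, probe).ravel()
            H[:, a] = (gp - gm) / (2 * step)
    else:
        e0 = _energy(model, mol)
        ediag = np.zeros((n3, 2))
        for a in range(n3):
            for s, sgn in enumerate((+1, -1)):
                x = coords.copy()
                x[a] += sgn * step
                probe.coordinates = x
                ediag[a, s] = _energy(model, probe)
            H[a, a] = (ediag[a, 0] - 2 * e0 + ediag[a, 1]) / step**2
        for a in range(n3):
            for b in range(a + 1, n3):
                vals = []
                for sa, sb in ((+1, +1), (+1, -1), (-1, +1), (-1, -1)):
                    x = coords.copy()
                    x[a] += sa * step
                    x[b] += sb * step
                    probe.coordinates = x
                    vals.append(_energy(model, probe))
                H[a, b] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * step**2)
                H[b, a] = H[a, b]
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Geometry optimization
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    """Path and outcome of a local minimization."""

    molecule: Molecule
    energy: float
    converged: bool
    n_steps: int
    max_gradient: float
    path: list[Molecule] = field(default_factory=list, repr=False)

    def dump_xyz(self, path) -> str:
        from .data import write_xyz

        db = MolecularDatabase(self.path or [self.molecule])
        return write_xyz(db, path)


def optimize_geometry(
    model,
    mol0: Molecule,
    gradient_tol: float = 4.5e-4,
    max_iter: int = 200,
) -> OptimizationResult:
    """Quasi-Newton (BFGS-family) minimization on Cartesian coordinates.

    Converged when the largest absolute gradient component drops below
    ``gradient_tol`` (hartree/angstrom); otherwise returns with
    ``converged=False`` after ``max_iter`` iterations.  Each accepted step
    is recorded in ``path`` (the starting geometry first).
    """
    work = mol0.copy(copy_properties=False)
    n = work.natoms

    def fun(x):
        work.coordinates = x.reshape(n, 3)
        e = _energy(model, work)
        if not np.isfinite(e):
            raise FloatingPointError("non-finite energy during optimization")
        g = model_gradients(model, work)
        return e, g.ravel()

    path: list[Molecule] = [mol0.copy(copy_properties=False)]

    def record(xk):
        snap = mol0.copy(copy_properties=False)
        snap.coordinates = xk.reshape(n, 3)
        path.append(snap)

    x0 = mol0.coordinates.ravel()
    e0, g0 = fun(x0)
    if np.max(np.abs(g0)) <= gradient_tol:
        final = mol0.copy(copy_properties=False)
        final.set_property("energy", e0)
        return OptimizationResult(final, e0, True, 0, float(np.max(np.abs(g0))), path)

    res = scipy.optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": max_iter, "gtol": gradient_tol * 1e-2, "ftol": 1e-15},
    )
    final = mol0.copy(copy_properties=False)
    final.coordinates = res.x.reshape(n, 3)
    e_fin, g_fin = fun(res.x)
    max_g = float(np.max(np.abs(g_fin)))
    final.set_property("energy", e_fin)
    final.set_property("energy_gradients", g_fin.reshape(n, 3))
    return OptimizationResult(
        final, e_fin, max_g <= gradient_tol, int(res.nit), max_g, path
    )


# ---------------------------------------------------------------------------
# Harmonic frequencies
# ---------------------------------------------------------------------------

def principal_moments(mol: Molecule) -> np.ndarray:
    """Principal moments of inertia in Da * A^2 (ascending)."""
    m = mol.masses
    com = (m[:, None] * mol.coordinates).sum(0) / m.sum()
    r = mol.coordinates - com
    I = np.zeros((3, 3))
    for mi, ri in zip(m, r):
        I += mi * ((ri @ ri) * np.eye(3) - np.outer(ri, ri))
    return np.sort(np.linalg.eigvalsh(I))


def is_linear(mol: Molecule, moment_tol: float = 1e-8) -> bool:
    """Linear when the smallest principal moment is below ``moment_tol``."""
    if mol.natoms == 1:
        return False
    return principal_moments(mol)[0] < moment_tol


@dataclass
class HarmonicAnalysis:
    """Vibrational analysis at a stationary point."""

    wavenumbers: np.ndarray        # cm^-1, ascending; imaginary modes negative
    modes: np.ndarray              # 3N x n_modes mass-weighted eigenvectors
    zpve: float                    # hartree, over real modes only
    linear: bool
    n_imaginary: int


def harmonic_frequencies(
    hessian: np.ndarray, mol: Molecule, symmetry_tol: float = 1e-6
) -> HarmonicAnalysis:
    """Mass-weight, project out rigid-body motion, diagonalize.

    Translations (and rotations for >= 2 atoms; 2 of them for a linear
    molecule) are projected out before diagonalization; the corresponding
    near-zero eigenvalues are discarded.  Wavenumbers come out as
    nu~ = sqrt(lambda)/(2 pi c); negative curvature is reported as a
    negative wavenumber.  ZPVE = 1/2 sum h c nu~ over real modes.
    """
    n = mol.natoms
    n3 = 3 * n
    H = np.asarray(hessian, dtype=float)
    if H.shape != (n3, n3):
        raise ValueError(f"hessian must be {n3} x {n3}")
    asym = np.max(np.abs(H - H.T))
    if asym > symmetry_tol:
        raise ValueError(f"hessian asymmetric beyond tolerance ({asym:g})")
    H = 0.5 * (H + H.T)

    m = np.repeat(mol.masses, 3)
    Hmw = H / np.sqrt(np.outer(m, m))

    # rigid-body basis in mass-weighted coordinates
    linear = is_linear(mol)
    sqm = np.sqrt(mol.masses)
    vecs = []
    for c in range(3):
        t = np.zeros((n, 3))
        t[:, c] = sqm
        vecs.append(t.ravel())
    if n >= 2:
        com = (mol.masses[:, None] * mol.coordinates).sum(0) / mol.masses.sum()
        rel = mol.coordinates - com
        for c in range(3):
            axis = np.zeros(3)
            axis[c] = 1.0
            rot = np.cross(np.broadcast_to(axis, (n, 3)), rel) * sqm[:, None]
            if np.linalg.norm(rot) > 1e-10:
                vecs.append(rot.ravel())
    B = np.array(vecs).T  # null rotations were filtered above
    Q, _ = np.linalg.qr(B)
    P = np.eye(n3) - Q @ Q.T

    Hproj = P @ Hmw @ P
    eigvals, eigvecs = np.linalg.eigh(0.5 * (Hproj + Hproj.T))
    order = np.argsort(np.abs(eigvals))
    n_modes = n3 - (3 if n == 1 else (5 if linear else 6))
    keep_idx = np.sort(order[n3 - n_modes:]) if n_modes > 0 else np.array([], int)
    lam = eigvals[keep_idx]
    modes = eigvecs[:, keep_idx]

    omega = np.sign(lam) * np.sqrt(np.abs(lam)) * const.OMEGA_SI_PER_SQRT_EIG
    wavenumbers = omega / (2 * np.pi * const.SPEED_OF_LIGHT_CM)
    srt = np.argsort(wavenumbers)
    wavenumbers = wavenumbers[srt]
    modes = modes[:, srt]
    real = wavenumbers[wavenumbers > 0]
    zpve = 0.5 * const.HC_HARTREE_CM * float(real.sum())
    return HarmonicAnalysis(
        wavenumbers, modes, zpve, linear, int(np.sum(wavenumbers < 0))
    )


# ---------------------------------------------------------------------------
# Thermochemistry
# ---------------------------------------------------------------------------

@dataclass
class ThermoResult:
    """Ideal-gas RRHO thermochemistry at temperature T (per molecule, hartree)."""

    T: float
    E_tot: float
    zpve: float
    E_trans: float
    E_rot: float
    E_vib: float          # thermal vibrational energy, ZPVE excluded
    H_T: float
    S: float              # hartree / K
    G_T: float
    delta_H_f: float | None = None   # kcal/mol

    def report(self) -> str:
        lines = [
            f"Thermochemistry at T = {self.T:.2f} K (RRHO, ideal gas)",
            f"  E_tot            {self.E_tot: .10f} hartree",
            f"  ZPVE             {self.zpve: .10f} hartree",
            f"  E_trans          {self.E_trans: .10f} hartree",
            f"  E_rot            {self.E_rot: .10f} hartree",
            f"  E_vib (thermal)  {self.E_vib: .10f} hartree",
            f"  H_T              {self.H_T: .10f} hartree",
            f"  S                {self.S: .12e} hartree/K",
            f"  G_T              {self.G_T: .10f} hartree",
        ]
        if self.delta_H_f is not None:
            lines.append(f"  Delta H_f        {self.delta_H_f: .3f} kcal/mol")
        return "\n".join(lines)

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "T", "E_tot", "zpve", "E_trans", "E_rot", "E_vib", "H_T", "S", "G_T",
            "delta_H_f")}
        return json.dumps(d)


def thermochemistry(
    freqs: np.ndarray | HarmonicAnalysis,
    mol: Molecule,
    T: float = 298.15,
    pressure: float = const.ATM_PA,
    symmetry_number: int = 1,
    electronic_degeneracy: int = 1,
    E_tot: float | None = None,
) -> ThermoResult:
    """RRHO thermal functions from harmonic wavenumbers.

    ``freqs`` is a :class:`HarmonicAnalysis` or an array of wavenumbers in
    cm^-1; negative (imaginary) wavenumbers are excluded with a warning.
    ``E_tot`` defaults to the molecule's attached energy (0 if absent).
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    if isinstance(freqs, HarmonicAnalysis):
        wn = np.asarray(freqs.wavenumbers, dtype=float)
    else:
        wn = np.asarray(freqs, dtype=float)
    if np.any(wn < 0):
        warnings.warn("imaginary wavenumbers excluded from thermochemistry")
        wn = wn[wn >= 0]
    wn = wn[wn > 0]
    if E_tot is None:
        E_tot = float(mol.properties.get("energy", 0.0))

    kT = const.KB_HARTREE * T

    # translation
    E_trans = 1.5 * kT
    M_kg = mol.masses.sum() * const.DALTON_SI
    kT_SI = const.BOLTZMANN_SI * T
    q_trans_vol = (2 * np.pi * M_kg * kT_SI / const.PLANCK_SI**2) ** 1.5 \
        * kT_SI / pressure
    S_trans = const.BOLTZMANN_SI * (np.log(q_trans_vol) + 2.5) / const.HARTREE_SI

    # rotation
    if mol.natoms == 1:
        E_rot, S_rot = 0.0, 0.0
        linear = False
    else:
        moments = principal_moments(mol)
        linear = moments[0] < 1e-8
        hbar = const.PLANCK_SI / (2 * np.pi)
        if linear:
            I_SI = moments[-1] * const.DALTON_SI * const.ANGSTROM_SI**2
            theta = hbar**2 / (2 * I_SI * const.BOLTZMANN_SI)
            q_rot = T / (symmetry_number * theta)
            E_rot = kT
            S_rot = const.BOLTZMANN_SI * (np.log(q_rot) + 1.0) / const.HARTREE_SI
        else:
            I_SI = moments * const.DALTON_SI * const.ANGSTROM_SI**2
            thetas = hbar**2 / (2 * I_SI * const.BOLTZMANN_SI)
            q_rot = np.sqrt(np.pi) / symmetry_number * np.sqrt(
                T**3 / np.prod(thetas)
            )
            E_rot = 1.5 * kT
            S_rot = const.BOLTZMANN_SI * (np.log(q_rot) + 1.5) / const.HARTREE_SI

    # vibration
    zpve = 0.5 * const.HC_HARTREE_CM * float(wn.sum())
    quanta = const.HC_HARTREE_CM * wn              # hartree per mode
    x = quanta / kT
    with np.errstate(over="ignore"):
        expm = np.expm1(x)
    E_vib = float(np.sum(quanta / expm)) if wn.size else 0.0
    S_vib = float(
        const.KB_HARTREE * np.sum(x / expm - np.log1p(-np.exp(-x)))
    ) if wn.size else 0.0

    S_elec = const.KB_HARTREE * math.log(electronic_degeneracy)
    H_T = E_tot + zpve + E_trans + E_rot + E_vib + kT
    S = S_trans + S_rot + S_vib + S_elec
    G_T = H_T - T * S
    return ThermoResult(T, E_tot, zpve, E_trans, E_rot, E_vib, H_T, S, G_T)


# ---------------------------------------------------------------------------
# Heats of formation
# ---------------------------------------------------------------------------

@dataclass
class AtomicReferenceTable:
    """Per-element free-atom energy (hartree) and experimental heat of
    formation of the free atom (kcal/mol)."""

    entries: dict[str, tuple[float, float]]

    def atomic_energy(self, element: str) -> float:
        return self._get(element)[0]

    def atomic_dHf(self, element: str) -> float:
        return self._get(element)[1]

    def _get(self, element: str) -> tuple[float, float]:
        try:
            return self.entries[element]
        except KeyError:
            raise KeyError(
                f"element {element} missing from the atomic reference table"
            ) from None


_ATOMIC_DHF = {"H": 52.102, "C": 170.89, "N": 113.00, "O": 59.559}

#: fitted free-atom energies of the ANI-1ccx pretrained method
ANI1CCX_REFERENCE = AtomicReferenceTable({
    "H": (-0.50088088, _ATOMIC_DHF["H"]),
    "C": (-37.79199048, _ATOMIC_DHF["C"]),
    "N": (-54.53379230, _ATOMIC_DHF["N"]),
    "O": (-75.00968205, _ATOMIC_DHF["O"]),
})

#: fitted free-atom energies of the AIQM1 pretrained method
AIQM1_REFERENCE = AtomicReferenceTable({
    "H": (-0.50088038, _ATOMIC_DHF["H"]),
    "C": (-37.79221710, _ATOMIC_DHF["C"]),
    "N": (-54.53360298, _ATOMIC_DHF["N"]),
    "O": (-75.00986203, _ATOMIC_DHF["O"]),
})


def heat_of_formation(
    H_T_molecule: float,
    composition: dict[str, int],
    reference_table: AtomicReferenceTable,
    T: float = 298.15,
) -> float:
    """Heat of formation (kcal/mol) via the atomization route.

    H_T(A) = E(A) + (5/2) k_B T per free atom;
    DH_at = sum_A H_T(A) - H_T(molecule);
    DH_f = sum_A DH_f,T(A) - DH_at (converted to kcal/mol).
    """
    kT = const.KB_HARTREE * T
    H_atoms = sum(
        n * (reference_table.atomic_energy(el) + 2.5 * kT)
        for el, n in composition.items()
    )
    dH_at = H_atoms - H_T_molecule
    dHf_atoms = sum(
        n * reference_table.atomic_dHf(el) for el, n in composition.items()
    )
    return float(dHf_atoms - dH_at * const.HARTREE_TO_KCALMOL)
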