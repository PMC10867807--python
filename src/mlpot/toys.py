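"""Analytic toy potentials with exact gradients and synthetic databases.

These potentials stand in for a quantum-chemistry backend: each one has a
closed-form energy, exact Cartesian gradients, and (optionally) a linear
dipole model, so every other part of the package — training, optimization,
frequencies, dynamics, spectra — can be exercised against known answers.

Available kinds (energies in hartree, distances in angstrom unless a
reduced-unit toy is built with unit masses and force constants):

* ``harmonic_bond``:   V(r) = 1/2 k (r - r0)^2 over every atom pair
* ``morse``:           V(r) = De [(1 - e^(-a (r - r0)))^2 - 1]
* ``lennard_jones``:   V(r) = 4 eps [(s/r)^12 - (s/r)^6]
* ``double_well``:     V(r) = barrier [((r - rm)/w)^2 - 1]^2, minima rm -/+ w
* ``harmonic_wells``:  atoms independently tethered to reference positions,
  V = 1/2 k sum_i |R_i - C_i|^2 (uncoupled 3-D oscillators)

The dipole model is a per-atom effective-charge map mu = sum_i q_i R_i —
linear in the geometry, which makes MD-derived IR peak positions exactly
comparable with harmonic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Atom, Molecule, MolecularDatabase

__all__ = ["ToyPotential", "make_diatomic", "generate_database"]

KINDS = ("harmonic_bond", "morse", "lennard_jones", "double_well", "harmonic_wells")


@dataclass
class ToyPotential:
    """Analytic potential over atom pairs (or per-atom wells).

    Parameters by kind — harmonic_bond: k (hartree/A^2), r0 (A);
    morse: De (hartree), a (1/A), r0 (A); lennard_jones: eps (hartree),
    sigma_lj (A); double_well: barrier (hartree), minima = (r1, r2) (A);
    harmonic_wells: k plus ``centers`` (natoms x 3 reference positions).

    ``charges``: optional per-atom effective charges (e) for the linear
    dipole model; when absent no dipole is produced.
    """

    kind: str
    k: float = 1.0
    r0: float = 1.0
    De: float = 0.1
    a: float = 1.0
    eps: float = 0.1
    sigma_lj: float = 1.0
    barrier: float = 0.05
    minima: tuple[float, float] = (0.8, 1.2)
    centers: np.ndarray | None = None
    charges: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown toy potential {self.kind!r}")
        if self.kind == "harmonic_wells" and self.centers is None:
            raise ValueError("harmonic_wells requires reference centers")
        if self.centers is not None:
            self.centers = np.asarray(self.centers, dtype=float)
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)

    # -- scalar pair potential ----------------------------------------------
    def pair_energy(self, r):
        """V(r) for the pairwise kinds (scalar or array)."""
        v, _ = self._pair(np.asarray(r, dtype=float))
        return v

    def _pair(self, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(V(r), dV/dr) for the pairwise kinds."""
        if self.kind == "harmonic_bond":
            d = r - self.r0
            return 0.5 * self.k * d**2, self.k * d
        if self.kind == "morse":
            ex = np.exp(-self.a * (r - self.r0))
            v = self.De * ((1 - ex) ** 2 - 1.0)
            dv = 2 * self.De * self.a * (1 - ex) * ex
            return v, dv
        if self.kind == "lennard_jones":
            sr6 = (self.sigma_lj / r) ** 6
            v = 4 * self.eps * (sr6**2 - sr6)
            dv = 4 * self.eps * (-12 * sr6**2 + 6 * sr6) / r
            return v, dv
        if self.kind == "double_well":
            r1, r2 = self.minima
            rm, w = 0.5 * (r1 + r2), 0.5 * (r2 - r1)
            s = (r - rm) / w
            return self.barrier * (s**2 - 1) ** 2, self.barrier * 4 * s * (s**2 - 1) / w
        raise AssertionError(self.kind)

    # -- evaluator protocol ---------------------------------------------------
    def evaluate(self, mol: Molecule, gradients: bool = True) -> dict:
        coords = mol.coordinates
        n = mol.natoms
        out: dict = {}
        if self.kind == "harmonic_wells":
            disp = coords - self.centers
            out["energy"] = float(0.5 * self.k * np.sum(disp**2))
            if gradients:
                out["energy_gradients"] = self.k * disp
        else:
            if n < 2:
                raise ValueError("pairwise toy potentials need >= 2 atoms")
            energy = 0.0
            grad = np.zeros((n, 3))
            for i in range(n):
                for j in range(i + 1, n):
                    dvec = coords[i] - coords[j]
                    r = float(np.linalg.norm(dvec))
                    if r < 1e-12:
                        raise ValueError("coincident atoms (r = 0)")
                    v, dv = self._pair(np.asarray(r))
                    energy += float(v)
                    g = float(dv) * dvec / r
                    grad[i] += g
                    grad[j] -= g
            out["energy"] = energy
            if gradients:
                out["energy_gradients"] = grad
        if self.charges is not None:
            out["dipole"] = self.charges @ coords
        return out

    def self_test(self, mol: Molecule, step: float = 1e-6, tol: float = 1e-8) -> None:
        """Check the analytic gradient against central finite differences."""
        base = self.evaluate(mol)
        coords = mol.coordinates
        fd = np.zeros_like(coords)
        for i in range(mol.natoms):
            for c in range(3):
                plus = mol.copy(copy_properties=False)
                xyz = coords.copy()
                xyz[i, c] += step
                plus.coordinates = xyz
                minus = mol.copy(copy_properties=False)
                xyz = coords.copy()
                xyz[i, c] -= step
                minus.coordinates = xyz
                fd[i, c] = (
                    self.evaluate(plus, gradients=False)["energy"]
                    - self.evaluate(minus, gradients=False)["energy"]
                ) / (2 * step)
        err = np.max(np.abs(fd - base["energy_gradients"]))
        if err > tol:
            raise AssertionError(f"analytic/FD gradient mismatch: {err:g}")


def make_diatomic(
    r: float,
    elements: tuple[str, str] = ("H", "H"),
    masses: tuple[float, float] | None = None,
    axis: int = 0,
) -> Molecule:
    """Two atoms separated by ``r`` along a coordinate axis (atom 0 at origin)."""
    xyz2 = np.zeros(3)
    xyz2[axis] = r
    m0 = m1 = None
    if masses is not None:
        m0, m1 = masses
    return Molecule(
        [Atom(elements[0], np.zeros(3), mass=m0), Atom(elements[1], xyz2, mass=m1)]
    )


def generate_database(
    potential: ToyPotential,
    base_molecule: Molecule,
    n: int,
    seed: int = 0,
    mode: str = "uniform_bond",
    bond_range: tuple[float, float] = (0.7, 1.6),
    sigma_disp: float = 0.1,
    label_noise_sd: float = 0.0,
    with_gradients: bool = True,
    with_dipole: bool = False,
) -> MolecularDatabase:
    """Sample geometries around a base molecule and label them analytically.

    ``mode='uniform_bond'`` (diatomics): bond lengths uniform in
    ``bond_range``.  ``mode='normal_displacement'``: every Cartesian
    coordinate perturbed by N(0, sigma_disp).  Optional Gaussian noise of
    standard deviation ``label_noise_sd`` is added to the energy labels.
    Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    db = MolecularDatabase()
    base = base_molecule.coordinates
    for _ in range(n):
        mol = base_molecule.copy(copy_properties=False)
        if mode == "uniform_bond":
            if mol.natoms != 2:
                raise ValueError("uniform_bond sampling requires a diatomic")
            lo, hi = bond_range
            if lo <= 0:
                raise ValueError("bond_range must stay above r = 0")
            r = rng.uniform(lo, hi)
            bond = base[1] - base[0]
            xyz = base.copy()
            xyz[1] = base[0] + bond / np.linalg.norm(bond) * r
            mol.coordinates = xyz
        elif mode == "normal_displacement":
            mol.coordinates = base + rng.normal(0.0, sigma_disp, size=base.shape)
        else:
            raise ValueError(f"unknown sampling mode {mode!r}")
        out = potential.evaluate(mol, gradients=with_gradients)
        energy = out["energy"]
        if label_noise_sd > 0:
            energy += rng.normal(0.0, label_noise_sd)
        mol.set_property("energy", energy)
        if with_gradients:
            mol.set_property("energy_gradients", out["energy_gradients"])
        if with_dipole and "dipole" in out:
            mol.set_property("dipole", out["dipole"])
        db.append(mol)
    return db
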