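"""Classical molecular dynamics: velocity Verlet in NVE and NVT.

Forces are the negative energy gradients of any evaluator model
(``evaluate(mol) -> {'energy', 'energy_gradients', ...}``); non-conservative
force providers work too, as the integrator never differentiates the
energy itself.

Two unit systems:

* ``real`` — angstrom / fs / Da / hartree / kelvin.  Accelerations are
  F/m times the hartree -> Da A^2/fs^2 conversion; k_B enters in hartree/K.
* ``reduced`` — all conversion factors and k_B equal 1 (textbook units,
  e.g. a k = 1, m = 1 oscillator has unit angular frequency).

Thermostats:

* Andersen — stochastic: after each Verlet step every atom's velocity is
  redrawn from the Maxwell–Boltzmann distribution with probability
  v * dt (collision frequency v); collisions therefore follow a Poisson
  process.
* Nosé–Hoover — deterministic single-variable chain: a friction degree of
  freedom xi with mass Q = N_dof k_B T tau^2 is integrated in symmetric
  half-steps around the Verlet update.  The extended energy
  E + 1/2 Q vxi^2 + N_dof k_B T xi is conserved and is tracked on every
  step for diagnostics.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import constants as const
from .data import Molecule, MolecularDatabase

__all__ = [
    "MDConfig",
    "TrajectoryStep",
    "Trajectory",
    "initialize_velocities",
    "instantaneous_temperature",
    "propagate",
    "dump_trajectory",
    "load_trajectory",
]


@dataclass
class MDConfig:
    """Molecular-dynamics run parameters.

    dt in fs; ``ensemble`` NVE or NVT; NVT requires a thermostat and a
    positive target temperature.  ``collision_frequency`` (1/fs) drives the
    Andersen thermostat, ``coupling_time`` (fs) the Nosé–Hoover one.
    ``stride`` records every n-th step (step 0 always recorded).
    ``n_dof`` defaults to 3 N (no constraint/COM correction), matching the
    instantaneous-temperature definition T = 2 E_kin / (N_dof k_B).
    """

    dt: float = 0.1
    n_steps: int = 1000
    ensemble: str = "NVE"
    thermostat: str = "none"
    target_T: float = 300.0
    collision_frequency: float = 0.01
    coupling_time: float = 20.0
    seed: int = 0
    stride: int = 1
    units: str = "real"
    n_dof: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.ensemble not in ("NVE", "NVT"):
            raise ValueError("ensemble must be NVE or NVT")
        if self.thermostat not in ("none", "andersen", "nose_hoover"):
            raise ValueError("unknown thermostat")
        if self.ensemble == "NVT":
            if self.thermostat == "none":
                raise ValueError("NVT requires a thermostat")
            if self.target_T <= 0:
                raise ValueError("NVT requires target_T > 0")
            if self.thermostat == "andersen" and \
                    self.collision_frequency * self.dt > 1:
                raise ValueError("collision_frequency * dt must be <= 1")
        if self.units not in ("real", "reduced"):
            raise ValueError("units must be 'real' or 'reduced'")

    @property
    def kB(self) -> float:
        return const.KB_HARTREE if self.units == "real" else 1.0

    @property
    def acc_conv(self) -> float:
        """Multiplies F/m to give acceleration in length/time^2."""
        return const.HARTREE_TO_DA_A2_FS2 if self.units == "real" else 1.0


@dataclass
class TrajectoryStep:
    time: float
    coordinates: np.ndarray
    velocities: np.ndarray
    kinetic_energy: float
    potential_energy: float
    total_energy: float
    temperature: float
    dipole: np.ndarray | None = None
    extended_energy: float | None = None   # Nosé–Hoover conserved quantity


@dataclass
class Trajectory:
    steps: list[TrajectoryStep] = field(default_factory=list)
    config: MDConfig | None = None
    status: str = "completed"

    def __len__(self) -> int:
        return len(self.steps)

    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.steps])

    def temperatures(self) -> np.ndarray:
        return np.array([s.temperature for s in self.steps])

    def total_energies(self) -> np.ndarray:
        return np.array([s.total_energy for s in self.steps])

    def extended_energies(self) -> np.ndarray:
        return np.array([s.extended_energy for s in self.steps])

    def velocities_array(self) -> np.ndarray:
        return np.array([s.velocities for s in self.steps])

    def coordinates_array(self) -> np.ndarray:
        return np.array([s.coordinates for s in self.steps])

    def dipoles_array(self) -> np.ndarray:
        if any(s.dipole is None for s in self.steps):
            raise ValueError("trajectory has no dipoles")
        return np.array([s.dipole for s in self.steps])

    @property
    def dt(self) -> float:
        return self.config.dt * self.config.stride if self.config else (
            self.steps[1].time - self.steps[0].time
        )


def instantaneous_temperature(
    masses: np.ndarray,
    velocities: np.ndarray,
    n_dof: int,
    units: str = "real",
) -> float:
    """T = sum(m v^2) / (N_dof k_B) from instantaneous velocities."""
    if n_dof < 1:
        raise ValueError("n_dof must be >= 1")
    masses = np.asarray(masses, dtype=float)
    v = np.asarray(velocities, dtype=float).reshape(len(masses), -1)
    mv2 = float(np.sum(masses[:, None] * v**2))
    if units == "real":
        mv2 *= const.DA_A2_FS2_TO_HARTREE
        kB = const.KB_HARTREE
    else:
        kB = 1.0
    return mv2 / (n_dof * kB)


def initialize_velocities(
    mol: Molecule,
    T: float,
    seed: int = 0,
    remove_com: bool = True,
    units: str = "real",
) -> np.ndarray:
    """Maxwell–Boltzmann velocities at temperature T (deterministic by seed).

    Each component is N(0, k_B T / m_i); optionally the center-of-mass
    momentum is removed.  Returns (and attaches) an natoms x 3 array.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    masses = mol.masses
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    rng = np.random.default_rng(seed)
    if T == 0:
        v = np.zeros((mol.natoms, 3))
    else:
        kB = const.KB_HARTREE if units == "real" else 1.0
        conv = const.HARTREE_TO_DA_A2_FS2 if units == "real" else 1.0
        sd = np.sqrt(kB * T / masses * conv)
        v = rng.normal(0.0, 1.0, size=(mol.natoms, 3)) * sd[:, None]
    if remove_com:
        p = (masses[:, None] * v).sum(0)
        v -= p / masses.sum()
    mol.velocities = v
    return v


def _maxwell_row(rng, mass, kB, T, conv) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(kB * T / mass * conv), size=3)


def propagate(model, mol0: Molecule, config: MDConfig) -> Trajectory:
    """Velocity-Verlet propagation of a molecule under a force model.

    Initial velocities are taken from ``mol0`` (zero if absent).  A force
    evaluation failure mid-run truncates the trajectory and sets
    ``status``.  Steps are recorded every ``config.stride`` steps.
    """
    cfg = config
    work = mol0.copy(copy_properties=False)
    masses = work.masses
    n = work.natoms
    n_dof = cfg.n_dof if cfg.n_dof is not None else 3 * n
    kB, conv = cfg.kB, cfg.acc_conv
    ke_conv = 1.0 / conv  # m v^2 (mass length^2/time^2) -> energy units

    x = mol0.coordinates
    v = mol0.velocities
    v = np.zeros((n, 3)) if v is None else v.copy()
    rng = np.random.default_rng(cfg.seed)

    andersen = cfg.ensemble == "NVT" and cfg.thermostat == "andersen"
    nose = cfg.ensemble == "NVT" and cfg.thermostat == "nose_hoover"
    if nose:
        Q = n_dof * kB * cfg.target_T * cfg.coupling_time**2
        xi, vxi = 0.0, 0.0

    def forces_at(xyz):
        work.coordinates = xyz
        out = model.evaluate(work, gradients=True)
        dip = out.get("dipole")
        return float(out["energy"]), -np.asarray(out["energy_gradients"]), dip

    def kinetic(vel):
        return 0.5 * float(np.sum(masses[:, None] * vel**2)) * ke_conv

    def nh_half(vel, dt_half):
        nonlocal xi, vxi
        ke2 = 2.0 * kinetic(vel)
        G = (ke2 - n_dof * kB * cfg.target_T) / Q
        vxi += 0.5 * dt_half * G
        scale = math.exp(-vxi * dt_half)
        vel *= scale
        xi += vxi * dt_half
        ke2 *= scale * scale
        G = (ke2 - n_dof * kB * cfg.target_T) / Q
        vxi += 0.5 * dt_half * G
        return vel

    traj = Trajectory(config=cfg)

    def record(step_index, epot, vel, dip):
        ke = kinetic(vel)
        ext = None
        if nose:
            ext = epot + ke + 0.5 * Q * vxi**2 + n_dof * kB * cfg.target_T * xi
        traj.steps.append(
            TrajectoryStep(
                time=step_index * cfg.dt,
                coordinates=x.copy(),
                velocities=vel.copy(),
                kinetic_energy=ke,
                potential_energy=epot,
                total_energy=epot + ke,
                temperature=2 * ke / (n_dof * kB),
                dipole=None if dip is None else np.asarray(dip, dtype=float),
                extended_energy=ext,
            )
        )

    try:
        epot, F, dip = forces_at(x)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"force evaluation failed at the start: {exc}") from exc
    record(0, epot, v, dip)
    a = F / masses[:, None] * conv

    for step in range(1, cfg.n_steps + 1):
        if nose:
            v = nh_half(v, 0.5 * cfg.dt)
        v_half = v + 0.5 * cfg.dt * a
        x = x + cfg.dt * v_half
        try:
            epot, F, dip = forces_at(x)
        except Exception as exc:  # noqa: BLE001
            traj.status = f"truncated at step {step}: {exc}"
            warnings.warn(traj.status)
            return traj
        a = F / masses[:, None] * conv
        v = v_half + 0.5 * cfg.dt * a
        if nose:
            v = nh_half(v, 0.5 * cfg.dt)
        if andersen:
            p_coll = cfg.collision_frequency * cfg.dt
            hits = rng.random(n) < p_coll
            for i in np.nonzero(hits)[0]:
                v[i] = _maxwell_row(rng, masses[i], kB, cfg.target_T, conv)
        if step % cfg.stride == 0:
            record(step, epot, v, dip)
    return traj


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def dump_trajectory(traj: Trajectory, path, fmt: str = "json",
                    elements: list[str] | None = None) -> None:
    """Write a trajectory as ``json`` (lossless), ``plain_text`` (tabular
    time/energies/temperature), or ``multi_xyz`` (frames only; needs
    ``elements``)."""
    if not traj.steps:
        raise ValueError("empty trajectory")
    path = Path(path)
    if fmt == "json":
        payload = {
            "status": traj.status,
            "steps": [
                {
                    "time": s.time,
                    "coordinates": s.coordinates.tolist(),
                    "velocities": s.velocities.tolist(),
                    "kinetic_energy": s.kinetic_energy,
                    "potential_energy": s.potential_energy,
                    "total_energy": s.total_energy,
                    "temperature": s.temperature,
                    "dipole": None if s.dipole is None else s.dipole.tolist(),
                    "extended_energy": s.extended_energy,
                }
                for s in traj.steps
            ],
        }
        path.write_text(json.dumps(payload))
    elif fmt == "plain_text":
        lines = ["# time  E_kin  E_pot  E_tot  T"]
        for s in traj.steps:
            lines.append(
                f"{s.time:14.6f} {s.kinetic_energy:18.10e} "
                f"{s.potential_energy:18.10e} {s.total_energy:18.10e} "
                f"{s.temperature:12.4f}"
            )
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "multi_xyz":
        if elements is None:
            raise ValueError("multi_xyz needs the element list")
        from .data import Atom, write_xyz

        db = MolecularDatabase()
        for s in traj.steps:
            atoms = [Atom(el, xyz) for el, xyz in zip(elements, s.coordinates)]
            db.append(Molecule(atoms, comment=f"t = {s.time} fs"))
        write_xyz(db, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_trajectory(path) -> Trajectory:
    """Read back a JSON trajectory written by :func:`dump_trajectory`."""
    payload = json.loads(Path(path).read_text())
    traj = Trajectory(status=payload.get("status", "completed"))
    for s in payload["steps"]:
        traj.steps.append(
            TrajectoryStep(
                time=s["time"],
                coordinates=np.asarray(s["coordinates"], dtype=float),
                velocities=np.asarray(s["velocities"], dtype=float),
                kinetic_energy=s["kinetic_energy"],
                potential_energy=s["potential_energy"],
                total_energy=s["total_energy"],
                temperature=s["temperature"],
                dipole=None if s["dipole"] is None
                else np.asarray(s["dipole"], dtype=float),
                extended_energy=s.get("extended_energy"),
            )
        )
    return traj
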