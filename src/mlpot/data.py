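"""Core chemistry containers, file I/O, dataset splitting, error statistics.

The three containers mirror what an atomistic ML workflow needs: an
``Atom`` (element, mass, Cartesian position, optional velocity), a
``Molecule`` (ordered atoms + charge/multiplicity + attached properties such
as energy, gradients, Hessian, dipole), and a ``MolecularDatabase`` (an
ordered list of molecules with per-molecule split tags for
subtraining/validation/test bookkeeping).

Units follow the package convention: coordinates in angstrom, energies in
hartree, gradients in hartree/angstrom, dipoles in e*angstrom, velocities in
angstrom/fs, masses in Da.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .elements import atomic_mass, normalize_symbol, nuclear_charge

__all__ = [
    "Atom",
    "Molecule",
    "MolecularDatabase",
    "StatsReport",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "dump_database",
    "load_database",
    "split_database",
    "farthest_point_indices",
    "error_statistics",
]

SPLIT_TAGS = ("subtraining", "validation", "test", "none")


class XYZParseError(ValueError):
    """Raised for malformed XYZ input; the message names the offending line."""


@dataclass
class Atom:
    """One atom: element, nuclear charge, mass (Da), position (A)."""

    element: str
    coordinates: np.ndarray
    mass: float | None = None
    velocity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.element = normalize_symbol(self.element)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,):
            raise ValueError("coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.mass is None:
            self.mass = atomic_mass(self.element)
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.velocity is not None:
            self.velocity = np.asarray(self.velocity, dtype=float)
            if self.velocity.shape != (3,):
                raise ValueError("velocity must be a 3-vector")

    @property
    def nuclear_charge(self) -> int:
        return nuclear_charge(self.element)

    def copy(self) -> "Atom":
        return Atom(
            self.element,
            self.coordinates.copy(),
            mass=self.mass,
            velocity=None if self.velocity is None else self.velocity.copy(),
        )


class Molecule:
    """An ordered collection of atoms with charge, multiplicity, properties.

    ``properties`` holds optional labels attached to the geometry:
    ``energy`` (hartree), ``energy_gradients`` (natoms x 3, hartree/A),
    ``hessian`` (3N x 3N, hartree/A^2, symmetric), ``dipole`` (3-vector, e*A).
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        charge: int = 0,
        multiplicity: int = 1,
        properties: dict | None = None,
        comment: str = "",
    ) -> None:
        atoms = list(atoms)
        if len(atoms) < 1:
            raise ValueError("a molecule needs at least one atom")
        if multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")
        self.atoms = atoms
        self.charge = int(charge)
        self.multiplicity = int(multiplicity)
        self.comment = comment
        self.properties: dict = {}
        for key, value in (properties or {}).items():
            self.set_property(key, value)

    # -- structural accessors ------------------------------------------------
    @property
    def natoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def nuclear_charges(self) -> np.ndarray:
        return np.array([a.nuclear_charge for a in self.atoms])

    @property
    def coordinates(self) -> np.ndarray:
        """natoms x 3 array of positions in angstrom (a copy)."""
        return np.array([a.coordinates for a in self.atoms])

    @coordinates.setter
    def coordinates(self, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float).reshape(self.natoms, 3)
        for atom, xyz in zip(self.atoms, value):
            atom.coordinates = xyz.copy()

    @property
    def velocities(self) -> np.ndarray | None:
        if any(a.velocity is None for a in self.atoms):
            return None
        return np.array([a.velocity for a in self.atoms])

    @velocities.setter
    def velocities(self, value: np.ndarray) -> None:
        value = np.asarray(value, dtype=float).reshape(self.natoms, 3)
        for atom, v in zip(self.atoms, value):
            atom.velocity = v.copy()

    def composition(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for el in self.elements:
            counts[el] = counts.get(el, 0) + 1
        return counts

    # -- properties ----------------------------------------------------------
    def set_property(self, key: str, value) -> None:
        if key == "energy":
            value = float(value)
        elif key == "energy_gradients":
            value = np.asarray(value, dtype=float)
            if value.shape != (self.natoms, 3):
                raise ValueError(
                    f"energy_gradients must have shape ({self.natoms}, 3), "
                    f"got {value.shape}"
                )
        elif key == "hessian":
            value = np.asarray(value, dtype=float)
            n3 = 3 * self.natoms
            if value.shape != (n3, n3):
                raise ValueError(f"hessian must have shape ({n3}, {n3})")
            if not np.allclose(value, value.T, atol=1e-8):
                raise ValueError("hessian must be symmetric within 1e-8")
        elif key == "dipole":
            value = np.asarray(value, dtype=float).reshape(3)
        self.properties[key] = value

    @property
    def energy(self) -> float | None:
        return self.properties.get("energy")

    @property
    def energy_gradients(self) -> np.ndarray | None:
        return self.properties.get("energy_gradients")

    def copy(self, copy_properties: bool = True) -> "Molecule":
        props = None
        if copy_properties:
            props = {
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self.properties.items()
            }
        return Molecule(
            [a.copy() for a in self.atoms],
            charge=self.charge,
            multiplicity=self.multiplicity,
            properties=props,
            comment=self.comment,
        )

    def __repr__(self) -> str:
        return f"Molecule({''.join(self.elements)}, charge={self.charge})"


class MolecularDatabase:
    """Ordered list of molecules with optional split tags.

    A database is *homogeneous* when every molecule shares the same atom
    count and element sequence — the precondition for global descriptors.
    Heterogeneous databases are allowed but rejected by descriptor-based
    models.
    """

    def __init__(self, molecules: Iterable[Molecule] = ()) -> None:
        self.molecules: list[Molecule] = list(molecules)
        self.split_labels: list[str] = ["none"] * len(self.molecules)

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.molecules)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            sub = MolecularDatabase(self.molecules[idx])
            sub.split_labels = self.split_labels[idx]
            return sub
        return self.molecules[idx]

    def append(self, mol: Molecule) -> None:
        self.molecules.append(mol)
        self.split_labels.append("none")

    @property
    def is_homogeneous(self) -> bool:
        if not self.molecules:
            return True
        ref = self.molecules[0].elements
        return all(m.elements == ref for m in self.molecules)

    def energies(self) -> np.ndarray:
        return np.array([m.properties["energy"] for m in self.molecules])

    def gradients(self) -> np.ndarray:
        return np.array(
            [m.properties["energy_gradients"] for m in self.molecules]
        )

    def coordinates(self) -> np.ndarray:
        return np.array([m.coordinates for m in self.molecules])

    def set_split(self, indices: Sequence[int], tag: str) -> None:
        if tag not in SPLIT_TAGS:
            raise ValueError(f"unknown split tag {tag!r}; use one of {SPLIT_TAGS}")
        for i in indices:
            self.split_labels[i] = tag

    def subset(self, tag: str) -> "MolecularDatabase":
        idx = [i for i, t in enumerate(self.split_labels) if t == tag]
        return self.take(idx)

    def take(self, indices: Sequence[int]) -> "MolecularDatabase":
        sub = MolecularDatabase([self.molecules[i] for i in indices])
        sub.split_labels = [self.split_labels[i] for i in indices]
        return sub

    def copy(self) -> "MolecularDatabase":
        out = MolecularDatabase([m.copy() for m in self.molecules])
        out.split_labels = list(self.split_labels)
        return out


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def _as_text(text_or_path) -> str:
    if isinstance(text_or_path, Path):
        return text_or_path.read_text()
    text = str(text_or_path)
    # Heuristic: a single short line without newline that exists on disk is a path
    if "\n" not in text and len(text) < 4096:
        p = Path(text)
        if p.exists():
            return p.read_text()
    return text


def read_xyz(text_or_path, multi_frame: bool = True) -> MolecularDatabase:
    """Parse standard (multi-frame) XYZ into a molecular database.

    Each frame: atom-count line, comment line, then ``element x y z`` rows.
    Frames are simply concatenated.  Element symbols resolve
    case-insensitively; coordinates are read as angstrom.
    """
    text = _as_text(text_or_path)
    lines = text.splitlines()
    db = MolecularDatabase()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if natoms < 1:
            raise XYZParseError(f"line {i + 1}: atom count must be >= 1")
        if len(lines) < i + 2 + natoms:
            raise XYZParseError(
                f"line {i + 1}: frame declares {natoms} atoms but file ends early"
            )
        comment = lines[i + 1]
        atoms = []
        for j in range(natoms):
            ln = i + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"line {ln + 1}: expected 'element x y z', got {lines[ln]!r}"
                )
            try:
                sym = normalize_symbol(parts[0])
            except ValueError:
                raise XYZParseError(
                    f"line {ln + 1}: unknown element {parts[0]!r}"
                ) from None
            try:
                xyz = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise XYZParseError(
                    f"line {ln + 1}: malformed coordinates in {lines[ln]!r}"
                ) from None
            atoms.append(Atom(sym, xyz))
        db.append(Molecule(atoms, comment=comment))
        i += 2 + natoms
        if not multi_frame:
            break
    if len(db) == 0:
        raise XYZParseError("no frames found in XYZ input")
    return db


def write_xyz(db_or_mol, path=None) -> str:
    """Serialize molecules as multi-frame XYZ (fixed-width, 12 decimals).

    Returns the text; also writes it to ``path`` when given.  Inverse of
    :func:`read_xyz` up to float formatting (round trips to < 1e-10 A).
    """
    if isinstance(db_or_mol, Molecule):
        mols = [db_or_mol]
    else:
        mols = list(db_or_mol)
        if not mols:
            raise ValueError("cannot write an empty database")
    chunks = []
    for mol in mols:
        chunks.append(str(mol.natoms))
        chunks.append(mol.comment)
        for atom in mol.atoms:
            x, y, z = atom.coordinates
            chunks.append(f"{atom.element:<3s} {x:18.12f} {y:18.12f} {z:18.12f}")
    text = "\n".join(chunks) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Database dump / load (json, npz, plain text trio)
# ---------------------------------------------------------------------------

def _mol_to_record(mol: Molecule) -> dict:
    rec = {
        "atoms": [
            {"element": a.element, "xyz": a.coordinates.tolist(), "mass": a.mass}
            for a in mol.atoms
        ],
        "charge": mol.charge,
        "multiplicity": mol.multiplicity,
        "comment": mol.comment,
        "properties": {},
    }
    for k, v in mol.properties.items():
        rec["properties"][k] = v.tolist() if isinstance(v, np.ndarray) else v
    return rec


def _mol_from_record(rec: dict) -> Molecule:
    atoms = [
        Atom(a["element"], a["xyz"], mass=a.get("mass"))
        for a in rec["atoms"]
    ]
    return Molecule(
        atoms,
        charge=rec.get("charge", 0),
        multiplicity=rec.get("multiplicity", 1),
        properties=rec.get("properties", {}),
        comment=rec.get("comment", ""),
    )


def dump_database(db: MolecularDatabase, path, fmt: str = "json") -> None:
    """Write a database to disk as ``json``, ``npz`` or ``plain_text``.

    ``plain_text`` writes the trio ``<path>.xyz`` (geometries), ``<path>.y``
    (one energy per line) and, when gradients are present, ``<path>.ygrad``
    (XYZ-style derivative blocks).
    """
    path = Path(path)
    if fmt == "json":
        payload = {
            "molecules": [_mol_to_record(m) for m in db],
            "split_labels": db.split_labels,
        }
        path.write_text(json.dumps(payload))
    elif fmt == "npz":
        arrays: dict[str, np.ndarray] = {}
        arrays["n_molecules"] = np.array(len(db))
        for i, mol in enumerate(db):
            arrays[f"elements_{i}"] = np.array(mol.elements)
            arrays[f"xyz_{i}"] = mol.coordinates
            arrays[f"charge_mult_{i}"] = np.array([mol.charge, mol.multiplicity])
            for k, v in mol.properties.items():
                arrays[f"prop_{k}_{i}"] = np.asarray(v)
        arrays["split_labels"] = np.array(db.split_labels)
        np.savez(path, **arrays)
    elif fmt == "plain_text":
        write_xyz(db, path.with_suffix(".xyz"))
        if any("energy" in m.properties for m in db):
            lines = [f"{m.properties['energy']:.12f}" for m in db]
            path.with_suffix(".y").write_text("\n".join(lines) + "\n")
        if all("energy_gradients" in m.properties for m in db):
            chunks = []
            for mol in db:
                chunks.append(str(mol.natoms))
                chunks.append("")
                for g in mol.properties["energy_gradients"]:
                    chunks.append(f"{g[0]:18.12f} {g[1]:18.12f} {g[2]:18.12f}")
            path.with_suffix(".ygrad").write_text("\n".join(chunks) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_database(path, fmt: str = "json") -> MolecularDatabase:
    """Load a database previously written by :func:`dump_database`."""
    path = Path(path)
    if fmt == "json":
        payload = json.loads(path.read_text())
        db = MolecularDatabase([_mol_from_record(r) for r in payload["molecules"]])
        db.split_labels = list(payload.get("split_labels", db.split_labels))
        return db
    if fmt == "npz":
        with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path,
                     allow_pickle=False) as data:
            n = int(data["n_molecules"])
            db = MolecularDatabase()
            for i in range(n):
                elements = [str(e) for e in data[f"elements_{i}"]]
                xyz = data[f"xyz_{i}"]
                charge, mult = (int(v) for v in data[f"charge_mult_{i}"])
                props = {}
                prefix = "prop_"
                suffix = f"_{i}"
                for key in data.files:
                    if key.startswith(prefix) and key.endswith(suffix):
                        name = key[len(prefix):-len(suffix)]
                        val = data[key]
                        props[name] = float(val) if val.ndim == 0 else val
                atoms = [Atom(e, c) for e, c in zip(elements, xyz)]
                db.append(Molecule(atoms, charge=charge, multiplicity=mult,
                                   properties=props))
            db.split_labels = [str(s) for s in data["split_labels"]]
        return db
    if fmt == "plain_text":
        db = read_xyz(path.with_suffix(".xyz"))
        yfile = path.with_suffix(".y")
        if yfile.exists():
            energies = [float(s) for s in yfile.read_text().split()]
            if len(energies) != len(db):
                raise ValueError(
                    f"label file has {len(energies)} energies for "
                    f"{len(db)} geometries"
                )
            for mol, e in zip(db, energies):
                mol.set_property("energy", e)
        gfile = path.with_suffix(".ygrad")
        if gfile.exists():
            lines = gfile.read_text().splitlines()
            i = 0
            for mol in db:
                natoms = int(lines[i].strip())
                if natoms != mol.natoms:
                    raise ValueError(
                        "gradient file atom count does not match geometry"
                    )
                block = lines[i + 2: i + 2 + natoms]
                grads = np.array([[float(v) for v in ln.split()] for ln in block])
                mol.set_property("energy_gradients", grads)
                i += 2 + natoms
        return db
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Splitting and sampling
# ---------------------------------------------------------------------------

def farthest_point_indices(X: np.ndarray, n_select: int) -> list[int]:
    """Greedy max–min (farthest-point) selection on descriptor rows.

    Starts from the point farthest from the centroid (the most extreme
    point, maximizing initial spread); each subsequent pick maximizes the
    minimal Euclidean distance to the already-selected set.  Ties break
    toward the lowest index, so the result is deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N = X.shape[0]
    if not 1 <= n_select <= N:
        raise ValueError(f"cannot select {n_select} of {N} points")
    centroid = X.mean(axis=0)
    d0 = np.linalg.norm(X - centroid, axis=1)
    selected = [int(np.argmax(d0))]
    min_dist = np.linalg.norm(X - X[selected[0]], axis=1)
    while len(selected) < n_select:
        pick = int(np.argmax(min_dist))
        selected.append(pick)
        min_dist = np.minimum(min_dist, np.linalg.norm(X - X[pick], axis=1))
    return selected


def _default_split_descriptors(db: MolecularDatabase) -> np.ndarray:
    from .descriptors import DescriptorSpec, descriptor

    if db.is_homogeneous and db.molecules[0].natoms >= 2:
        spec = DescriptorSpec("inverse_distance")
        return np.array([descriptor(m, spec) for m in db])
    return np.array([m.coordinates.ravel() for m in db])


def split_database(
    db: MolecularDatabase,
    fractions: Sequence[float],
    method: str = "random",
    seed: int | None = 0,
    labels: Sequence[str] | None = None,
    descriptors: np.ndarray | None = None,
) -> MolecularDatabase:
    """Tag molecules with disjoint split labels.

    ``fractions`` are positive and sum to <= 1; subset sizes are
    ``round(fraction * N)``.  ``method='random'`` permutes with the given
    seed; ``method='farthest_point'`` fills the first subset by greedy
    max–min selection on descriptor rows (remaining subsets are filled in
    index order from the unselected pool).  Returns the same database with
    ``split_labels`` set.
    """
    N = len(db)
    fractions = list(fractions)
    if any(f <= 0 for f in fractions) or sum(fractions) > 1 + 1e-9:
        raise ValueError("fractions must be positive and sum to <= 1")
    sizes = [int(round(f * N)) for f in fractions]
    if any(s == 0 for s in sizes):
        raise ValueError("a requested fraction implies an empty subset")
    while sum(sizes) > N:
        sizes[-1] -= 1
    if labels is None:
        if len(fractions) == 1:
            labels = ["subtraining"]
        elif len(fractions) == 2:
            labels = ["subtraining", "validation"]
        elif len(fractions) == 3:
            labels = ["subtraining", "validation", "test"]
        else:
            raise ValueError("provide explicit labels for > 3 subsets")
    if len(labels) != len(fractions):
        raise ValueError("labels and fractions must have equal length")

    if method == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(N)
    elif method == "farthest_point":
        X = descriptors if descriptors is not None else _default_split_descriptors(db)
        first = farthest_point_indices(np.atleast_2d(X), sizes[0])
        rest = [i for i in range(N) if i not in set(first)]
        order = np.array(first + rest)
    else:
        raise ValueError(f"unknown split method {method!r}")

    db.split_labels = ["none"] * N
    start = 0
    for size, tag in zip(sizes, labels):
        db.set_split(order[start:start + size].tolist(), tag)
        start += size
    return db


# ---------------------------------------------------------------------------
# Error statistics
# ---------------------------------------------------------------------------

@dataclass
class StatsReport:
    """Error measures of a predicted vector against a reference vector."""

    rmse: float
    mae: float
    mean_signed_error: float
    pearson_r: float
    r_squared: float
    largest_outliers: list[tuple[int, float]] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [
            f"RMSE               {self.rmse: .8e}",
            f"MAE                {self.mae: .8e}",
            f"mean signed error  {self.mean_signed_error: .8e}",
            f"Pearson r          {self.pearson_r: .8f}",
            f"R^2                {self.r_squared: .8f}",
        ]
        if self.largest_outliers:
            lines.append("largest outliers (index, residual):")
            for i, r in self.largest_outliers:
                lines.append(f"    {i:6d}  {r: .6e}")
        return "\n".join(lines)


def error_statistics(
    estimated: np.ndarray, reference: np.ndarray, n_outliers: int = 3
) -> StatsReport:
    """RMSE, MAE, mean signed error, Pearson r and r^2 of estimated vs reference.

    Residuals are ``estimated - reference``.  With a constant reference the
    correlation is undefined and reported as NaN with a warning.
    """
    e = np.asarray(estimated, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if e.shape != r.shape:
        raise ValueError("estimated and reference must have equal length")
    resid = e - r
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    mse = float(np.mean(resid))
    if e.size >= 2 and np.std(r) > 0 and np.std(e) > 0:
        pearson = float(np.corrcoef(e, r)[0, 1])
        r2 = pearson**2
    else:
        warnings.warn("correlation undefined (constant vector); reporting NaN")
        pearson = float("nan")
        r2 = float("nan")
    order = np.argsort(-np.abs(resid))[:n_outliers]
    outliers = [(int(i), float(resid[i])) for i in order]
    return StatsReport(rmse, mae, mse, pearson, r2, outliers)
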