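"""Global molecular descriptors and their Cartesian Jacobians.

Three descriptor families map a geometry to a fixed-length vector:

* ``inverse_distance`` — 1/r_ij over all atom pairs (i < j), in 1/angstrom;
* ``RE`` — the same pairs normalized by an equilibrium reference,
  r_eq,ij / r_ij (dimensionless; > 1 for a compressed pair);
* ``coulomb_matrix`` — M_ii = 0.5 Z_i^2.4, M_ij = Z_i Z_j / r_ij with r in
  bohr (the convention of the original descriptor literature), flattened as
  the upper triangle including the diagonal, optionally sorted by descending
  row norm for permutational invariance, optionally zero-padded to a fixed
  system size.

The Jacobians (descriptor dimension x 3N) are analytic and make any
energy-predicting kernel model differentiable with respect to Cartesian
coordinates via the chain rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import BOHR_TO_ANGSTROM
from .data import Molecule

__all__ = ["DescriptorSpec", "descriptor", "descriptor_jacobian"]

KINDS = ("inverse_distance", "RE", "coulomb_matrix")


@dataclass
class DescriptorSpec:
    """Descriptor family plus its options.

    ``reference_geometry`` is required for kind ``RE`` and must have the
    same element sequence as the molecules it will be applied to.
    ``cm_size`` pads the Coulomb matrix to a fixed atom count (>= natoms);
    ``cm_sorted`` sorts rows/columns by descending row norm.
    """

    kind: str = "RE"
    reference_geometry: Molecule | None = None
    cm_size: int | None = None
    cm_sorted: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        if self.kind == "RE" and self.reference_geometry is None:
            raise ValueError("RE descriptor requires a reference geometry")


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    ii, jj = _pair_indices(coords.shape[0])
    d = coords[ii] - coords[jj]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("coincident atoms: singular geometry")
    return r


def _check_re_reference(mol: Molecule, spec: DescriptorSpec) -> np.ndarray:
    ref = spec.reference_geometry
    if ref.elements != mol.elements:
        raise ValueError(
            "RE reference geometry has a different element sequence"
        )
    return _pair_distances(ref.coordinates)


def descriptor(mol: Molecule, spec: DescriptorSpec) -> np.ndarray:
    """Map a molecule to its descriptor vector."""
    coords = mol.coordinates
    n = mol.natoms
    if spec.kind in ("inverse_distance", "RE"):
        if n < 2:
            raise ValueError("pairwise descriptors need at least 2 atoms")
        r = _pair_distances(coords)
        if spec.kind == "inverse_distance":
            return 1.0 / r
        r_eq = _check_re_reference(mol, spec)
        return r_eq / r

    # Coulomb matrix
    size = spec.cm_size if spec.cm_size is not None else n
    if size < n:
        raise ValueError("cm_size must be >= natoms")
    Z = mol.nuclear_charges.astype(float)
    M = np.zeros((size, size))
    M[np.arange(n), np.arange(n)] = 0.5 * Z**2.4
    if n >= 2:
        ii, jj = _pair_indices(n)
        r_bohr = _pair_distances(coords) / BOHR_TO_ANGSTROM
        M[ii, jj] = M[jj, ii] = Z[ii] * Z[jj] / r_bohr
    if spec.cm_sorted:
        order = _cm_sort_order(M, n)
        perm = np.concatenate([order, np.arange(n, size)])
        M = M[np.ix_(perm, perm)]
    return M[np.triu_indices(size)]


def _cm_sort_order(M: np.ndarray, n: int) -> np.ndarray:
    norms = np.linalg.norm(M[:n, :n], axis=1)
    # stable sort by descending norm; ties keep original atom order
    return np.argsort(-norms, kind="stable")


def descriptor_jacobian(mol: Molecule, spec: DescriptorSpec) -> np.ndarray:
    """Analytic Jacobian d(descriptor)/d(Cartesians), shape D x 3N.

    For the sorted Coulomb matrix the Jacobian is taken at the fixed sorted
    order (piecewise definition across sorting discontinuities).
    """
    coords = mol.coordinates
    n = mol.natoms
    if spec.kind in ("inverse_distance", "RE"):
        if n < 2:
            raise ValueError("pairwise descriptors need at least 2 atoms")
        ii, jj = _pair_indices(n)
        diff = coords[ii] - coords[jj]
        r = np.linalg.norm(diff, axis=1)
        if np.any(r < 1e-12):
            raise ValueError("coincident atoms: singular geometry")
        # d(1/r)/dR_i = -(R_i - R_j)/r^3 ; opposite sign for atom j
        J = np.zeros((len(r), 3 * n))
        grad_i = -diff / r[:, None] ** 3
        for p, (a, b) in enumerate(zip(ii, jj)):
            J[p, 3 * a: 3 * a + 3] = grad_i[p]
            J[p, 3 * b: 3 * b + 3] = -grad_i[p]
        if spec.kind == "RE":
            r_eq = _check_re_reference(mol, spec)
            J *= r_eq[:, None]
        return J

    # Coulomb matrix: diagonal rows are constant, off-diagonal rows follow 1/r
    size = spec.cm_size if spec.cm_size is not None else n
    if size < n:
        raise ValueError("cm_size must be >= natoms")
    Z = mol.nuclear_charges.astype(float)
    if spec.cm_sorted:
        M = np.zeros((n, n))
        M[np.arange(n), np.arange(n)] = 0.5 * Z**2.4
        if n >= 2:
            ii, jj = _pair_indices(n)
            r_bohr = _pair_distances(coords) / BOHR_TO_ANGSTROM
            M[ii, jj] = M[jj, ii] = Z[ii] * Z[jj] / r_bohr
        order = _cm_sort_order(M, n)
    else:
        order = np.arange(n)
    pos = {int(a): p for p, a in enumerate(order)}  # atom -> row in sorted M

    D = size * (size + 1) // 2
    J = np.zeros((D, 3 * n))
    if n < 2:
        return J
    row_of = {}
    idx = 0
    for a in range(size):
        for b in range(a, size):
            row_of[(a, b)] = idx
            idx += 1
    ii, jj = _pair_indices(n)
    diff = coords[ii] - coords[jj]
    r_ang = np.linalg.norm(diff, axis=1)
    if np.any(r_ang < 1e-12):
        raise ValueError("coincident atoms: singular geometry")
    for p, (a, b) in enumerate(zip(ii, jj)):
        pa, pb = pos[int(a)], pos[int(b)]
        row = row_of[(min(pa, pb), max(pa, pb))]
        # M_ab = Za Zb / (r/bohr);  dM/dR_a = -Za Zb * bohr * (R_a-R_b)/r^3
        g = -Z[a] * Z[b] * BOHR_TO_ANGSTROM * diff[p] / r_ang[p] ** 3
        J[row, 3 * a: 3 * a + 3] = g
        J[row, 3 * b: 3 * b + 3] = -g
    return J
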