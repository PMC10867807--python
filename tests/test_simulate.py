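"""Single points, numerical derivatives, optimization, frequencies, thermo."""

import math

import numpy as np
import pytest

from mlpot import constants as const
from mlpot.data import Atom, Molecule, MolecularDatabase
from mlpot.simulate import (
    ANI1CCX_REFERENCE,
    AtomicReferenceTable,
    harmonic_frequencies,
    heat_of_formation,
    numerical_gradient,
    numerical_hessian,
    optimize_geometry,
    single_point_batch,
    thermochemistry,
)
from mlpot.toys import ToyPotential, generate_database, make_diatomic


class EnergyOnly:
    """Wraps a toy potential, exposing energies but never gradients."""

    def __init__(self, pot):
        self.pot = pot

    def evaluate(self, mol, gradients=False):
        return {"energy": self.pot.evaluate(mol, gradients=False)["energy"]}


class TestSinglePointBatch:
    def test_attaches_energies(self, harmonic, diatomic):
        db = generate_database(harmonic, diatomic, 10, seed=0,
                               with_gradients=False)
        for m in db:
            m.properties.clear()
        failures = single_point_batch(harmonic, db, ("energy",))
        assert failures == []
        assert all("energy" in m.properties for m in db)

    def test_fd_fallback_for_gradients(self, harmonic, diatomic):
        db = MolecularDatabase([make_diatomic(1.1)])
        single_point_batch(EnergyOnly(harmonic), db,
                           ("energy", "energy_gradients"))
        exact = harmonic.evaluate(db[0])["energy_gradients"]
        np.testing.assert_allclose(
            db[0].properties["energy_gradients"], exact, atol=1e-8
        )

    def test_partial_failure_recorded_batch_continues(self, morse):
        db = MolecularDatabase([
            make_diatomic(1.0),
            Molecule([Atom("H", [0, 0, 0]), Atom("H", [0, 0, 0])]),  # r = 0
            make_diatomic(1.2),
        ])
        failures = single_point_batch(morse, db, ("energy",))
        assert [i for i, _ in failures] == [1]
        assert "energy" in db[0].properties and "energy" in db[2].properties

    def test_empty_database(self, morse):
        assert single_point_batch(morse, MolecularDatabase(), ("energy",)) == []


class TestNumericalDerivatives:
    def test_quadratic_gradient_exact(self, harmonic):
        mol = make_diatomic(1.3)
        fd = numerical_gradient(harmonic, mol)
        exact = harmonic.evaluate(mol)["energy_gradients"]
        np.testing.assert_allclose(fd, exact, atol=1e-9)

    def test_halving_step_reduces_error_fourfold(self):
        # quartic pair potential via double_well: FD error is O(step^2)
        pot = ToyPotential("double_well", barrier=0.05, minima=(0.8, 1.2))
        mol = make_diatomic(1.1)
        exact = pot.evaluate(mol)["energy_gradients"]
        errs = []
        for step in (2e-3, 1e-3):
            fd = numerical_gradient(pot, mol, step=step)
            errs.append(np.max(np.abs(fd - exact)))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.1)

    def test_hessian_eigenvalue_along_bond(self, harmonic):
        H = numerical_hessian(harmonic, make_diatomic(1.0))
        w = np.linalg.eigvalsh(H)
        # one stretch mode with curvature 2k (both atoms move), rest ~ 0
        assert w[-1] == pytest.approx(2 * 0.5, rel=1e-5)
        np.testing.assert_allclose(w[:-1], 0.0, atol=1e-5)

    def test_symmetry_enforced_exactly(self, morse):
        H = numerical_hessian(morse, make_diatomic(1.05))
        np.testing.assert_array_equal(H, H.T)

    def test_semianalytical_matches_fully_numerical(self, morse):
        mol = make_diatomic(1.07)
        H_semi = numerical_hessian(morse, mol, from_gradients=True)
        H_full = numerical_hessian(EnergyOnly(morse), mol, from_gradients=False)
        np.testing.assert_allclose(H_semi, H_full, atol=1e-5)

    def test_nonpositive_step_rejected(self, harmonic):
        with pytest.raises(ValueError):
            numerical_gradient(harmonic, make_diatomic(1.0), step=0.0)


class TestOptimizeGeometry:
    def test_harmonic_converges_to_r0(self, harmonic):
        res = optimize_geometry(harmonic, make_diatomic(1.2))
        r = np.linalg.norm(
            res.molecule.coordinates[1] - res.molecule.coordinates[0]
        )
        assert res.converged
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_start_at_minimum_zero_steps(self, harmonic):
        res = optimize_geometry(harmonic, make_diatomic(1.0))
        assert res.n_steps == 0 and res.converged

    def test_morse_reaches_well_depth(self, morse):
        res = optimize_geometry(
            morse, make_diatomic(0.95 * 1.3), gradient_tol=1e-7
        )
        assert res.energy == pytest.approx(-0.17, abs=1e-8)

    def test_energy_only_model_uses_fd_fallback(self, harmonic):
        res = optimize_geometry(EnergyOnly(harmonic), make_diatomic(1.15))
        assert res.converged
        r = np.linalg.norm(
            res.molecule.coordinates[1] - res.molecule.coordinates[0]
        )
        assert r == pytest.approx(1.0, abs=1e-5)

    def test_path_recorded_and_dumpable(self, harmonic, tmp_path):
        res = optimize_geometry(harmonic, make_diatomic(1.4))
        assert len(res.path) >= 2
        text = res.dump_xyz(tmp_path / "opt.xyz")
        assert text.count("\n2\n") + text.startswith("2\n") == len(res.path)


def diatomic_closed_form_wavenumber(k, mu):
    """(1/2 pi c) sqrt(k/mu) with k in hartree/A^2, mu in Da."""
    omega = math.sqrt(
        k * const.HARTREE_SI / const.ANGSTROM_SI**2 / (mu * const.DALTON_SI)
    )
    return omega / (2 * math.pi * const.SPEED_OF_LIGHT_CM)


class TestHarmonicFrequencies:
    def test_diatomic_matches_closed_form(self):
        k = 1.0
        pot = ToyPotential("harmonic_bond", k=k, r0=1.0)
        mol = make_diatomic(1.0, masses=(2.0, 2.0))  # mu = 1 Da
        analysis = harmonic_frequencies(numerical_hessian(pot, mol), mol)
        assert len(analysis.wavenumbers) == 1
        assert analysis.wavenumbers[0] == pytest.approx(
            diatomic_closed_form_wavenumber(k, 1.0), abs=0.01
        )

    def test_zpve_half_quantum(self):
        pot = ToyPotential("harmonic_bond", k=0.6, r0=1.0)
        mol = make_diatomic(1.0)
        analysis = harmonic_frequencies(numerical_hessian(pot, mol), mol)
        expected = 0.5 * const.HC_HARTREE_CM * analysis.wavenumbers[0]
        assert analysis.zpve == pytest.approx(expected)

    def test_linear_triatomic_mode_count(self):
        mol = Molecule([
            Atom("O", [0, 0, 0]), Atom("C", [0, 0, 1.16]),
            Atom("O", [0, 0, 2.32]),
        ])
        pot = ToyPotential("harmonic_bond", k=0.5, r0=1.16)
        analysis = harmonic_frequencies(numerical_hessian(pot, mol), mol)
        assert analysis.linear
        assert len(analysis.wavenumbers) == 4  # 3N - 5

    def test_bent_triatomic_mode_count(self, water_like):
        pot = ToyPotential("harmonic_bond", k=0.5, r0=0.96)
        analysis = harmonic_frequencies(
            numerical_hessian(pot, water_like), water_like
        )
        assert not analysis.linear
        assert len(analysis.wavenumbers) == 3  # 3N - 6

    def test_double_well_top_has_imaginary_mode(self):
        pot = ToyPotential("double_well", barrier=0.05, minima=(0.8, 1.2))
        mol = make_diatomic(1.0)  # the barrier top
        analysis = harmonic_frequencies(numerical_hessian(pot, mol), mol)
        assert analysis.n_imaginary == 1
        assert analysis.wavenumbers[0] < 0

    def test_asymmetric_hessian_rejected(self):
        mol = make_diatomic(1.0)
        H = np.random.default_rng(0).normal(size=(6, 6))
        with pytest.raises(ValueError, match="asymmetric"):
            harmonic_frequencies(H, mol)


class TestThermochemistry:
    def test_monatomic_enthalpy_offset(self):
        atom = Molecule([Atom("Ar", [0, 0, 0])], properties={"energy": -1.0})
        th = thermochemistry(np.array([]), atom, T=298.15)
        assert th.H_T - th.E_tot == pytest.approx(
            2.5 * const.KB_HARTREE * 298.15, abs=1e-15
        )

    def test_sackur_tetrode_closed_form(self):
        T, p = 298.15, const.ATM_PA
        atom = Molecule([Atom("Ar", [0, 0, 0])], properties={"energy": 0.0})
        th = thermochemistry(np.array([]), atom, T=T, pressure=p)
        # independent closed form in SI
        m = 39.95 * const.DALTON_SI
        kT = const.BOLTZMANN_SI * T
        S_si = const.BOLTZMANN_SI * (
            np.log((2 * np.pi * m * kT / const.PLANCK_SI**2) ** 1.5 * kT / p)
            + 2.5
        )
        assert th.S == pytest.approx(S_si / const.HARTREE_SI, rel=1e-6)

    def test_gibbs_identity(self, water_like):
        pot = ToyPotential("harmonic_bond", k=0.5, r0=0.96)
        analysis = harmonic_frequencies(
            numerical_hessian(pot, water_like), water_like
        )
        water_like.set_property("energy", -76.0)
        th = thermochemistry(analysis, water_like, T=350.0)
        assert th.G_T == pytest.approx(th.H_T - 350.0 * th.S, abs=1e-10)

    def test_low_temperature_limit(self):
        mol = make_diatomic(1.0)
        th = thermochemistry(np.array([2000.0]), mol, T=1e-5, E_tot=-1.0)
        assert th.E_vib == pytest.approx(0.0, abs=1e-30)
        # H -> E_tot + ZPVE as the thermal terms (a few kT) vanish with T
        assert th.H_T - (-1.0 + th.zpve) == pytest.approx(0.0, abs=1e-9)

    def test_imaginary_modes_excluded_with_warning(self):
        mol = make_diatomic(1.0)
        with pytest.warns(UserWarning, match="imaginary"):
            th = thermochemistry(np.array([-500.0, 1500.0]), mol, T=298.15)
        clean = thermochemistry(np.array([1500.0]), mol, T=298.15)
        assert th.zpve == clean.zpve

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            thermochemistry(np.array([]), make_diatomic(1.0), T=0.0)


class TestHeatOfFormation:
    T = 298.15

    def test_synthetic_h2_hand_derived(self):
        # independent end-to-end hand formula:
        # dHf = 2 dHf(H) - [2 (E_H + 2.5 kT) - H_T(H2)] * 627.5094740631
        kT = const.KB_HARTREE * self.T
        e_h, dhf_h = -0.50088088, 52.102
        h_mol = -1.15
        expected = 2 * dhf_h - (
            (2 * (e_h + 2.5 * kT) - h_mol) * const.HARTREE_TO_KCALMOL
        )
        got = heat_of_formation(h_mol, {"H": 2}, ANI1CCX_REFERENCE, self.T)
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(8.22, abs=0.01)

    def test_zero_atomization_enthalpy(self):
        kT = const.KB_HARTREE * self.T
        table = AtomicReferenceTable({"H": (-0.5, 52.102)})
        h_mol = 2 * (-0.5 + 2.5 * kT)  # exactly the atomic sum
        got = heat_of_formation(h_mol, {"H": 2}, table, self.T)
        assert got == pytest.approx(2 * 52.102, abs=1e-10)

    def test_linearity_under_doubling(self):
        got1 = heat_of_formation(-1.15, {"H": 2}, ANI1CCX_REFERENCE, self.T)
        got2 = heat_of_formation(-2.30, {"H": 4}, ANI1CCX_REFERENCE, self.T)
        assert got2 == pytest.approx(2 * got1, abs=1e-9)

    def test_missing_element_rejected(self):
        with pytest.raises(KeyError, match="missing"):
            heat_of_formation(-1.0, {"Si": 1}, ANI1CCX_REFERENCE, self.T)
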