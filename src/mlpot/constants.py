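"""Physical constants and unit conversions.

Internal unit system: length in angstrom (A), time in femtoseconds (fs),
mass in dalton (Da), energy in hartree, temperature in kelvin.  Everything
that crosses a unit boundary goes through the constants below (CODATA 2018 /
SI-2019 exact values where available).
"""

# --- SI building blocks (exact where SI defines them so) -------------------
PLANCK_SI = 6.62607015e-34          # J s
BOLTZMANN_SI = 1.380649e-23         # J / K
AVOGADRO = 6.02214076e23            # 1 / mol
SPEED_OF_LIGHT_CM = 2.99792458e10   # cm / s

HARTREE_SI = 4.3597447222071e-18    # J
DALTON_SI = 1.66053906660e-27       # kg
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_SI = 1e-10                 # m
FEMTOSECOND_SI = 1e-15              # s

# --- derived conversions ----------------------------------------------------
HARTREE_TO_KCALMOL = 627.5094740631
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL

#: Boltzmann constant in hartree / K
KB_HARTREE = BOLTZMANN_SI / HARTREE_SI

#: One Da * A^2 / fs^2 expressed in hartree (kinetic-energy conversion)
DA_A2_FS2_TO_HARTREE = DALTON_SI * ANGSTROM_SI**2 / FEMTOSECOND_SI**2 / HARTREE_SI

#: One hartree / (Da * A^2 / fs^2): multiplies F[hartree/A] / m[Da] to give
#: acceleration in A / fs^2
HARTREE_TO_DA_A2_FS2 = 1.0 / DA_A2_FS2_TO_HARTREE

#: h*c in hartree * cm — converts a wavenumber in cm^-1 to a mode quantum
HC_HARTREE_CM = PLANCK_SI * SPEED_OF_LIGHT_CM / HARTREE_SI

#: sqrt(hartree / (Da * A^2)) in rad / s — converts mass-weighted Hessian
#: eigenvalues to angular frequencies
OMEGA_SI_PER_SQRT_EIG = (HARTREE_SI / (DALTON_SI * ANGSTROM_SI**2)) ** 0.5

#: speed of light in cm / fs (wavenumber <-> frequency on the fs time axis)
SPEED_OF_LIGHT_CM_FS = SPEED_OF_LIGHT_CM * FEMTOSECOND_SI

#: 1 atm in Pa (standard-state pressure for thermochemistry)
ATM_PA = 101325.0
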