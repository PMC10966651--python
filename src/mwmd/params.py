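"""Physical constants and the versioned toy parameter set.

Units throughout the package follow GROMOS conventions: lengths in nm,
time in ps, mass in u, temperature in K, energy in kJ/mol, charge in
units of the elementary charge e.  All force-field numbers that are not
derived at run time live here so that every simulation is reproducible
from a single versioned table.
"""

from __future__ import annotations

import math

PARAMETER_SET_VERSION = "toy-1.0"

# Boltzmann constant, kJ/(mol*K); fixed to 8 significant digits so that
# temperatures computed in tests are bit-reproducible.
KB = 0.00831446

# Coulomb conversion factor  e^2/(4 pi eps0), in kJ*nm/(mol*e^2).
F_COULOMB = 138.935458

# Pressure conversion: 1 kJ/(mol*nm^3) expressed in bar and in atm.
BAR_PER_KJ_MOL_NM3 = 16.6054
ATM_PER_KJ_MOL_NM3 = BAR_PER_KJ_MOL_NM3 / 1.01325

# Molar concentration of pure water (mol/L), used to convert a salt
# concentration into a number of ion pairs per water molecule.
WATER_MOLARITY = 55.345

AVOGADRO = 6.02214076e23

# ---------------------------------------------------------------------------
# Rigid three-site (SPC) water
# ---------------------------------------------------------------------------
# Canonical published SPC geometry and charges: one Lennard-Jones oxygen,
# two charged hydrogens, O-H 0.1 nm, H-O-H 109.47 degrees.
WATER_O_MASS = 15.9994
WATER_H_MASS = 1.008
WATER_MASS = WATER_O_MASS + 2.0 * WATER_H_MASS
WATER_MOLAR_MASS_G = 18.0154  # g/mol, for density arithmetic

WATER_Q_O = -0.82
WATER_Q_H = 0.41

WATER_D_OH = 0.1  # nm
WATER_ANGLE_HOH = 109.47  # degrees
WATER_D_HH = 2.0 * WATER_D_OH * math.sin(math.radians(WATER_ANGLE_HOH) / 2.0)

# SPC oxygen Lennard-Jones parameters in C6/C12 form
#   C6  in kJ mol^-1 nm^6,  C12 in kJ mol^-1 nm^12
WATER_C6_O = 2.617e-3
WATER_C12_O = 2.634e-6

# ---------------------------------------------------------------------------
# Toy ion parameters (single Lennard-Jones site, +-1 e)
# ---------------------------------------------------------------------------
ION_PARAMS = {
    "NA": {"mass": 22.98977, "charge": 1.0, "c6": 7.21e-5, "c12": 2.1e-8},
    "CL": {"mass": 35.453, "charge": -1.0, "c6": 8.77e-3, "c12": 1.54e-5},
}

# ---------------------------------------------------------------------------
# Toy united-atom solute parameters
# ---------------------------------------------------------------------------
# Per-site Lennard-Jones parameters; pair parameters are combined
# geometrically, C6_ij = sqrt(C6_i C6_j), as in GROMOS-style tables.
SOLUTE_LJ = {
    "N": {"c6": 2.436e-3, "c12": 2.319e-6},
    "C": {"c6": 4.838e-3, "c12": 1.837e-5},   # united CH_n carbon
    "O": {"c6": 2.262e-3, "c12": 1.0e-6},
    "CB": {"c6": 9.0e-3, "c12": 2.7e-5},      # side-chain bead
}

# Backbone partial charges for the 5-site residue (N, CA, C, O, CB);
# the amide hydrogen is united into the geometry (it is reconstructed
# from backbone coordinates during hydrogen-bond analysis).
SOLUTE_CHARGES = {"N": -0.31, "CA": 0.31, "C": 0.45, "O": -0.45}
SIDECHAIN_CHARGED_FRACTION = 0.2  # fraction of residues carrying a +-1 bead

# Bonded parameters (harmonic bonds/angles, periodic dihedrals)
BOND_LENGTHS = {  # nm
    ("N", "CA"): 0.147,
    ("CA", "C"): 0.153,
    ("C", "O"): 0.123,
    ("C", "N"): 0.133,   # peptide bond to next residue
    ("CA", "CB"): 0.153,
}
BOND_K = 3.0e5  # kJ/(mol*nm^2), stiff enough to be SHAKE-equivalent

ANGLE_THETA0 = {  # degrees
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "N"): 116.0,
    ("CA", "C", "O"): 121.0,
    ("O", "C", "N"): 123.0,
    ("C", "N", "CA"): 121.0,
    ("N", "CA", "CB"): 110.0,
    ("CB", "CA", "C"): 110.0,
}
ANGLE_K = 400.0  # kJ/(mol*rad^2)

# Backbone dihedrals: omega is kept stiff and trans; phi/psi get a soft
# threefold term so conformations can interconvert at desk scale.
DIHEDRAL_OMEGA = {"k": 33.5, "multiplicity": 2, "phase_deg": 180.0}
DIHEDRAL_SOFT = {"k": 1.0, "multiplicity": 3, "phase_deg": 0.0}

# ---------------------------------------------------------------------------
# Analysis defaults
# ---------------------------------------------------------------------------
# Geometric hydrogen-bond criterion (GROMOS++ convention).
HBOND_MAX_HA_DISTANCE = 0.25  # nm, H...acceptor
HBOND_MIN_ANGLE = 135.0  # degrees, donor-H...acceptor

# Solvent-probe radius and sphere-point density for accessible surface area.
SASA_PROBE_RADIUS = 0.14  # nm
SASA_N_POINTS = 960

# Atomic radii for surface-area calculations, by element/site key (nm).
SASA_RADII = {
    "C": 0.180,
    "N": 0.155,
    "O": 0.152,
    "H": 0.110,
    "NA": 0.230,
    "CL": 0.180,
}

# Residue polarity classes used for the polar/nonpolar surface split.
NONPOLAR_RESIDUES = frozenset(
    {"ALA", "CYS", "ILE", "LEU", "MET", "PHE", "TRP", "TYR", "VAL"}
)
POLAR_RESIDUES = frozenset(
    {"ARG", "ASN", "ASP", "GLU", "GLY", "GLN", "HIS", "LYS", "PRO", "SER", "THR"}
)

# Backbone hydrogen-bond energy threshold for the simplified secondary-
# structure assignment (kJ/mol); the classic -0.5 kcal/mol cutoff.
SS_ENERGY_CUTOFF = -2.09
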