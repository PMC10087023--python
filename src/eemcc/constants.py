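"""Physical constants and unit conversions.

Internal units are fixed throughout the package: lengths in Å, energies in
kJ mol⁻¹ (forces in kJ mol⁻¹ Å⁻¹), masses in amu, temperatures in K.
Entropies are reported in J K⁻¹ mol⁻¹ to match the conventions of the
thermodynamic tables produced by :mod:`eemcc.reporting`.
"""

# CODATA 2018
PLANCK_SI = 6.62607015e-34        # J s
KB_SI = 1.380649e-23              # J K^-1
AVOGADRO = 6.02214076e23          # mol^-1

R_J = 8.31446261815324            # gas constant, J K^-1 mol^-1 (= kB per mole)
KB_KJ = R_J * 1e-3                # kJ K^-1 mol^-1

KCAL_TO_KJ = 4.184

# Conversion of lambda/(kB T) from internal units (kJ mol^-1 Å^-2 amu^-1, the
# same for torque eigenvalues in kJ^2 mol^-2 / (amu Å^2) / (kJ mol^-1)) to
# angular frequency squared in s^-2.  The factor is exactly 1e26 because
# 1 kJ/mol = 1e3/N_A J and 1 amu = 1e-3/N_A kg, so their ratio is 1e6 J/kg,
# and Å^-2 contributes 1e20 m^-2.
OMEGA_SQ_TO_SI = 1.0e26

# Symmetry number of the water molecule (C2v).
WATER_SYMMETRY_NUMBER = 2.0

# Ideal hydrogen-bond probability: two HBs with 0.5 probability each to
# donate and accept gives p_HB = 0.5 * 0.5 = 0.25.
P_HB_IDEAL = 0.25

WATER_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP3", "TIP3P", "TP3", "SOL", "SPC", "SPCE", "H2O", "W"}
)
ION_RESNAMES = frozenset(
    {"NA", "NA+", "SOD", "CL", "CL-", "CLA", "K", "K+", "POT",
     "MG", "MG2", "CA2", "ZN", "ZN2", "LI", "CS", "BR", "IOD", "F"}
)
PROTEIN_RESNAMES = frozenset(
    {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
     "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
     "HIE", "HID", "HIP", "ASH", "GLH", "CYX", "CYM", "LYN", "ACE", "NME",
     "NMA"}
)
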