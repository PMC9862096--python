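"""Physical constants and published reference values for the native-membrane system.

The native membranes are inside-out vesicles from High-Five insect cells
over-expressing mouse P-glycoprotein.  The composition constants below
(phospholipid:protein mass ratio, mean phospholipid molar mass, lipid molar
volume, protein density, P-gp molar volume) characterise that preparation and
are the defaults used throughout the package.
"""

from __future__ import annotations

# Membrane-preparation composition defaults
PL_PROTEIN_MASS_RATIO = 0.57     # w/w, phospholipid : total protein
PL_MOLAR_MASS = 750.0            # g/mol, mean phospholipid molar mass
LIPID_MOLAR_VOLUME = 0.8         # dm^3/mol
PROTEIN_DENSITY = 1.2            # g/mL, assumed for all membrane proteins
PGP_MOLAR_VOLUME = 142.0         # dm^3/mol, from P-gp molar mass at 1.2 g/mL

# Assay conditions
ATPASE_PROTEIN_CONC = 0.107      # mg total protein / mL in ATPase assays
IAAP_PROTEIN_CONC = 1.0          # mg/mL in IAAP photolabeling assays
ATPASE_PGP_CONC = 6e-9           # M
IAAP_PGP_CONC = 60e-9            # M

# IAAP radioligand
IAAP_KD = 412e-9                 # M, literature dissociation constant
IAAP_TOTAL = 5e-9                # M, tracer concentration (5-7 nM used)

# Published partition coefficients between media (dimensionless, volume basis).
# Two reduction scenarios for the whole-membrane value: the protein volume in
# the membrane taken as P-gp only, or as all membrane proteins.
TABLE_KP = {
    "pgp_only": {
        "NBD-C4": {"kp_w_m": 1.4e3, "kp_w_lb": 3.9e2, "kp_w_p": 6.9e4, "kp_lb_p": 176.0},
        "NBD-C6": {"kp_w_m": 3.9e3, "kp_w_lb": 2.4e3, "kp_w_p": 1.0e5, "kp_lb_p": 43.0},
        "NBD-C8": {"kp_w_m": 2.2e4, "kp_w_lb": 1.9e4, "kp_w_p": 2.3e5, "kp_lb_p": 12.0},
    },
    "all_proteins": {
        "NBD-C4": {"kp_w_m": 5.7e2, "kp_w_lb": 3.9e2, "kp_w_p": 6.9e2, "kp_lb_p": 1.8},
        "NBD-C6": {"kp_w_m": 1.6e3, "kp_w_lb": 2.4e3, "kp_w_p": 1.0e3, "kp_lb_p": 0.43},
        "NBD-C8": {"kp_w_m": 9.0e3, "kp_w_lb": 1.9e4, "kp_w_p": 2.3e3, "kp_lb_p": 0.12},
    },
}

# Molecular descriptors of the amphiphile series (computed LogD at pH 7.4,
# net charge, alkyl-chain carbons, critical aggregation concentration at 25 C).
AMPHIPHILES = {
    "NBD-C4": {"chain_length": 4, "clogd": 2.06, "charge": 0, "cac_25c": 250e-6},
    "NBD-C6": {"chain_length": 6, "clogd": 2.95, "charge": 0, "cac_25c": None},
    "NBD-C8": {"chain_length": 8, "clogd": 3.84, "charge": 0, "cac_25c": 1e-6},
    "NBD-LysoMPE": {"chain_length": 14, "clogd": 2.64, "charge": -1, "cac_25c": 4e-6},
}

# Log10 KP to pure POPC bilayers for the homologous series (literature values)
POPC_LOG_KP = {"NBD-C4": 2.99, "NBD-C6": 3.79, "NBD-C8": 4.67, "NBD-LysoMPE": 4.2}

# Log10 KP (water -> whole native membrane, all-proteins volume reduction)
NATIVE_LOG_KP_W_M = {"NBD-C4": 2.75, "NBD-C6": 3.20, "NBD-C8": 3.95, "NBD-LysoMPE": 4.34}
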