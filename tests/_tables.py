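"""Published hERG fit values used as inputs to the energetics arm.

(z, V1/2) pairs from two-state Boltzmann fits of activation (G-V) and
steady-state inactivation curves for the wild type and the
noncanonical-path mutants, with their standard errors, plus the derived
free-energy tables they determine.  Voltages in mV, energies kcal/mol.
"""

# construct -> (v_half, v_half_se, z, z_se)
ACTIVATION_FITS = {
    "WT": (-24.6, 0.5, 2.8, 0.1),
    "T425L": (-5.2, 0.4, 2.6, 0.1),
    "L524R": (-39.6, 0.7, 2.1, 0.1),
    "A527L": (-30.8, 1.6, 2.9, 0.5),
    "L529H": (-56.7, 0.9, 2.8, 0.3),
    "L532H": (-33.9, 1.4, 3.0, 0.4),
    "W563L": (-51.7, 1.0, 3.3, 0.4),
    "A614G": (-21.2, 0.2, 3.3, 0.1),
    "T618L": (-18.9, 0.7, 2.7, 0.2),
}

INACTIVATION_FITS = {
    "WT": (-61.8, 0.7, 0.9, 0.1),
    "T425L": (-34.8, 1.1, 0.7, 0.1),
    "L524R": (-89.6, 1.5, 0.7, 0.1),
    "A527L": (-78.6, 0.6, 0.9, 0.1),
    "L529H": (-77.5, 1.6, 0.8, 0.1),
    "L532H": (-86.6, 1.5, 0.6, 0.1),
    "W563L": (-60.7, 0.7, 0.9, 0.1),
    "A614G": (-69.7, 2.0, 1.1, 0.1),
    "T618L": (-63.0, 0.7, 0.9, 0.1),
}

# construct -> dG (kcal/mol), printed to one decimal
DG_ACTIVATION = {
    "WT": -1.6,
    "T425L": -0.3,
    "L524R": -1.9,
    "A527L": -2.1,
    "L529H": -3.7,
    "L532H": -2.4,
    "W563L": -4.0,
    "A614G": -1.6,
    "T618L": -1.2,
}

DG_INACTIVATION = {
    "WT": -1.2,
    "T425L": -0.6,
    "L524R": -1.5,
    "A527L": -1.6,
    "L529H": -1.4,
    "L532H": -1.2,
    "W563L": -1.2,
    "A614G": -1.8,
    "T618L": -1.3,
}

# construct -> ddG vs WT (kcal/mol)
DDG_ACTIVATION = {
    "T425L": 1.3,
    "L524R": -0.4,
    "A527L": -0.5,
    "L529H": -2.1,
    "L532H": -0.8,
    "W563L": -2.4,
    "A614G": 0.0,
    "T618L": 0.4,
}

DDG_INACTIVATION = {
    "T425L": 0.7,
    "L524R": -0.3,
    "A527L": -0.3,
    "L529H": -0.2,
    "L532H": 0.1,
    "W563L": 0.0,
    "A614G": -0.6,
    "T618L": 0.0,
}


def fits_dataframe():
    """Long-format fit table (construct, kind, z, z_se, v_half, v_half_se)."""
    import pandas as pd

    rows = []
    for kind, table in (
        ("activation", ACTIVATION_FITS),
        ("inactivation", INACTIVATION_FITS),
    ):
        for construct, (v, v_se, z, z_se) in table.items():
            rows.append(
                {
                    "construct": construct,
                    "kind": kind,
                    "z": z,
                    "z_se": z_se,
                    "v_half": v,
                    "v_half_se": v_se,
                }
            )
    return pd.DataFrame(rows)
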