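"""Unit constants and species reference parameters.

All unit conversions used anywhere in the package are centralized here so the
dose/irradiance bookkeeping (photons nm⁻² vs μmol photons m⁻² s⁻¹) lives in one
place.
"""

from __future__ import annotations

#: photons nm⁻² s⁻¹ delivered by 1 μmol photons m⁻² s⁻¹.
#: 1 μmol photons m⁻² s⁻¹ = 6.022e17 photons m⁻² s⁻¹ = 6.022e-4 photons nm⁻² s⁻¹.
PHOTONS_NM2_PER_UMOL_M2 = 6.022e-4

#: molar mass of carbon, g mol⁻¹
CARBON_MOLAR_MASS = 12.011

#: minutes -> seconds
S_PER_MIN = 60.0
#: hours -> minutes
MIN_PER_H = 60.0
#: day -> hours
H_PER_DAY = 24.0

#: study irradiances, μmol photons m⁻² s⁻¹
GROWTH_IRRADIANCE = 85.0
HIGH_LIGHT = 1200.0
RECOVERY_LIGHT = 15.0

# ---------------------------------------------------------------------------
# Reference photophysiological parameters for the three Thalassiosira species
# (means under exponential growth at 85 μmol photons m⁻² s⁻¹, 20 °C).  These
# ship with the package so synthetic datasets can be generated with realistic
# ground truth without transcription.
# ---------------------------------------------------------------------------

SPECIES_REFERENCE: dict[str, dict[str, float]] = {
    "T_weissflogii": {
        "growth_rate_per_d": 0.68,
        "cells_per_ml": 1.40e5,
        "chla_pg_cell": 5.66,
        "poc_pg_cell": 158.91,
        "fv_fm": 0.58,
        "sigma_psii_nm2": 2.29,
        "k_pi_per_s": 2.23e-4,
        "k_rec_per_s": 3.16e-4,
    },
    "T_oceanica": {
        "growth_rate_per_d": 0.80,
        "cells_per_ml": 3.62e5,
        "chla_pg_cell": 1.03,
        "poc_pg_cell": 56.13,
        "fv_fm": 0.55,
        "sigma_psii_nm2": 3.98,
        "k_pi_per_s": 4.50e-4,
        "k_rec_per_s": 5.48e-4,
    },
    "T_pseudonana": {
        "growth_rate_per_d": 0.94,
        "cells_per_ml": 12.68e5,
        "chla_pg_cell": 0.60,
        "poc_pg_cell": 7.92,
        "fv_fm": 0.56,
        "sigma_psii_nm2": 3.01,
        "k_pi_per_s": 3.46e-4,
        "k_rec_per_s": 1.50e-3,
    },
}

#: xanthophyll-cycle pigment pools normalized to Chl a (μg μg⁻¹) under growth
#: irradiance (Ig) and after a 10 min shift to high light (HL)
PIGMENT_REFERENCE: dict[tuple[str, str], dict[str, float]] = {
    ("T_weissflogii", "Ig"): {"chlc": 0.028, "fuc": 0.533, "bcar": 0.021, "dd": 0.034, "dt": 0.012},
    ("T_weissflogii", "HL"): {"chlc": 0.027, "fuc": 0.525, "bcar": 0.021, "dd": 0.026, "dt": 0.028},
    ("T_oceanica", "Ig"): {"chlc": 0.053, "fuc": 0.959, "bcar": 0.017, "dd": 0.032, "dt": 0.008},
    ("T_oceanica", "HL"): {"chlc": 0.049, "fuc": 0.953, "bcar": 0.018, "dd": 0.027, "dt": 0.027},
    ("T_pseudonana", "Ig"): {"chlc": 0.033, "fuc": 0.659, "bcar": 0.019, "dd": 0.049, "dt": 0.005},
    ("T_pseudonana", "HL"): {"chlc": 0.031, "fuc": 0.650, "bcar": 0.020, "dd": 0.036, "dt": 0.025},
}

#: oxygen-budget fractions (% of GP_O2) used as synthetic ground truth; the
#: T. weissflogii HL row is pinned by the reported %LDR decline from 11.8 (Ig)
#: to 8.1 (HL)
BUDGET_REFERENCE: dict[tuple[str, str], dict[str, float]] = {
    ("T_weissflogii", "Ig"): {"pct_LDR": 11.8, "pct_RDARK": 18.0, "pct_Net": 70.2},
    ("T_weissflogii", "HL"): {"pct_LDR": 8.1, "pct_RDARK": 16.6, "pct_Net": 75.3},
    ("T_oceanica", "Ig"): {"pct_LDR": 10.5, "pct_RDARK": 8.0, "pct_Net": 81.5},
    ("T_oceanica", "HL"): {"pct_LDR": 16.6, "pct_RDARK": 7.0, "pct_Net": 76.4},
    ("T_pseudonana", "Ig"): {"pct_LDR": 10.5, "pct_RDARK": 21.7, "pct_Net": 67.8},
    ("T_pseudonana", "HL"): {"pct_LDR": 16.6, "pct_RDARK": 16.6, "pct_Net": 66.8},
}
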