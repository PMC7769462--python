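"""Regenerate a full synthetic fixture tree (all five input classes plus
sidecar ground-truth JSON) from one seed."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .constants import (BUDGET_REFERENCE, GROWTH_IRRADIANCE, HIGH_LIGHT,
                        PIGMENT_REFERENCE, SPECIES_REFERENCE)
from .synthetic import (budget_to_rates, gen_flc, gen_inactivation_course,
                        gen_mims_set, gen_st_transient, kok_params_for_species,
                        st_params_for_species)
from .sturnover import STProtocol

__all__ = ["make_fixtures"]

#: a feasible 6-step yield-partition target table (dark step first with
#: YNPQ = 0, quenching developing with irradiance)
_FLC_TARGETS = [
    (0.55, 0.00, 0.45),
    (0.50, 0.02, 0.48),
    (0.40, 0.10, 0.50),
    (0.25, 0.25, 0.50),
    (0.12, 0.42, 0.46),
    (0.05, 0.55, 0.40),
]
_FLC_IRRADIANCES = [0.0, 56.0, 134.0, 311.0, 724.0, 1304.0]


def make_fixtures(out_dir, seed: int = 0, species: str = "T_oceanica",
                  noise_cv: float = 0.0, n_replicates: int = 3) -> dict:
    """Write every stage's input CSV plus truth sidecars under ``out_dir``.

    Ground truth comes from the bundled species reference tables; the same
    seed always regenerates byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(8)]
    truths = {}

    protocol = STProtocol()
    tr, truth = gen_st_transient(st_params_for_species(species), protocol,
                                 noise_cv=noise_cv, seed=seeds[0])
    pio.write_transient_csv(tr, protocol, out / "transient.csv")
    truths["transient"] = truth

    f0 = 0.45
    fm = f0 / (1.0 - SPECIES_REFERENCE[species]["fv_fm"])
    # dark step carries the species' Fv/Fm partition
    targets = [(SPECIES_REFERENCE[species]["fv_fm"], 0.0,
                1.0 - SPECIES_REFERENCE[species]["fv_fm"])] + _FLC_TARGETS[1:]
    steps, dark, truth = gen_flc(targets, F0=f0, Fm=fm,
                                 irradiances=_FLC_IRRADIANCES, seed=seeds[1])
    pio.write_flc_csv(steps, out / "flc.csv")
    truths["flc"] = truth

    kok = kok_params_for_species(species)
    courses = []
    for i in range(n_replicates):
        c, t_l = gen_inactivation_course(kok, lincomycin=True,
                                         noise_cv=noise_cv,
                                         seed=seeds[2] + i,
                                         replicate_id=f"linco{i}")
        courses.append(c)
        c, t_c = gen_inactivation_course(kok, lincomycin=False,
                                         noise_cv=noise_cv,
                                         seed=seeds[3] + i,
                                         replicate_id=f"ctrl{i}")
        courses.append(c)
    pio.write_timecourse_csv(courses, out / "timecourse.csv")
    truths["timecourse"] = t_c

    frac = BUDGET_REFERENCE[(species, "HL")]
    gp_hl, r_dark, ldr_hl = budget_to_rates(frac["pct_LDR"],
                                            frac["pct_RDARK"], gp=240.0)
    readings, truth = gen_mims_set((gp_hl, r_dark, ldr_hl),
                                   light_treatment="HL",
                                   noise_cv=noise_cv, seed=seeds[4])
    # the Ig vial shares the T0/dark baseline (one dark vial per set), so its
    # rate triple reuses the HL set's absolute R_DARK
    gp_ig = 120.0
    ldr_ig = BUDGET_REFERENCE[(species, "Ig")]["pct_LDR"] / 100.0 * gp_ig
    readings_ig, _ = gen_mims_set((gp_ig, r_dark, ldr_ig),
                                  light_treatment="Ig",
                                  noise_cv=noise_cv, seed=seeds[5])
    all_readings = list(readings.values()) + [readings_ig["Ig"]]
    pio.write_mims_csv(all_readings, out / "mims.csv")
    truths["mims"] = truth

    ref = SPECIES_REFERENCE[species]
    n0 = ref["cells_per_ml"]
    mu = ref["growth_rate_per_d"]
    pd.DataFrame(
        {
            "sample_id": ["s1", "s1"],
            "species": [species, species],
            "t_day": [0.0, 1.0],
            "cells_per_ml": [n0, n0 * np.exp(mu)],
            "poc_pg_cell": [ref["poc_pg_cell"]] * 2,
            "chla_pg_cell": [ref["chla_pg_cell"]] * 2,
        }
    ).to_csv(out / "culture.csv", index=False)

    rows = []
    chla = 1.0  # μg mL⁻¹ scale; ratios are what matter
    for (sp, treat), pig in PIGMENT_REFERENCE.items():
        if sp != species:
            continue
        rows.append({"sample_id": "p1", "treatment": treat, "chla": chla,
                     "chlc": pig["chlc"] * chla, "fuc": pig["fuc"] * chla,
                     "bcar": pig["bcar"] * chla, "dd": pig["dd"] * chla,
                     "dt": pig["dt"] * chla})
    pd.DataFrame(rows).to_csv(out / "pigment.csv", index=False)

    sidecar = {k: json.loads(v.to_json()) for k, v in truths.items()}
    sidecar["species"] = species
    sidecar["seed"] = seed
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
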