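"""Tidy-CSV readers and writers for every stage input/output.

Column layouts:

* transient:   flashlet_index, phase, time_us, dose_photons_per_nm2, fluorescence
* FLC:         step_index, irradiance_umol_m2_s, F_prime, Fm_prime, duration_min
* time course: replicate_id, lincomycin, time_min, measure, value
               (measure ∈ {FvFm_relaxed, FvFm_prime})
* MIMS:        vial_id, treatment, current_32, current_36, current_40, timestamp
* culture:     sample_id, species, t_day, cells_per_ml, poc_pg_cell, chla_pg_cell
* pigments:    sample_id, treatment, chla, chlc, fuc, bcar, dd, dt
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kok import InactivationTimecourse, LightPhase
from .mims import IonCurrentReading
from .sturnover import STProtocol, STTransient
from .yields import FLCStep


def write_transient_csv(transient: STTransient, protocol: STProtocol,
                        path) -> None:
    df = transient.to_frame()[["flashlet_index", "phase", "time_us",
                               "fluorescence"]]
    df.insert(3, "dose_photons_per_nm2", protocol.flashlet_dose)
    df.to_csv(path, index=False)


def read_transient_csv(path) -> tuple[STTransient, float]:
    """Read a transient trace; closed fractions are not observable from the
    instrument and come back as NaN.  Returns (transient, flashlet dose)."""
    df = pd.read_csv(path)
    dose = float(df["dose_photons_per_nm2"].iloc[0])
    tr = STTransient(
        times=df["time_us"].to_numpy(float),
        closed_fraction=np.full(len(df), np.nan),
        fluorescence=df["fluorescence"].to_numpy(float),
        phase_labels=df["phase"].to_numpy(object),
    )
    return tr, dose


def write_flc_csv(steps: Sequence[FLCStep], path) -> None:
    pd.DataFrame(
        {
            "step_index": range(len(steps)),
            "irradiance_umol_m2_s": [s.irradiance for s in steps],
            "F_prime": [s.F_prime for s in steps],
            "Fm_prime": [s.Fm_prime for s in steps],
            "duration_min": [s.duration_min for s in steps],
        }
    ).to_csv(path, index=False)


def read_flc_csv(path) -> list[FLCStep]:
    df = pd.read_csv(path).sort_values("step_index")
    return [
        FLCStep(irradiance=r.irradiance_umol_m2_s, F_prime=r.F_prime,
                Fm_prime=r.Fm_prime, duration_min=r.duration_min)
        for r in df.itertuples()
    ]


def write_timecourse_csv(courses: Sequence[InactivationTimecourse], path) -> None:
    rows = []
    for c in courses:
        for t, v in zip(c.times_min, c.y):
            rows.append({"replicate_id": c.replicate_id,
                         "lincomycin": int(c.lincomycin), "time_min": t,
                         "measure": "FvFm_relaxed", "value": v})
        if c.y_unrelaxed is not None:
            for t, v in zip(c.times_min, c.y_unrelaxed):
                rows.append({"replicate_id": c.replicate_id,
                             "lincomycin": int(c.lincomycin), "time_min": t,
                             "measure": "FvFm_prime", "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_timecourse_csv(path, phases: tuple[LightPhase, ...],
                        ) -> list[InactivationTimecourse]:
    df = pd.read_csv(path)
    courses = []
    for (rep, linco), g in df.groupby(["replicate_id", "lincomycin"], sort=True):
        relaxed = g[g["measure"] == "FvFm_relaxed"].sort_values("time_min")
        prime = g[g["measure"] == "FvFm_prime"].sort_values("time_min")
        courses.append(InactivationTimecourse(
            times_min=relaxed["time_min"].to_numpy(float),
            y=relaxed["value"].to_numpy(float),
            lincomycin=bool(linco), replicate_id=str(rep), phases=phases,
            y_unrelaxed=(prime["value"].to_numpy(float) if len(prime) else None),
        ))
    return courses


def write_mims_csv(readings: Sequence[IonCurrentReading], path) -> None:
    pd.DataFrame(
        [
            {"vial_id": r.vial_id, "treatment": r.treatment,
             "current_32": r.current_32, "current_36": r.current_36,
             "current_40": r.current_40, "timestamp": r.timestamp}
            for r in readings
        ]
    ).to_csv(path, index=False)


def read_mims_csv(path) -> list[IonCurrentReading]:
    df = pd.read_csv(path)
    return [
        IonCurrentReading(vial_id=str(r.vial_id), treatment=str(r.treatment),
                          current_32=r.current_32, current_36=r.current_36,
                          current_40=r.current_40, timestamp=float(r.timestamp))
        for r in df.itertuples()
    ]


def read_culture_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_pigment_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
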