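"""Seeded synthetic-data generators emulating the study's instruments.

Every generator is an exact right-inverse of its analysis stage at zero
noise, attaches a :class:`SyntheticTruth` record holding the generating
parameters, and is bit-reproducible from its seed.  Noise is multiplicative
Gaussian by default (an approximation to fluorescence / ion-current
shot-plus-gain noise); additive mode is available where it matters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import SPECIES_REFERENCE
from .exceptions import InfeasibleTargetError
from .kok import (InactivationTimecourse, KokParams, LightPhase,
                  default_phases, kok_predict)
from .mims import IonCurrentReading
from .sturnover import STParams, STProtocol, STTransient, simulate_transient
from .yields import DarkReference, FLCStep

__all__ = [
    "SyntheticTruth", "gen_st_transient", "gen_flc",
    "gen_inactivation_course", "gen_mims_set", "budget_to_rates",
    "st_params_for_species", "kok_params_for_species", "DEFAULT_SAMPLE_TIMES_MIN",
]

#: the study's inactivation/recovery sampling grid: 0/30/60/120 min at high
#: light, then 150/180 min under recovery light
DEFAULT_SAMPLE_TIMES_MIN = (0.0, 30.0, 60.0, 120.0, 150.0, 180.0)
LINCOMYCIN_SAMPLE_TIMES_MIN = (0.0, 30.0, 60.0, 120.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters attached to every synthetic dataset."""

    stage: str
    params: dict
    seed: int | None
    noise: str = "none"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)


def _as_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return dict(obj)


def st_params_for_species(species: str, F0: float = 0.45) -> STParams:
    """Single-turnover ground truth for a reference species: the printed
    σ_PSII with F₀/F_m chosen to reproduce the printed F_v/F_m."""
    ref = SPECIES_REFERENCE[species]
    fm = F0 / (1.0 - ref["fv_fm"])
    return STParams(F0=F0, Fm=fm, sigma_psii=ref["sigma_psii_nm2"])


def kok_params_for_species(species: str) -> KokParams:
    ref = SPECIES_REFERENCE[species]
    return KokParams(k_pi=ref["k_pi_per_s"], k_rec=ref["k_rec_per_s"])


# ---------------------------------------------------------------------------
# single-turnover transients
# ---------------------------------------------------------------------------

def gen_st_transient(truth: STParams, protocol: STProtocol | None = None,
                     noise_cv: float = 0.0, seed: int | None = None,
                     ) -> tuple[STTransient, SyntheticTruth]:
    """Simulate an acquisition: ``n_sequences`` per-flashlet multiplicative-
    noise replicate sequences, averaged into one trace (the instrument's
    sequence averaging).  noise_cv = 0 returns the noiseless forward model."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    protocol = protocol or STProtocol()
    clean = simulate_transient(truth, protocol)
    if noise_cv == 0.0:
        f = clean.fluorescence.copy()
    else:
        rng = np.random.default_rng(seed)
        reps = clean.fluorescence * rng.normal(
            1.0, noise_cv, size=(protocol.n_sequences, len(clean.fluorescence)))
        f = reps.mean(axis=0)
    out = STTransient(clean.times.copy(), clean.closed_fraction.copy(),
                      f, clean.phase_labels.copy())
    meta = SyntheticTruth("st_transient",
                          {**_as_dict(truth), "protocol": _as_dict(protocol)},
                          seed, noise=f"multiplicative_gaussian cv={noise_cv}")
    return out, meta


# ---------------------------------------------------------------------------
# fluorescence light curves
# ---------------------------------------------------------------------------

def gen_flc(targets: Sequence[tuple[float, float, float]],
            F0: float, Fm: float,
            irradiances: Sequence[float] | None = None,
            seed: int | None = None,
            ) -> tuple[list[FLCStep], DarkReference, SyntheticTruth]:
    """Invert the yield partition: emit (F′, F_m′) per step so that
    ``partition_flc`` recovers the target (YII, YNPQ, YNO) triples exactly.

    F′ = YNO·F_m and F_m′ = F′/(1 − YII); feasibility requires each triple in
    [0,1] summing to 1 and YNPQ = 0 at the reference (F_m-attaining) step.
    """
    targets = [tuple(map(float, t)) for t in targets]
    if irradiances is None:
        irradiances = np.linspace(0.0, 1304.0, len(targets))
    if len(irradiances) != len(targets):
        raise ValueError("irradiances and targets must have equal length")
    if not any(abs(t[1]) < 1e-12 for t in targets):
        raise InfeasibleTargetError(
            "no step with YNPQ = 0: the reference step must attain Fm")
    steps = []
    for i, (y2, ynpq_t, yno_t) in enumerate(targets):
        for name, v in (("YII", y2), ("YNPQ", ynpq_t), ("YNO", yno_t)):
            if not 0.0 <= v <= 1.0:
                raise InfeasibleTargetError(
                    f"step {i}: {name}={v} outside [0, 1]")
        if abs(y2 + ynpq_t + yno_t - 1.0) > 1e-9:
            raise InfeasibleTargetError(
                f"step {i}: targets sum to {y2 + ynpq_t + yno_t}, not 1")
        f_prime = yno_t * Fm
        if y2 >= 1.0 or f_prime <= 0.0:
            raise InfeasibleTargetError(
                f"step {i}: YII={y2}, YNO={yno_t} give no valid (F', Fm')")
        fm_prime = f_prime / (1.0 - y2)
        if fm_prime > Fm * (1 + 1e-12):
            raise InfeasibleTargetError(
                f"step {i}: implied Fm'={fm_prime} exceeds Fm={Fm} "
                f"(violates YNPQ >= 0)")
        steps.append(FLCStep(irradiance=float(irradiances[i]),
                             F_prime=f_prime, Fm_prime=min(fm_prime, Fm)))
    dark = DarkReference(F0=F0, Fm=Fm)
    meta = SyntheticTruth("flc", {"targets": targets, "F0": F0, "Fm": Fm},
                          seed)
    return steps, dark, meta


# ---------------------------------------------------------------------------
# inactivation / recovery time courses
# ---------------------------------------------------------------------------

def gen_inactivation_course(truth: KokParams,
                            phases: Sequence[LightPhase] | None = None,
                            sample_times_min: Sequence[float] | None = None,
                            lincomycin: bool = False,
                            noise_cv: float = 0.0,
                            seed: int | None = None,
                            amplitude: float = 0.55,
                            replicate_id: str = "r0",
                            ) -> tuple[InactivationTimecourse, SyntheticTruth]:
    """Forward-simulate a dark-relaxed F_v/F_m trajectory.

    ``amplitude`` is the pre-treatment F_v/F_m the active fraction is scaled
    by.  Lincomycin mode forces k_REC = 0 regardless of the truth value and
    defaults to the four high-light sampling times.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    phases = tuple(phases) if phases is not None else default_phases()
    if sample_times_min is None:
        sample_times_min = (LINCOMYCIN_SAMPLE_TIMES_MIN if lincomycin
                            else DEFAULT_SAMPLE_TIMES_MIN)
    t = np.asarray(sample_times_min, dtype=float)
    k_rec = 0.0 if lincomycin else truth.k_rec
    a = kok_predict(truth.sigma_i, k_rec, phases, t, y0=truth.y0)
    y = amplitude * np.asarray(a)
    if noise_cv > 0.0:
        rng = np.random.default_rng(seed)
        y = y * rng.normal(1.0, noise_cv, size=y.shape)
    course = InactivationTimecourse(times_min=t, y=y, lincomycin=lincomycin,
                                    replicate_id=replicate_id, phases=phases)
    meta = SyntheticTruth(
        "inactivation_course",
        {**_as_dict(truth), "lincomycin": lincomycin, "amplitude": amplitude,
         "phases": [_as_dict(p) for p in phases],
         "sample_times_min": list(map(float, t))},
        seed, noise=f"multiplicative_gaussian cv={noise_cv}")
    return course, meta


# ---------------------------------------------------------------------------
# MIMS ion-current sets
# ---------------------------------------------------------------------------

def budget_to_rates(pct_LDR: float, pct_RDARK: float,
                    gp: float = 240.0) -> tuple[float, float, float]:
    """Turn budget fractions (% of GP_O2) into a (GP, R_DARK, LDR) rate
    triple at a chosen gross-production scale."""
    return gp, gp * pct_RDARK / 100.0, gp * pct_LDR / 100.0


def gen_mims_set(truth: tuple[float, float, float],
                 duration_min: float = 20.0,
                 baseline_32: float = 50.0, baseline_36: float = 100.0,
                 ar_current: float = 10.0,
                 light_treatment: str = "HL",
                 noise_cv: float = 0.0, seed: int | None = None,
                 ) -> tuple[dict[str, IonCurrentReading], SyntheticTruth]:
    """Construct T₀/dark/light vial readings whose two-point analysis
    returns the (GP_O2, R_DARK, LDR) hourly-rate truth exactly at zero noise.

    Baselines are O₂/Ar concentration ratios; emitted currents are ratios ×
    the Ar current, so the Ar-normalized analysis recovers them whatever the
    common instrument gain.
    """
    gp, r_dark, ldr = map(float, truth)
    if gp < 0 or r_dark < 0 or r_dark + ldr < 0:
        raise InfeasibleTargetError("GP and uptake rates must be >= 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    d_h = duration_min / 60.0
    sig = {
        "T0": (baseline_32, baseline_36),
        "dark": (baseline_32, baseline_36 - r_dark * d_h),
        light_treatment: (baseline_32 + gp * d_h,
                          baseline_36 - (r_dark + ldr) * d_h),
    }
    rng = np.random.default_rng(seed) if noise_cv > 0 else None
    readings = {}
    for i, (treat, (s32, s36)) in enumerate(sig.items()):
        if s32 <= 0 or s36 <= 0:
            raise InfeasibleTargetError(
                f"truth implies non-positive {treat} signal "
                f"(32: {s32}, 36: {s36}); raise the baselines")
        c32, c36 = s32 * ar_current, s36 * ar_current
        if rng is not None:
            c32 *= rng.normal(1.0, noise_cv)
            c36 *= rng.normal(1.0, noise_cv)
        readings[treat] = IonCurrentReading(
            vial_id=f"v{i}", treatment=treat, current_32=c32, current_36=c36,
            current_40=ar_current, timestamp=float(i * 5))
    meta = SyntheticTruth(
        "mims_set",
        {"GP_O2": gp, "R_DARK": r_dark, "LDR": ldr,
         "duration_min": duration_min, "light_treatment": light_treatment},
        seed, noise=f"multiplicative_gaussian cv={noise_cv}")
    return readings, meta
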