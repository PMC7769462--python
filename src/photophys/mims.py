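"""¹⁸O₂-labelled oxygen budgets from membrane-inlet mass spectrometry (MIMS).

Cultures sparged of ¹⁶O₂ and enriched with ¹⁸O₂ are split into time-zero
(T₀), dark, and light vials and incubated for 20 min.  Ion currents at
m/z 32 (¹⁶O₂), 36 (¹⁸O₂) and 40 (Ar, drift tracer) then separate gross O₂
production (¹⁶O₂ evolution by PSII) from O₂ uptake (¹⁸O₂ decline):

    GP_O2  = (¹⁶O₂_light − ¹⁶O₂_T0) / Δt          gross production
    R_DARK = (¹⁸O₂_T0 − ¹⁸O₂_dark) / Δt           dark respiration
    U_L    = (¹⁸O₂_T0 − ¹⁸O₂_light) / Δt          total light uptake
    LDR    = U_L − R_DARK                          light-dependent respiration
    Net_O2 = GP_O2 − (R_DARK + LDR)

scaled to hourly rates.  Two-point (T₀ vs endpoint) estimation conservatively
underestimates the true rates; this is documented behaviour, not corrected.
Negative computed rates are preserved and flagged, never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .constants import MIN_PER_H
from .exceptions import PhotophysError

__all__ = [
    "IonCurrentReading", "CalibrationPair", "O2Rates", "OxygenBudget",
    "drift_correct", "signals_to_rates", "budget_fractions", "cell_normalize",
]

TREATMENTS = ("T0", "dark", "Ig", "HL")


@dataclass(frozen=True)
class IonCurrentReading:
    """Raw (or drift-corrected) MIMS signals for one vial."""

    vial_id: str
    treatment: str
    current_32: float  # ¹⁶O₂
    current_36: float  # ¹⁸O₂
    current_40: float  # Ar
    timestamp: float = 0.0  # min, on the run clock

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if min(self.current_32, self.current_36, self.current_40) <= 0:
            raise ValueError("ion currents must be > 0")


@dataclass(frozen=True)
class CalibrationPair:
    """Air-equilibrated standard readings bracketing the run.

    ``factor_pre``/``factor_post`` are signal-to-concentration factors per
    mass, interpolated linearly in time between the two calibrations.
    """

    t_pre: float
    t_post: float
    factor_pre: dict
    factor_post: dict

    def __post_init__(self) -> None:
        if self.t_post < self.t_pre:
            raise ValueError("post-calibration must not precede pre-calibration")
        for d in (self.factor_pre, self.factor_post):
            if any(v <= 0 for v in d.values()):
                raise ValueError("calibration factors must be > 0")

    def factor_at(self, t: float, mass: str) -> float:
        if t < self.t_pre or t > self.t_post:
            warnings.warn("reading outside the calibration window; using the "
                          "nearest factor", stacklevel=3)
            t = min(max(t, self.t_pre), self.t_post)
        if self.t_post == self.t_pre:
            return self.factor_pre[mass]
        w = (t - self.t_pre) / (self.t_post - self.t_pre)
        return (1 - w) * self.factor_pre[mass] + w * self.factor_post[mass]


def identity_calibration(t_pre: float = 0.0, t_post: float = 60.0) -> CalibrationPair:
    """Unit signal-to-concentration factors (signals already in concentration
    units)."""
    unit = {"32": 1.0, "36": 1.0, "40": 1.0}
    return CalibrationPair(t_pre, t_post, dict(unit), dict(unit))


def drift_correct(reading: IonCurrentReading, cal: CalibrationPair,
                  ar_normalize: bool = True) -> IonCurrentReading:
    """Scale ion currents to concentration units with the time-interpolated
    calibration factor; optionally express O₂ signals as O₂/Ar ratios so a
    common instrument drift cancels."""
    f32 = cal.factor_at(reading.timestamp, "32")
    f36 = cal.factor_at(reading.timestamp, "36")
    f40 = cal.factor_at(reading.timestamp, "40")
    c32 = reading.current_32 / f32
    c36 = reading.current_36 / f36
    c40 = reading.current_40 / f40
    if ar_normalize:
        c32, c36 = c32 / c40, c36 / c40
    return replace(reading, current_32=c32, current_36=c36, current_40=c40)


@dataclass(frozen=True)
class O2Rates:
    """Hourly oxygen fluxes; Net_O2 = GP_O2 − (R_DARK + LDR) by construction."""

    GP_O2: float
    R_DARK: float
    LDR: float
    incubation_min: float = 20.0

    def __post_init__(self) -> None:
        if self.incubation_min <= 0:
            raise ValueError("incubation duration must be > 0")

    @property
    def Net_O2(self) -> float:
        return self.GP_O2 - (self.R_DARK + self.LDR)

    @property
    def flags(self) -> list[str]:
        out = []
        if self.GP_O2 < 0:
            out.append("negative GP_O2")
        if self.LDR < 0:
            out.append("negative LDR")
        if self.R_DARK < 0:
            out.append("negative R_DARK")
        return out


@dataclass(frozen=True)
class OxygenBudget:
    """Oxygen fluxes as percentages of gross production; sums to 100."""

    pct_Net: float
    pct_RDARK: float
    pct_LDR: float


def signals_to_rates(t0: IonCurrentReading, dark: IonCurrentReading,
                     light: IonCurrentReading,
                     duration_min: float = 20.0) -> O2Rates:
    """Two-point rate estimation from drift-corrected T₀/dark/light signals."""
    if duration_min <= 0:
        raise ValueError("duration must be > 0")
    if t0.treatment != "T0" or dark.treatment != "dark":
        raise ValueError("readings must be (T0, dark, light) in that order")
    scale = MIN_PER_H / duration_min
    gp = (light.current_32 - t0.current_32) * scale
    r_dark = (t0.current_36 - dark.current_36) * scale
    u_light = (t0.current_36 - light.current_36) * scale
    ldr = u_light - r_dark
    rates = O2Rates(GP_O2=gp, R_DARK=r_dark, LDR=ldr,
                    incubation_min=duration_min)
    for flag in rates.flags:
        warnings.warn(f"{flag} for vial {light.vial_id}", stacklevel=2)
    return rates


def budget_fractions(rates: O2Rates) -> OxygenBudget:
    """Express Net, R_DARK and LDR as percentages of GP_O2 (sum = 100)."""
    if rates.GP_O2 <= 0:
        raise PhotophysError(
            f"oxygen budget undefined for GP_O2 = {rates.GP_O2} <= 0")
    s = 100.0 / rates.GP_O2
    return OxygenBudget(pct_Net=rates.Net_O2 * s,
                        pct_RDARK=rates.R_DARK * s,
                        pct_LDR=rates.LDR * s)


def cell_normalize(rate_nmol_per_ml_h: float, cells_per_ml: float) -> float:
    """Convert a bulk rate (nmol mL⁻¹ h⁻¹) to pmol cell⁻¹ h⁻¹.

    nmol mL⁻¹ h⁻¹ ÷ (cells mL⁻¹) = nmol cell⁻¹ h⁻¹ × 10³ pmol/nmol.
    """
    if cells_per_ml <= 0:
        raise ValueError("cell density must be > 0")
    return rate_nmol_per_ml_h / cells_per_ml * 1e3
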