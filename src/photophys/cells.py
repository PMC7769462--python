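"""Growth, biomass, pigment-ratio and xanthophyll de-epoxidation bookkeeping.

Specific growth rate μ = ln(N₂/N₁)/(t₂−t₁); net primary production
NPP = μ·C expressed per unit chlorophyll as μmol C (mg Chl h)⁻¹; pigment
pools normalized to Chl a; and the xanthophyll-cycle de-epoxidation state
DPS = Dt/(Dd + Dt), where diadinoxanthin (Dd) is the light-harvesting and
diatoxanthin (Dt) the photo-protective form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CARBON_MOLAR_MASS, H_PER_DAY

__all__ = [
    "CultureSample", "PigmentProfile",
    "growth_rate", "npp", "dps", "pigment_to_chla",
]


@dataclass(frozen=True)
class CultureSample:
    """Cell counts at two times plus per-cell biomass."""

    N1: float  # cells mL⁻¹ at t1
    N2: float  # cells mL⁻¹ at t2
    t1: float  # days
    t2: float  # days
    poc_pg_cell: float = np.nan
    chla_pg_cell: float = np.nan

    def __post_init__(self) -> None:
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("cell concentrations must be > 0")
        if self.t2 <= self.t1:
            raise ValueError("t2 must exceed t1")

    @property
    def mu(self) -> float:
        return growth_rate(self.N1, self.N2, self.t1, self.t2)


@dataclass(frozen=True)
class PigmentProfile:
    """Pigment concentrations (μg mL⁻¹) for one sample/treatment."""

    chla: float
    chlc: float
    fucoxanthin: float
    beta_carotene: float
    Dd: float
    Dt: float
    treatment: str = "Ig"

    def __post_init__(self) -> None:
        vals = (self.chla, self.chlc, self.fucoxanthin, self.beta_carotene,
                self.Dd, self.Dt)
        if any(v < 0 for v in vals):
            raise ValueError("pigment concentrations must be >= 0")
        if self.chla <= 0:
            raise ValueError("Chl a must be > 0 for normalization")


def growth_rate(N1: float, N2: float, t1: float, t2: float) -> float:
    """Specific growth rate μ = ln(N₂/N₁)/(t₂−t₁) in d⁻¹."""
    if N1 <= 0 or N2 <= 0:
        raise ValueError("cell concentrations must be > 0")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return float(np.log(N2 / N1) / (t2 - t1))


def npp(mu_per_d: float, poc_pg_cell: float, chla_pg_cell: float) -> float:
    """Net primary production per unit chlorophyll, μmol C (mg Chl h)⁻¹.

    NPP = μ·C; the unit chain is μ [d⁻¹]/24 → h⁻¹, C/Chl a [pg pg⁻¹ ≡
    mg mg⁻¹], and mg C → μmol C via ×1000/12.011.
    """
    if mu_per_d < 0:
        raise ValueError("growth rate must be >= 0")
    if poc_pg_cell <= 0:
        raise ValueError("cellular carbon must be > 0")
    if chla_pg_cell <= 0:
        raise ValueError("cellular Chl a must be > 0")
    mu_per_h = mu_per_d / H_PER_DAY
    c_to_chl = poc_pg_cell / chla_pg_cell
    return mu_per_h * c_to_chl * 1000.0 / CARBON_MOLAR_MASS


def dps(Dd: float, Dt: float) -> float:
    """Xanthophyll de-epoxidation state Dt/(Dd + Dt) ∈ [0, 1]."""
    if Dd < 0 or Dt < 0:
        raise ValueError("pigment pools must be >= 0")
    if Dd + Dt <= 0:
        raise ValueError("Dd + Dt must be > 0")
    return Dt / (Dd + Dt)


def pigment_to_chla(profile: PigmentProfile) -> pd.Series:
    """Normalize each pigment pool to Chl a (dimensionless ratios) and
    append the de-epoxidation state."""
    return pd.Series(
        {
            "chlc_chla": profile.chlc / profile.chla,
            "fuc_chla": profile.fucoxanthin / profile.chla,
            "bcar_chla": profile.beta_carotene / profile.chla,
            "dd_chla": profile.Dd / profile.chla,
            "dt_chla": profile.Dt / profile.chla,
            "dps": dps(profile.Dd, profile.Dt),
        },
        name=profile.treatment,
    )
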