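"""Partitioning of absorbed excitation energy at PSII over a fluorescence
light curve (FLC).

At every actinic light step the absorbed excitation energy splits into three
yields that sum to one by construction:

    YII  = (F_m′ − F′)/F_m′        photochemical conversion
    YNPQ = F′/F_m′ − F′/F_m        regulated non-photochemical quenching
    YNO  = F′/F_m                  non-regulated losses

together with the (unbounded) Stern–Volmer quenching NPQ = (F_m − F_m′)/F_m′
and the quenching coordinates [1−C] (fraction of open reaction centres) and
[1−Q] (dynamic non-photochemical quenching), whose product equals
YII/(F_v/F_m).  Throughout, F_m is the maximum F_m′ attained over the FLC
(Serôdio convention), which offsets dark plastoquinone-pool reduction.
F₀′ under actinic light is estimated with the Oxborough–Baker formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FLCStep", "DarkReference", "YieldSet",
    "fv_over_fm", "npq_stern_volmer", "ynpq", "yii", "yno",
    "f0_prime", "one_minus_c", "one_minus_q", "partition_flc",
]


@dataclass(frozen=True)
class FLCStep:
    """One step of a fluorescence light curve."""

    irradiance: float  # μmol photons m⁻² s⁻¹
    F_prime: float
    Fm_prime: float
    duration_min: float = 4.0

    def __post_init__(self) -> None:
        if self.irradiance < 0:
            raise ValueError("irradiance must be >= 0")
        if not 0 < self.F_prime <= self.Fm_prime:
            raise ValueError(
                f"require 0 < F' <= Fm' (got F'={self.F_prime}, Fm'={self.Fm_prime})")


@dataclass(frozen=True)
class DarkReference:
    """Dark-regulated reference fluorescence levels."""

    F0: float
    Fm: float

    def __post_init__(self) -> None:
        if not 0 < self.F0 < self.Fm:
            raise ValueError("require 0 < F0 < Fm")

    @property
    def fv_over_fm(self) -> float:
        return fv_over_fm(self.F0, self.Fm)


@dataclass(frozen=True)
class YieldSet:
    """Energy partition and quenching coordinates for one FLC step."""

    irradiance: float
    YII: float
    YNPQ: float
    YNO: float
    NPQ_sv: float
    F0_prime: float
    one_minus_C: float
    one_minus_Q: float
    one_minus_q_flagged: bool  # True where [1−Q] > 1 (chlororespiration signature)


def fv_over_fm(F0: float, Fm: float) -> float:
    """Maximum PSII photochemical efficiency (F_m − F₀)/F_m."""
    if Fm <= 0:
        raise ValueError("Fm must be > 0")
    if not 0 < F0 <= Fm:
        raise ValueError("require 0 < F0 <= Fm")
    return (Fm - F0) / Fm


def npq_stern_volmer(Fm_ref: float, Fm_prime: float) -> float:
    """Stern–Volmer non-photochemical quenching (F_m − F_m′)/F_m′."""
    if Fm_prime <= 0:
        raise ValueError("Fm' must be > 0")
    return (Fm_ref - Fm_prime) / Fm_prime


def ynpq(F_prime: float, Fm_prime: float, Fm_ref: float) -> float:
    """Yield of regulated non-photochemical quenching F′/F_m′ − F′/F_m."""
    _check_ordering(F_prime, Fm_prime, Fm_ref)
    return F_prime / Fm_prime - F_prime / Fm_ref


def yii(F_prime: float, Fm_prime: float) -> float:
    """Yield of PSII photochemistry (F_m′ − F′)/F_m′."""
    if not 0 < F_prime <= Fm_prime:
        raise ValueError(f"require 0 < F' <= Fm' (got {F_prime}, {Fm_prime})")
    return (Fm_prime - F_prime) / Fm_prime


def yno(F_prime: float, Fm_ref: float) -> float:
    """Yield of non-regulated non-photochemical losses F′/F_m."""
    if not 0 < F_prime <= Fm_ref:
        raise ValueError(f"require 0 < F' <= Fm (got {F_prime}, {Fm_ref})")
    return F_prime / Fm_ref


def f0_prime(F0: float, Fv_over_Fm: float, Fm_prime: float) -> float:
    """Oxborough–Baker estimate of the minimal fluorescence under actinic
    light: F₀′ = F₀ / (F_v/F_m + F₀/F_m′)."""
    if min(F0, Fv_over_Fm, Fm_prime) <= 0:
        raise ValueError("all inputs must be > 0")
    denom = Fv_over_Fm + F0 / Fm_prime
    if denom <= 0:  # unreachable under the preconditions; guarded anyway
        raise ZeroDivisionError("degenerate F0' denominator")
    return F0 / denom


def one_minus_c(Fm_prime: float, F_prime: float, F0_prime: float) -> float:
    """Photochemical quenching coordinate (F_m′ − F′)/(F_m′ − F₀′): the
    fraction of open reaction centres."""
    if F0_prime >= Fm_prime:
        raise ValueError("require F0' < Fm'")
    return (Fm_prime - F_prime) / (Fm_prime - F0_prime)


def one_minus_q(Fm_prime: float, F0_prime: float, Fv_over_Fm: float) -> float:
    """Dynamic non-photochemical quenching coordinate
    ((F_m′ − F₀′)/F_m′)/(F_v/F_m).  Values > 1 occur under very low
    light/darkness (chlororespiration) and are retained, not clipped."""
    if min(Fm_prime, F0_prime, Fv_over_Fm) <= 0:
        raise ValueError("all inputs must be > 0")
    return ((Fm_prime - F0_prime) / Fm_prime) / Fv_over_Fm


def _check_ordering(F_prime, Fm_prime, Fm_ref, step_index=None):
    where = "" if step_index is None else f" at step {step_index}"
    if not 0 < F_prime <= Fm_prime:
        raise ValueError(f"require 0 < F' <= Fm'{where} "
                         f"(got F'={F_prime}, Fm'={Fm_prime})")
    if Fm_prime > Fm_ref * (1 + 1e-12):
        raise ValueError(f"require Fm' <= Fm_ref{where} "
                         f"(got Fm'={Fm_prime}, Fm_ref={Fm_ref})")


def partition_flc(steps: Sequence[FLCStep], dark: DarkReference) -> pd.DataFrame:
    """Partition every step of a fluorescence light curve.

    The reference maximal fluorescence F_m is the maximum F_m′ over the whole
    curve, computed before any per-step calculation.  Returns a tidy frame
    with one row per step carrying the full YieldSet; the partition identity
    YII + YNPQ + YNO = 1 holds on every row by construction.
    """
    steps = list(steps)
    if len(steps) < 2:
        raise ValueError("an FLC needs at least 2 steps")
    fm_ref = max(s.Fm_prime for s in steps)
    fvfm = dark.fv_over_fm
    rows = []
    for i, s in enumerate(steps):
        _check_ordering(s.F_prime, s.Fm_prime, fm_ref, step_index=i)
        f0p = f0_prime(dark.F0, fvfm, s.Fm_prime)
        omq = one_minus_q(s.Fm_prime, f0p, fvfm)
        ys = YieldSet(
            irradiance=s.irradiance,
            YII=yii(s.F_prime, s.Fm_prime),
            YNPQ=ynpq(s.F_prime, s.Fm_prime, fm_ref),
            YNO=yno(s.F_prime, fm_ref),
            NPQ_sv=npq_stern_volmer(fm_ref, s.Fm_prime),
            F0_prime=f0p,
            one_minus_C=one_minus_c(s.Fm_prime, s.F_prime, f0p),
            one_minus_Q=omq,
            one_minus_q_flagged=bool(omq > 1.0),
        )
        rows.append({"step_index": i, **ys.__dict__})
    df = pd.DataFrame(rows)
    df.attrs["Fm_ref"] = fm_ref
    df.attrs["Fv_over_Fm"] = fvfm
    return df
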