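"""PSII photoinactivation and repair (Kok damage–repair) kinetics.

High light photoinactivates PSII with first-order rate constant k_PI (s⁻¹),
while chloroplast protein synthesis repairs inactivated centres with rate
constant k_REC (s⁻¹).  Writing A(t) for the active PSII fraction under
piecewise-constant irradiance E(t):

    dA/dt = −σ_I·E(t)·A + k_REC·(1 − A),

where σ_I = k_PI/E is the target cross-section for photoinactivation, which
makes the damage term transferable across light levels.  Within a phase of
constant E the solution is

    A(t) = A_ss + (A₀ − A_ss)·exp(−(k + k_REC)·(t − t₀)),
    k = σ_I·E,   A_ss = k_REC/(k + k_REC),

continuous across phase boundaries.

The experimental design is two-phase: 120 min at 1200 μmol photons m⁻² s⁻¹
then 60 min at 15 μmol photons m⁻² s⁻¹ recovery light.  k_PI is estimated
from lincomycin-treated (repair-blocked, k_REC = 0) decays of dark-relaxed
F_v/F_m; k_REC from repair-active trajectories with σ_I held fixed at the
lincomycin-derived value.  Replicate time courses are pooled into one
residual vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np

from .constants import (HIGH_LIGHT, PHOTONS_NM2_PER_UMOL_M2, RECOVERY_LIGHT,
                        S_PER_MIN)
from .exceptions import FitConvergenceError

__all__ = [
    "LightPhase", "KokParams", "InactivationTimecourse", "RelaxationPair",
    "default_phases", "kok_predict", "sigma_i_from_kpi", "sigma_i_nm2_per_photon",
    "fit_kpi", "fit_krec", "relaxation_amplitude",
    "PhotoinactivationModel", "RepairModel", "KineticsResults",
]


@dataclass(frozen=True)
class LightPhase:
    """A constant-irradiance interval of the treatment protocol."""

    irradiance: float  # μmol photons m⁻² s⁻¹
    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if self.end_min <= self.start_min:
            raise ValueError("phase end must exceed start")
        if self.irradiance < 0:
            raise ValueError("irradiance must be >= 0")


def default_phases(treatment_min: float = 120.0, recovery_min: float = 60.0,
                   e_treatment: float = HIGH_LIGHT,
                   e_recovery: float = RECOVERY_LIGHT) -> tuple[LightPhase, ...]:
    """The study's two-phase protocol: high light then recovery light."""
    return (
        LightPhase(e_treatment, 0.0, treatment_min),
        LightPhase(e_recovery, treatment_min, treatment_min + recovery_min),
    )


@dataclass(frozen=True)
class KokParams:
    """Damage/repair constants.  k_PI refers to the treatment irradiance;
    σ_I = k_PI/E generalizes it across phases."""

    k_pi: float  # s⁻¹ at e_ref
    k_rec: float  # s⁻¹
    e_ref: float = HIGH_LIGHT  # μmol photons m⁻² s⁻¹
    y0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.k_pi, self.k_rec, self.y0) < 0 or self.e_ref <= 0:
            raise ValueError("rate constants and y0 must be >= 0, e_ref > 0")

    @property
    def sigma_i(self) -> float:
        """Photoinactivation target cross-section, (μmol photons m⁻²)⁻¹."""
        return self.k_pi / self.e_ref


@dataclass
class InactivationTimecourse:
    """One replicate's photoinhibition/recovery trajectory.

    ``y`` is the dark-relaxed F_v/F_m series (the damage signal); the
    unrelaxed F_v′/F_m′ series, when present, is carried as annotation only.
    """

    times_min: np.ndarray
    y: np.ndarray
    lincomycin: bool
    replicate_id: str = "r0"
    phases: tuple[LightPhase, ...] = field(default_factory=default_phases)
    y_unrelaxed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.times_min) != len(self.y):
            raise ValueError("times and y must have equal length")
        if np.any(np.diff(self.times_min) < 0):
            raise ValueError("times must be sorted")
        t0, t1 = self.phases[0].start_min, self.phases[-1].end_min
        if np.any(self.times_min < t0 - 1e-9) or np.any(self.times_min > t1 + 1e-9):
            raise ValueError("sample times must be covered by the light phases")


@dataclass(frozen=True)
class RelaxationPair:
    """Immediate vs. dark-relaxed YNPQ after a light exposure."""

    ynpq_immediate: float
    ynpq_after_dark: float

    @property
    def amplitude(self) -> float:
        return self.ynpq_immediate - self.ynpq_after_dark

    @property
    def flagged_negative(self) -> bool:
        return self.amplitude < 0


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def kok_predict(sigma_i: float, k_rec: float,
                phases: Sequence[LightPhase], t_min, y0: float = 1.0):
    """Active PSII fraction A(t) under piecewise-constant irradiance.

    ``t_min`` may be scalar or array (minutes); all times must fall within
    the phases.  Rates are s⁻¹; times are converted internally.
    """
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    if np.any(t < phases[0].start_min - 1e-9) or np.any(t > phases[-1].end_min + 1e-9):
        raise ValueError("t outside the light phases")
    out = np.empty_like(t)
    a_start = float(y0)
    for ph in phases:
        k = sigma_i * ph.irradiance
        ktot = k + k_rec
        mask = (t >= ph.start_min - 1e-9) & (t <= ph.end_min + 1e-9)
        dt_s = (t[mask] - ph.start_min) * S_PER_MIN
        if ktot == 0.0:
            out[mask] = a_start
            a_end = a_start
        else:
            a_ss = k_rec / ktot
            out[mask] = a_ss + (a_start - a_ss) * np.exp(-ktot * dt_s)
            dur_s = (ph.end_min - ph.start_min) * S_PER_MIN
            a_end = a_ss + (a_start - a_ss) * np.exp(-ktot * dur_s)
        a_start = a_end
    return out if np.ndim(t_min) else float(out[0])


def sigma_i_from_kpi(k_pi: float, irradiance: float) -> float:
    """Target cross-section σ_I = k_PI/E in (μmol photons m⁻²)⁻¹."""
    if irradiance <= 0:
        raise ValueError("irradiance must be > 0")
    return k_pi / irradiance


def sigma_i_nm2_per_photon(k_pi: float, irradiance: float) -> float:
    """σ_I expressed as nm² photon⁻¹ via the photon-flux unit constant."""
    if irradiance <= 0:
        raise ValueError("irradiance must be > 0")
    return k_pi / (irradiance * PHOTONS_NM2_PER_UMOL_M2)


def relaxation_amplitude(ynpq_immediate: float, ynpq_after_dark: float) -> RelaxationPair:
    """YNPQ relaxation amplitude over a 10 min dark period; negative
    amplitudes (quenching deepening in the dark) are flagged, not clipped."""
    for v in (ynpq_immediate, ynpq_after_dark):
        if not 0.0 <= v <= 1.0:
            raise ValueError("YNPQ values must lie in [0, 1]")
    pair = RelaxationPair(ynpq_immediate, ynpq_after_dark)
    if pair.flagged_negative:
        warnings.warn("negative YNPQ relaxation amplitude", stacklevel=2)
    return pair


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _pool_normalized(courses: Sequence[InactivationTimecourse]):
    """Concatenate replicate courses, normalized to the pooled t=0 mean."""
    t = np.concatenate([c.times_min for c in courses])
    y = np.concatenate([c.y for c in courses])
    t0 = min(c.times_min[0] for c in courses)
    at_start = y[np.isclose(t, t0)]
    scale = float(np.mean(at_start)) if at_start.size else float(np.mean(y[t == t.min()]))
    if scale <= 0:
        raise ValueError("non-positive amplitude at t=0; cannot normalize")
    return t, y / scale


@dataclass
class KineticsResults:
    """Estimates and diagnostics from a damage/repair kinetics fit."""

    estimates: dict
    stderr: dict
    residual_norm: float
    success: bool
    n_points: int
    n_replicates: int
    label: str

    def summary(self) -> str:
        lines = [f"{self.label}", "=" * len(self.label)]
        for k, v in self.estimates.items():
            se = self.stderr.get(k, np.nan)
            lines.append(f"  {k:10s} {v:12.5g}  (se {se:.3g})")
        lines.append(f"  pooled points {self.n_points} from "
                     f"{self.n_replicates} replicates; "
                     f"residual norm {self.residual_norm:.3g}")
        return "\n".join(lines)


class PhotoinactivationModel:
    """Single-exponential decay fit y(t) = y₀·e^{−k_PI·t} to lincomycin
    (repair-blocked) time courses, pooled across replicates."""

    def __init__(self, courses: Sequence[InactivationTimecourse]):
        courses = list(courses)
        if not courses:
            raise ValueError("no time courses supplied")
        for c in courses:
            if not c.lincomycin:
                raise ValueError(
                    f"replicate {c.replicate_id} is not lincomycin-treated")
            if len(c.times_min) < 3:
                raise ValueError("need >= 3 time points per course")
        e = {c.phases[0].irradiance for c in courses}
        if len(e) > 1:
            raise ValueError("all courses must share the treatment irradiance")
        self.courses = courses
        self.irradiance = e.pop()

    def fit(self) -> KineticsResults:
        t_min, y = _pool_normalized(self.courses)
        t_s = t_min * S_PER_MIN
        slope = np.polyfit(t_s, np.log(np.clip(y, 1e-12, None)), 1)[0]
        if slope > 0:
            warnings.warn("fluorescence increases over time; k_PI fit may be "
                          "meaningless", stacklevel=2)
        pars = lmfit.Parameters()
        pars.add("y0", value=1.0, min=0.8, max=1.2)
        pars.add("k_pi", value=max(-slope, 1e-8), min=0.0)

        def resid(p):
            v = p.valuesdict()
            return v["y0"] * np.exp(-v["k_pi"] * t_s) - y

        out = lmfit.minimize(resid, pars, method="least_squares",
                     ftol=1e-14, xtol=1e-14, gtol=1e-14)
        if not out.success:
            raise FitConvergenceError(f"k_PI fit failed: {out.message}")
        v = out.params.valuesdict()
        return KineticsResults(
            estimates={"k_pi": v["k_pi"], "y0": v["y0"],
                       "sigma_i": sigma_i_from_kpi(v["k_pi"], self.irradiance)},
            stderr={"k_pi": out.params["k_pi"].stderr or np.nan,
                    "y0": out.params["y0"].stderr or np.nan},
            residual_norm=float(np.sqrt(np.sum(out.residual ** 2))),
            success=True, n_points=len(y), n_replicates=len(self.courses),
            label="PSII photoinactivation (lincomycin) fit",
        )


class RepairModel:
    """Kok damage–repair fit of repair-active trajectories with σ_I fixed.

    Only k_REC (and the normalized initial amplitude y₀ ∈ [0.8, 1.2]) vary.
    Deterministic multi-start (3 starts log-spaced over [1e-5, 1e-2] s⁻¹)
    guards against local minima.
    """

    _starts = (1e-5, 3.16e-4, 1e-2)

    def __init__(self, courses: Sequence[InactivationTimecourse], sigma_i: float):
        courses = list(courses)
        if not courses:
            raise ValueError("no time courses supplied")
        for c in courses:
            if c.lincomycin:
                raise ValueError(
                    f"replicate {c.replicate_id} is lincomycin-treated")
        phases = courses[0].phases
        for c in courses:
            if c.phases != phases:
                raise ValueError("all courses must share the light phases")
        if len(phases) > 1:
            t_rec = phases[-1].start_min
            if not any(np.any(c.times_min > t_rec) for c in courses):
                warnings.warn("no recovery-phase points: k_REC is weakly "
                              "identified", stacklevel=2)
        if sigma_i < 0:
            raise ValueError("sigma_i must be >= 0")
        self.courses = courses
        self.sigma_i = sigma_i
        self.phases = phases

    def fit(self) -> KineticsResults:
        t_min, y = _pool_normalized(self.courses)

        def resid(p):
            v = p.valuesdict()
            return kok_predict(self.sigma_i, v["k_rec"], self.phases,
                               t_min, y0=v["y0"]) - y

        best = None
        for start in self._starts:
            pars = lmfit.Parameters()
            pars.add("y0", value=1.0, min=0.8, max=1.2)
            pars.add("k_rec", value=start, min=0.0, max=1.0)
            out = lmfit.minimize(resid, pars, method="least_squares",
                     ftol=1e-14, xtol=1e-14, gtol=1e-14)
            if out.success and (best is None or out.chisqr < best.chisqr):
                best = out
        if best is None:
            raise FitConvergenceError("k_REC fit failed from every start")
        v = best.params.valuesdict()
        return KineticsResults(
            estimates={"k_rec": v["k_rec"], "y0": v["y0"]},
            stderr={"k_rec": best.params["k_rec"].stderr or np.nan,
                    "y0": best.params["y0"].stderr or np.nan},
            residual_norm=float(np.sqrt(np.sum(best.residual ** 2))),
            success=True, n_points=len(y), n_replicates=len(self.courses),
            label="PSII repair (Kok damage-repair) fit",
        )


def fit_kpi(courses: Sequence[InactivationTimecourse]) -> KineticsResults:
    """Fit k_PI from pooled lincomycin decays (functional wrapper)."""
    return PhotoinactivationModel(courses).fit()


def fit_krec(courses: Sequence[InactivationTimecourse],
             sigma_i: float) -> KineticsResults:
    """Fit k_REC from pooled repair-active trajectories with σ_I fixed."""
    return RepairModel(courses, sigma_i).fit()
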