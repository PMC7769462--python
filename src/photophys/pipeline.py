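"""End-to-end orchestration: run every configured stage and assemble a
study report (per-species derived tables, kinetic constants, yield
partitions, oxygen budgets and the combined energy-allocation stack)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cells import PigmentProfile, growth_rate, npp, pigment_to_chla
from .constants import GROWTH_IRRADIANCE, HIGH_LIGHT, RECOVERY_LIGHT
from .exceptions import PhotophysError
from .kok import default_phases, fit_kpi, fit_krec
from .mims import (OxygenBudget, budget_fractions, drift_correct,
                   identity_calibration, signals_to_rates)
from .sturnover import STProtocol, fit_transient
from .yields import DarkReference, partition_flc

log = logging.getLogger("photophys")

__all__ = ["RunConfig", "StudyReport", "run_pipeline", "energy_stack",
           "PipelineStageError"]


class PipelineStageError(PhotophysError):
    """A stage failed; the message names the stage and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {detail}")


@dataclass
class RunConfig:
    """Input paths and run parameters.  Any path may be None: missing stages
    are skipped and the report carries explicit gaps."""

    transient_csv: str | None = None
    flc_csv: str | None = None
    timecourse_csv: str | None = None
    mims_csv: str | None = None
    culture_csv: str | None = None
    pigment_csv: str | None = None
    species: str = "unspecified"
    growth_irradiance: float = GROWTH_IRRADIANCE
    high_light: float = HIGH_LIGHT
    recovery_light: float = RECOVERY_LIGHT
    treatment_min: float = 120.0
    recovery_min: float = 60.0
    mims_duration_min: float = 20.0
    ar_normalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("growth_irradiance", "high_light", "recovery_light"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("transient_csv", "flc_csv", "timecourse_csv",
                     "mims_csv", "culture_csv", "pigment_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """Per-stage tidy tables; every row carries a provenance column naming
    the input it came from."""

    transient_fit: pd.DataFrame | None = None
    yields: pd.DataFrame | None = None
    kinetics: pd.DataFrame | None = None
    oxygen: pd.DataFrame | None = None
    cell_metrics: pd.DataFrame | None = None
    pigments: pd.DataFrame | None = None
    energy: pd.DataFrame | None = None
    gaps: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {k: v for k, v in vars(self).items()
                if isinstance(v, pd.DataFrame)}

    def write(self, out_dir, fmt: str = "csv") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self.tables().items():
            p = out_dir / f"{name}.{fmt}"
            if fmt == "json":
                df.to_json(p, orient="records", indent=2)
            else:
                df.to_csv(p, index=False)
            written.append(p)
        meta = {**self.meta, "gaps": self.gaps}
        p = out_dir / "report_meta.json"
        p.write_text(json.dumps(meta, indent=2, default=str))
        written.append(p)
        return written


def energy_stack(yset, budget: OxygenBudget | None) -> pd.Series:
    """Subdivide YII by the oxygen-budget fractions (YII taken as directly
    proportional to GP_O2): the full stack sums to 1.  With an undefined
    budget YII is left unsubdivided and flagged."""
    y2, ynpq_v, yno_v = yset["YII"], yset["YNPQ"], yset["YNO"]
    if abs(y2 + ynpq_v + yno_v - 1.0) > 1e-9:
        raise ValueError("yield partition does not sum to 1")
    if budget is None:
        return pd.Series({"YNPQ": ynpq_v, "YNO": yno_v, "YII": y2,
                          "YII_subdivided": False})
    total = budget.pct_Net + budget.pct_RDARK + budget.pct_LDR
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"budget fractions sum to {total}, not 100")
    return pd.Series({
        "YNPQ": ynpq_v, "YNO": yno_v,
        "YII_Net": y2 * budget.pct_Net / 100.0,
        "YII_RDARK": y2 * budget.pct_RDARK / 100.0,
        "YII_LDR": y2 * budget.pct_LDR / 100.0,
        "YII_subdivided": True,
    })


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 — annotate with stage name
                raise PipelineStageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("fit-transient")
def _run_transient(cfg: RunConfig) -> pd.DataFrame:
    tr, dose = pio.read_transient_csv(cfg.transient_csv)
    n_ind = int(np.sum(tr.induction_mask))
    n_rel = len(tr.times) - n_ind
    protocol = STProtocol(n_induction_flashlets=n_ind,
                          n_relaxation_flashlets=max(n_rel, 1),
                          flashlet_dose=dose)
    res = fit_transient(tr, protocol)
    p = res.params
    return pd.DataFrame([{
        "species": cfg.species, "F0": p.F0, "Fm": p.Fm,
        "sigma_psii_nm2": p.sigma_psii, "tau_us": p.tau, "p": p.p,
        "fv_fm": res.fv_fm, "residual_norm": res.residual_norm,
        "converged": res.success, "provenance": str(cfg.transient_csv),
    }])


@_stage("partition-flc")
def _run_flc(cfg: RunConfig) -> pd.DataFrame:
    steps = pio.read_flc_csv(cfg.flc_csv)
    dark_steps = [s for s in steps if s.irradiance == 0]
    if not dark_steps:
        raise ValueError("FLC has no dark (E=0) step to supply F0")
    f0 = dark_steps[0].F_prime
    fm = max(s.Fm_prime for s in steps)
    df = partition_flc(steps, DarkReference(F0=f0, Fm=fm))
    df["species"] = cfg.species
    df["provenance"] = str(cfg.flc_csv)
    return df


@_stage("fit-kinetics")
def _run_kinetics(cfg: RunConfig) -> pd.DataFrame:
    phases = default_phases(cfg.treatment_min, cfg.recovery_min,
                            cfg.high_light, cfg.recovery_light)
    courses = pio.read_timecourse_csv(cfg.timecourse_csv, phases)
    linco = [c for c in courses if c.lincomycin]
    ctrl = [c for c in courses if not c.lincomycin]
    rows = []
    sigma_i = None
    if linco:
        r = fit_kpi(linco)
        sigma_i = r.estimates["sigma_i"]
        rows.append({"species": cfg.species, "parameter": "k_pi",
                     "estimate": r.estimates["k_pi"],
                     "stderr": r.stderr["k_pi"], "units": "s-1",
                     "n_replicates": r.n_replicates,
                     "provenance": str(cfg.timecourse_csv)})
        rows.append({"species": cfg.species, "parameter": "sigma_i",
                     "estimate": sigma_i, "stderr": np.nan,
                     "units": "(umol photons m-2)-1",
                     "n_replicates": r.n_replicates,
                     "provenance": str(cfg.timecourse_csv)})
    if ctrl and sigma_i is not None:
        r = fit_krec(ctrl, sigma_i)
        rows.append({"species": cfg.species, "parameter": "k_rec",
                     "estimate": r.estimates["k_rec"],
                     "stderr": r.stderr["k_rec"], "units": "s-1",
                     "n_replicates": r.n_replicates,
                     "provenance": str(cfg.timecourse_csv)})
    if not rows:
        raise ValueError("no usable time courses (need lincomycin decays; "
                         "repair fits additionally need control courses)")
    return pd.DataFrame(rows)


@_stage("mims-budget")
def _run_mims(cfg: RunConfig) -> pd.DataFrame:
    readings = pio.read_mims_csv(cfg.mims_csv)
    cal = identity_calibration(
        t_pre=min(r.timestamp for r in readings),
        t_post=max(r.timestamp for r in readings))
    corr = {r.treatment: drift_correct(r, cal, ar_normalize=cfg.ar_normalize)
            for r in readings}
    if "T0" not in corr or "dark" not in corr:
        raise ValueError("MIMS set needs T0 and dark vials")
    rows = []
    for treat in ("Ig", "HL"):
        if treat not in corr:
            continue
        rates = signals_to_rates(corr["T0"], corr["dark"], corr[treat],
                                 duration_min=cfg.mims_duration_min)
        row = {"species": cfg.species, "treatment": treat,
               "GP_O2": rates.GP_O2, "R_DARK": rates.R_DARK,
               "LDR": rates.LDR, "Net_O2": rates.Net_O2,
               "flags": ";".join(rates.flags),
               "provenance": str(cfg.mims_csv)}
        if rates.GP_O2 > 0:
            b = budget_fractions(rates)
            row.update({"pct_Net": b.pct_Net, "pct_RDARK": b.pct_RDARK,
                        "pct_LDR": b.pct_LDR})
        rows.append(row)
    if not rows:
        raise ValueError("MIMS set has no light (Ig/HL) vials")
    return pd.DataFrame(rows)


@_stage("cell-metrics")
def _run_cells(cfg: RunConfig) -> pd.DataFrame:
    df = pio.read_culture_csv(cfg.culture_csv)
    rows = []
    for sid, g in df.groupby("sample_id"):
        g = g.sort_values("t_day")
        if len(g) < 2:
            raise ValueError(f"sample {sid}: need >= 2 time points")
        first, last = g.iloc[0], g.iloc[-1]
        mu = growth_rate(first.cells_per_ml, last.cells_per_ml,
                         first.t_day, last.t_day)
        rows.append({
            "sample_id": sid, "species": last.get("species", cfg.species),
            "mu_per_d": mu,
            "npp_umolC_mgchl_h": npp(mu, last.poc_pg_cell, last.chla_pg_cell),
            "provenance": str(cfg.culture_csv),
        })
    return pd.DataFrame(rows)


@_stage("pigments")
def _run_pigments(cfg: RunConfig) -> pd.DataFrame:
    df = pio.read_pigment_csv(cfg.pigment_csv)
    rows = []
    for r in df.itertuples():
        prof = PigmentProfile(chla=r.chla, chlc=r.chlc, fucoxanthin=r.fuc,
                              beta_carotene=r.bcar, Dd=r.dd, Dt=r.dt,
                              treatment=str(r.treatment))
        s = pigment_to_chla(prof)
        rows.append({"sample_id": r.sample_id, "treatment": r.treatment,
                     **s.to_dict(), "provenance": str(cfg.pigment_csv)})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute every stage whose input is configured, in dependency order.

    Missing inputs leave explicit gaps in the report rather than failing;
    stage errors propagate as :class:`PipelineStageError`.
    """
    report = StudyReport(meta={"species": config.species,
                               "config_digest": config.digest(),
                               "seed": config.seed})
    log.info("pipeline start: species=%s digest=%s", config.species,
             config.digest())
    stage_map = {
        "transient_fit": (config.transient_csv, _run_transient),
        "yields": (config.flc_csv, _run_flc),
        "kinetics": (config.timecourse_csv, _run_kinetics),
        "oxygen": (config.mims_csv, _run_mims),
        "cell_metrics": (config.culture_csv, _run_cells),
        "pigments": (config.pigment_csv, _run_pigments),
    }
    for name, (path, fn) in stage_map.items():
        if path is None:
            report.gaps.append(name)
            continue
        setattr(report, name, fn(config))
        log.info("stage %s: %d rows", name, len(getattr(report, name)))
    # combined energy stack: highest-irradiance FLC step × HL oxygen budget
    if report.yields is not None:
        ys = report.yields.sort_values("irradiance").iloc[-1]
        budget = None
        if report.oxygen is not None and "pct_LDR" in report.oxygen.columns:
            hl = report.oxygen[report.oxygen["treatment"] == "HL"]
            if len(hl):
                r = hl.iloc[0]
                budget = OxygenBudget(pct_Net=r.pct_Net,
                                      pct_RDARK=r.pct_RDARK,
                                      pct_LDR=r.pct_LDR)
        stack = energy_stack(ys, budget)
        stack["species"] = config.species
        stack["provenance"] = "yields+oxygen"
        report.energy = stack.to_frame().T
    else:
        report.gaps.append("energy")
    return report
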