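# photophys

Analysis pipeline for diatom photophysiology: how phytoplankton balance
light harvesting, photoprotection, photosystem II (PSII) damage/repair and
downstream oxygen consumption when light shifts from moderate to excess.
It is written for researchers working with fast repetition rate fluorometry
(FRRf) and membrane-inlet mass spectrometry (MIMS) data from phytoplankton
cultures — in particular the *Thalassiosira* species whose reference
parameters ship with the package — and for anyone who needs a tested,
seeded synthetic-data stand-in for those instruments.

## What it computes

**Single-turnover fluorescence transients** (`photophys.sturnover`).
A flashlet train closes PSII reaction centres; with C the closed fraction,
per-flashlet excitation dose Φ (photons nm⁻²), cross-section σ_PSII
(nm² PSII⁻¹) and connectivity p,

    dC/dΦ = σ_PSII (1 − C)/(1 − pC),
    f(C) = F₀ + (F_m − F₀) · C(1 − p)/(1 − pC),

with exponential re-opening (lifetime τ, μs) between relaxation flashlets.
`SingleTurnoverModel(transient, protocol).fit()` returns F₀, F_m, σ_PSII, τ
with standard errors and a `summary()`.

**Excitation-energy partition over a fluorescence light curve**
(`photophys.yields`). At each actinic step: YII = (F_m′−F′)/F_m′,
YNPQ = F′/F_m′ − F′/F_m, YNO = F′/F_m (summing to 1 by construction), the
Stern–Volmer NPQ, the Oxborough–Baker F₀′, and the quenching coordinates
[1−C] and [1−Q] whose product equals YII/(F_v/F_m).  F_m is the maximum
F_m′ over the curve.

**PSII damage–repair kinetics** (`photophys.kok`). The active-fraction
balance dA/dt = −σ_I E(t) A + k_REC (1−A) over a two-phase protocol
(120 min at 1200, then 60 min at 15 μmol photons m⁻² s⁻¹).  k_PI comes from
lincomycin (repair-blocked) decays, σ_I = k_PI/E transfers it across light
levels, and k_REC is fitted with σ_I held fixed, replicates pooled.

**¹⁸O₂ oxygen budgets** (`photophys.mims`). Ion currents at m/z 32/36/40
from T₀/dark/light vials give gross production (GP_O2), dark respiration
(R_DARK), light-dependent respiration (LDR) and net production, plus their
percentages of GP_O2 (which sum to 100 exactly).

**Cell metrics** (`photophys.cells`): growth rate μ = ln(N₂/N₁)/Δt,
chlorophyll-normalized net primary production NPP = μ·C, pigment:Chl *a*
ratios and the xanthophyll de-epoxidation state DPS = Dt/(Dd+Dt).

**Synthetic generators** (`photophys.synthetic`): seeded, exact
right-inverses of every stage at zero noise, with `SyntheticTruth` sidecars.
`photophys.pipeline.run_pipeline` orchestrates all stages from CSV inputs,
and the `photophys` CLI exposes `simulate`, `fit-transient`,
`partition-flc`, `fit-kinetics`, `mims-budget`, `cell-metrics`, `report`
and `make-fixtures`.

## Worked example

```python
from photophys import STProtocol, fit_transient
from photophys.synthetic import gen_st_transient, st_params_for_species

protocol = STProtocol()                       # 100 + 40 flashlet protocol
truth = st_params_for_species("T_oceanica")   # sigma 3.98 nm2, Fv/Fm 0.55
transient, _ = gen_st_transient(truth, protocol, noise_cv=0.01, seed=42)
print(fit_transient(transient, protocol).summary())
```

```
Single-turnover transient fit
=============================
  F0                 0.44977  (se 0.000644)
  Fm                 0.99998  (se 0.000325)
  sigma_PSII          3.9791  nm2 PSII-1  (se 0.0101)
  tau                  799.8  us  (se 1.78)
  p                        0  (fixed)
  Fv/Fm              0.55022
  residual norm     0.016227   nfev 26
```

Under 1 % per-flashlet noise averaged over 40 sequences, the fitted
cross-section (3.979 nm² PSII⁻¹) and F_v/F_m (0.550) sit within a fraction
of a percent of the generating values — the oceanic species' reference
cross-section of 3.98 nm² and photochemical efficiency of 0.55.  The same
round-trip pattern holds for the kinetics: a repair-active trajectory
simulated with the coastal species' constants refits k_REC = 1.50×10⁻³ s⁻¹
with zero residual.

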