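# Methods

## Single-turnover transient model

The forward model treats each acquisition as a train of discrete excitation
flashlets acting on the closed fraction C of PSII reaction centres.  Within
one flashlet of dose Φ (photons nm⁻²) the closure equation
dC/dΦ = σ_PSII(1−C)/(1−pC) is integrated exactly: the implicit solution
p·ΔC − (1−p)·Δln(1−C) = σΦ has a Lambert-W closed form, reducing at p = 0
to C′ = 1 − (1−C)e^{−σΦ}.  Exact within-flashlet integration (rather than a
first-order Euler step) makes the simulated induction agree with the
continuous closed form 1 − exp(−σ·D) at any per-flashlet dose, so the
discretization never biases σ_PSII.  Fluorescence is evaluated at the
end-of-flashlet closure (times are labelled at flashlet midpoints); with a
1 μs flash this distinction is far below instrument resolution.

Re-opening during the 3 μs induction pitch is neglected (τ is hundreds of
μs); during the relaxation train closure decays by e^{−Δt/τ} per 51 μs
pitch before each probe dose is applied.  A single re-opening lifetime is
used; multi-component relaxation is out of scope.

Defaults mirror the standard FastOcean acquisition: 100 induction flashlets
(1 μs flash / 2 μs gap), 40 relaxation flashlets (50 μs gap), 40 sequences
averaged per acquisition, 150 ms apart.  Sequences are assumed fully
relaxed at their start (the 150 ms interval is ≫ τ), so sequence averaging
matters only under noise and is performed in the synthetic generator
(arithmetic mean of per-sequence traces before fitting).  The per-flashlet
dose defaults to 0.01 photons nm⁻², which saturates closure (σ·D ≈ 2–4)
over the induction train for cross-sections in the 2–4 nm² range typical of
diatoms.  The irradiance↔photon-dose conversion (1 μmol photons m⁻² s⁻¹ =
6.022×10⁻⁴ photons nm⁻² s⁻¹) lives in `photophys.constants`.

Fitting is unweighted nonlinear least squares (Levenberg–Marquardt via
lmfit) over the concatenated induction+relaxation trace with F₀, F_m,
σ_PSII and τ free.  Connectivity p is fixed at 0 by default and can be
freed or fixed elsewhere: a single transient constrains p weakly, and all
derived quantities are reproducible under any convention applied
consistently to simulation and fit.  Initial values come from the trace
(min/max fluorescence, a log-slope estimate of σ); flat traces raise an
explicit "unresolvable" error rather than returning garbage, and
non-convergence raises with the optimizer message.

## Yield partition

The reference F_m for the Stern–Volmer and yield equations is the maximum
F_m′ attained across the light curve, not the dark F_m; this offsets
fluorescence lowering from dark plastoquinone-pool reduction.  The same
reference is used in every equation that contains F_m.  [1−Q] can exceed 1
under darkness/very low light (chlororespiration); such values are flagged
in the output and never clipped.  Yields are kept at full precision
internally.  YII + YNPQ + YNO = 1 and [1−C]·[1−Q] = YII/(F_v/F_m) are
algebraic identities and are enforced as such in the test suite.

## Damage–repair kinetics

The Kok-style balance dA/dt = −σ_I E(t) A + k_REC (1−A) is solved in closed
form on piecewise-constant irradiance, continuous across phase boundaries;
the test suite checks it against direct ODE integration to 1e−8.  The
fitting target is the dark-relaxed F_v/F_m series (measured after 10 min
darkness), normalized to the pooled t = 0 mean, so non-photochemical
quenching transients do not contaminate the damage signal; unrelaxed
F_v′/F_m′ series are carried as annotation only.  Time is seconds
internally, minutes at I/O.

k_PI is fitted as a plain exponential decay on lincomycin-treated
(repair-blocked) courses pooled across replicates; σ_I = k_PI/E then fixes
the damage term in the repair fit, where only k_REC and a normalized
initial amplitude y₀ ∈ [0.8, 1.2] vary.  The y₀ bound absorbs first-point
noise without letting amplitude trade against rate.  Both fits use bounded
trust-region least squares with tight (1e−14) convergence tolerances; the
repair fit runs a deterministic 3-point multi-start log-spaced over
[1e−5, 1e−2] s⁻¹ to avoid local minima.  Recovery-phase damage is not
neglected: the model applies σ_I·15 during the low-light phase.

## Oxygen budgets

Rates are two-point estimates (T₀ vs a 20 min endpoint) because the study
design uses discrete, not continuous, MIMS sampling; such rates are known
conservative underestimates and are reported as-is.  Ar normalization
(O₂/Ar ratios) is on by default so a common instrument gain drift cancels;
raw mode is available.  Calibration factors are interpolated linearly
between bracketing standards; readings outside the window fall back to the
nearest factor with a warning.  Negative GP or LDR values are preserved and
flagged — filtering is a reporting decision, not a silent one.  No
isotope-dilution back-correction is applied to the ¹⁶O₂ signal.

## Cell metrics

DPS is computed as Dt/(Dd+Dt), the form consistent with the reference
de-epoxidation values bundled here.  Per-replicate quantities (NPP, DPS)
are computed first and averaged afterwards (mean-of-ratios); the
ratio-of-means alternative can be assembled from the same primitives.
NPP converts μ (d⁻¹) to h⁻¹ and carbon mass to moles (12.011 g mol⁻¹),
yielding μmol C (mg Chl h)⁻¹.

## Synthetic generators

Each generator emulates one input class with known ground truth and is an
exact right-inverse of its analysis stage at zero noise: the transient
generator is the forward model plus per-flashlet multiplicative Gaussian
noise averaged over sequences; the light-curve generator inverts the yield
equations (F′ = YNO·F_m, F_m′ = F′/(1−YII)) and rejects infeasible target
triples by naming the violated constraint; the time-course generator scales
the active fraction by a pre-treatment F_v/F_m (default 0.55); the MIMS
generator constructs endpoint O₂/Ar ratios from a prescribed rate triple.
Noise is multiplicative Gaussian because fluorescence and ion-current noise
are approximately proportional to signal; no instrument artifact shapes
(electrode drift, flashlet jitter) are emulated, so passing recovery tests
demonstrates estimator correctness under well-behaved noise, not robustness
to structured artifacts in real records.

Default generating parameters are the bundled reference tables for the
three *Thalassiosira* species (growth, pigments, fluorescence
cross-sections, damage/repair constants, budget fractions) in
`photophys.constants`.  The default sampling grids are the study protocols:
4 time points (0/30/60/120 min) for lincomycin decays, 6 (adding
150/180 min recovery) for repair fits, 20 min MIMS incubations.  Noise
studies in the test suite use 10–200 seeded replicates per condition —
sizes at which the medians under test are stable.

## Pipeline

`run_pipeline` executes whichever stages have inputs configured and leaves
explicit gaps otherwise; every output row carries a provenance column.  The
energy-allocation stack subdivides YII proportionally by the oxygen-budget
fractions, resting on the premise that YII is directly proportional to
GP_O2; with an undefined budget (GP ≤ 0) YII is left whole and flagged.
Reports regenerate byte-identically from identical config and inputs; the
only randomness anywhere is the config seed consumed by the generators.

## Known limitations

- Connectivity p and τ identifiability degrade at low per-flashlet dose or
  coarse relaxation sampling; the defaults avoid both regimes.
- The repair fit assumes primary photoinactivation is identical with and
  without lincomycin, and that σ_I measured at 1200 applies at 15 μmol
  photons m⁻² s⁻¹.
- Oxygen budgets do not attribute LDR to specific O₂-consuming pathways
  (Mehler, PTOX, mitochondrial), and two-point rates underestimate truth.
- Inferential statistics (ANOVA-style species comparisons) are outside the
  package's scope.
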