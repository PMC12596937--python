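# Methods

This note documents the model formulation, the numerical choices, the
provenance of every shipped parameter, and the limits of what the bundled
synthetic scenarios demonstrate.

## 1. Ionic speciation

**Formulation.** The solution state is described by conserved analytical
totals of each moiety (Mg, the four NTPs, the AG cap analog, phosphate,
pyrophosphate, tris, acetate) plus spectator ions (Na⁺, Cl⁻, strong-base
equivalents from NaOH, and RNA backbone phosphodiesters at −1 charge each).
Species form from free components by mass action,
`c_j = β_j Π_k x_k^(s_jk)`; one mass balance is written per moiety and the
proton is fixed by electroneutrality.  Totals follow the *acid-form
convention*: they refer to the fully deprotonated species, with counterions
supplied explicitly.  A disodium NTP stock therefore appears as
NTP⁴⁻ + 2 Na⁺, and bringing a recipe to its working pH is an explicit
titration step (`titrate_to_ph`), exactly as at the bench.

A consequence worth stating: transcription bookkeeping converts one NTP
moiety (reference charge −4) into one backbone phosphodiester (−1) plus two
orthophosphates (reference −3 each).  Re-solving the charge balance after
this transformation *is* the proton bookkeeping — the pH of a progressing
reaction falls without any explicit acid-equivalents counter.  An
`extra_proton_stoich` parameter (default 0) is available for stoichiometries
beyond this baseline.

**Numerics.** Concentrations span well over ten orders of magnitude, so the
solver works in log10-concentration space: a damped Newton iteration with
the analytic Jacobian `J_kl = ln10 Σ_j s_jk s_jl c_j` (warm-started from the
previous ODE step, typically 2–5 iterations), backed by a robust nested 1-D
path for cold starts and failures — an outer Brent root on the charge
balance in pH ∈ [−2, 16] with, per pH, an inner Brent root on the Mg balance
(ligand frees are closed-form given H and Mg).  Residual tolerances:
≤10⁻⁸ relative per-moiety mass balance and charge balance (the suite
verifies ~10⁻¹⁵ in practice over 1000 randomized compositions).
Activities are identified with concentrations (ideal solution); a
Davies-type correction would enter as per-species activity coefficients in
the compiled system but is not implemented.

**Equilibrium constants** (`data/equilibrium_constants.yaml`, 25 °C, from
standard critically evaluated stability-constant compilations; ATP-like
values shared across the four NTPs and the cap analog): NTP protonation
log K 6.51 / 4.05; phosphate 12.375 / 7.198 / 2.148; pyrophosphate
9.40 / 6.68; tris 8.07; acetate 4.757; log Kw −13.997; Mg·NTP²⁻ 4.22,
Mg·HNTP⁻ 2.32, MgHPO₄ 2.71, Mg·PPi²⁻ 5.42.  The temperature field is
carried but no van 't Hoff correction is applied (documented limitation).

**Effective-salt weights ω.** The weighted-complex-sum form requires an ω
per species.  The shipped defaults were set once to respect the
experimentally established qualitative ordering — chloride-bearing species
disrupt polymerase–promoter binding more than acetate-bearing ones, and
free Mg²⁺ is strongly disruptive — and to put typical reaction mixes in a
plausible 50–200 mM effective-salt window: Na⁺ = Cl⁻ = 1.0, Ac⁻ = 0.4,
trisH⁺ = 0.6, Mg²⁺ = 3.0, NTP⁴⁻ = 2.0 grading down with protonation/Mg
complexation to 0.8–1.5, phosphates 0.6–1.5, neutral species 0, RNA
backbone 0 (condensed counterions).  They are configuration, not
measurement: all are overridable in the constants file.

**Solubility product.** σ = ln([Mg²⁺]³[PO₄³⁻]²/Ksp) with log₁₀ Ksp = −28.0
for the anhydrous magnesium phosphate polymorph.  Literature values for
Mg₃(PO₄)₂ phases span roughly 10⁻²³ (hydrated, 22 H₂O) to well below
10⁻²⁵ (8 H₂O) with the anhydrous phase the least soluble; the shipped value
sits at the insoluble end of that spread and was fixed together with the
scenario reconstructions (§6).  σ is a driving force only — no
crystallization kinetics or precipitation mass sink is modeled, so
predicted σ trajectories assume no solid has yet formed.

## 2. Transcription kinetics

`r = k_cat [DNA] f_occ Γ_pH Π_i S(Mg·NTPᵢ)`, with

- `f_occ`: equilibrium promoter occupancy from exact two-species binding
  (DNA, polymerase, K_d = k_off/k_on) with depletion;
  `k_off = k_off,1M [salt]^n_salt`.
- `Γ_pH = (1 + [H⁺]/K_a + K_b/[H⁺])⁻¹`, maximal at [H⁺] = √(K_a K_b).
- `S(c) = c/(K_M + c)` in the *free Mg·NTP complex* of each base — excess
  free Mg²⁺ therefore hurts through the salt channel while the saturation
  terms stay full, reproducing the observed high-Mg rate drop.

| parameter | default | units | rationale |
|---|---|---|---|
| k_off,1M | 10^2.93 (ordinary), 10^3.93 (salt-sensitive construct) | s⁻¹ | detachment scales at 1 M effective salt; the two printed values |
| n_salt | 5.0 | – | counterion-condensation-style power law for protein–DNA dissociation (typical 4–8); S-table value unavailable |
| k_on | 4×10⁷ | M⁻¹s⁻¹ | facilitated-diffusion protein–promoter association (10⁷–10⁸) |
| k_cat | 0.25 | s⁻¹ | full-length 4.4-knt transcripts per occupied promoter (≈1100 nt/s elongation-equivalent across initiations) |
| K_M | 0.2 | mM Mg·NTP | shared across bases (not separately identifiable) |
| K_a, K_b | 10⁻⁷, 10⁻⁹ | M | Γ_pH maximal at pH 8, Γ(8) = 0.83 |

The lumped single-expression rate law stands in for an explicit
initiation/elongation chain; it is isolated behind the
`transcription_rate` contract so a multi-state scheme can replace it
without touching other modules.  Pyrophosphatase is treated as
instantaneous (PPi → 2 Pi, no accumulation), and no polymerase
deactivation term is included (relevant only for residence times beyond
the horizons simulated here).

## 3. Capping competition

`CFᵢ = cap/(cap + λ·ATP·GTP/(1 + GTP/θ))`.  The denominator term is
`(1 + GTP/θ)` — θ carries concentration units (reported in mM), which is
the only dimensionally consistent reading, and makes the competing flux
commensurate with [cap].  The six elementary initiation rate constants are
retained only through the identifiable composites λ = k₁/(k₄θ) and
θ = k₋₁(k₃+k₋₂)/(k₂k₃).

Cumulative capping integrates d(capped)/dt = CFᵢ·r with one cap analog
consumed per capped transcript; inside the reactor ODE this shares the
state vector and stepper with everything else.  A standalone
`batch_cap_fraction` integrates in reaction extent ξ (ATP and GTP fall
linearly in ξ; the clock is irrelevant to CF), to `conversion` × the extent
of limiting-pool exhaustion (default 1.0).

**Initial parameter estimates.** The two-condition inversion of the
instantaneous formula at the calibration table's predicted cap fractions
(0.48 at ATP/GTP/cap = 3.6/7/0.3 mM; 0.50 at 2/0.25/0.05 mM) gives
λ = 133.4 M⁻¹, θ = 0.75 mM — inside the published 25–150 M⁻¹ and
0.5–20 mM ranges.  These serve as the shipped starting estimates wherever
initial values are needed.

**Instantaneous vs batch-integrated prediction.** The predicted CFs of the
calibration table are reproduced exactly by the instantaneous formula at
t = 0 and *not* by batch integration (which yields ≈0.69/0.68 at those
conditions, since NTP drawdown steers late initiations toward the cap).
The calibration default is therefore the instantaneous predictor, with the
batch-extent predictor selectable (`mode="batch"`); fitting the *measured*
CFs under batch integration also leaves θ unidentified (it diverges), a
further reason not to default to it.  `predictor_discrepancy` reports the
gap at any condition.  The cap analog contributes to effective salt with
NTP-like weights (configurable).

## 4. Reactor

Amount-basis state (moles + volume).  Between events, stiff-capable LSODA
integration at rtol 10⁻⁸ / atol 10⁻¹⁵; integration stops exactly at each
bolus and continuous-feed breakpoint (no interpolation across
discontinuities).  Boluses mix instantaneously and isothermally:
n ← n + c_feed·V_f, V ← V + V_f.  The output grid is the union of a uniform
reporting grid (default 60 s) and all event times, with pre- and post-event
states both recorded.  Derived trajectories (pH, effective salt, σ, rate
factors, CFᵢ) are computed by re-speciating every saved state with
warm-started Newton solves.

`decompose_rate_decline` reports the factors of the rate law normalized to
t = 0 — salt-driven occupancy (polymerase dilution also acts through this
factor), Γ_pH, DNA dilution, NTP saturation — whose product equals the
normalized rate identically, so attribution is exact by construction.

Grid-refinement, zero-feed-equals-batch, water-bolus dilution,
per-moiety-conservation-across-events, and continuous-feed-as-bolus-limit
behaviors are all asserted in the test suite.

## 5. Optimization, calibration, design

**Policy optimization.** The decision vector covers initial Mg, buffer and
NTP levels plus per-event feed-stock volumes at fixed bolus times (amounts
only — optimizing event times would break the box-bounded space; a
documented extension).  The objective is nonsmooth at event times, so the
search is derivative-free: seeded uniform sampling in the box, then
Nelder-Mead polish of the incumbent, with failed simulations mapped to a
large finite penalty and an optional hard σ cap.  Weight defaults
(ν_NTP = 10⁶ M⁻², ν_pH = 1, ν_RNA = 1.5×10⁶ M⁻¹) put the three terms at the
same order on the reference scenario; setpoint evaluation grids default to
5-minute spacing.  An evolution strategy would be a drop-in alternative;
the scipy-based hybrid was chosen because it is dependency-free and
reproducible bit-for-bit given the seed.

**MLE.** Independent Gaussian errors on CF with per-row sd (0.05–0.10,
matching replicate scatter); truncation of CF to [0,1] is ignored in the
likelihood (documented approximation).  Optimization in log-parameter space
enforces positivity (Nelder-Mead then BFGS polish; the fit is never allowed
to return a point worse than its start).  The covariance is the inverse
Gauss-Newton observed information assembled in log space — the
identifiability check must be scale-free, since λ (~10²) and θ (~10⁻³)
differ by ten orders in squared scale — and mapped back to (λ, θ)
coordinates.  A flat log-space direction raises an error naming it; two
measurements at one GTP level is the canonical non-identifiable design.

**D-optimal design.** det of the Fisher information
Σ ∇CF ∇CFᵀ/sd² (analytic gradients) maximized over log-concentration space
by seeded random search plus Nelder-Mead polish.  Optimal two-point designs
separate GTP levels (high/low) because θ enters only through the GTP
saturation curvature.  D-optimality under log-reparameterization differs by
the design-independent Jacobian factor (λθ)², leaving rankings unchanged
(tested).

**Monte Carlo prediction intervals.** Multivariate-normal parameter draws
from the covariance; non-positive draws rejected and counted; central 95%
quantiles of the predicted CF; deterministic given the seed.

## 6. Bundled scenarios — what they are and are not

The exact experimental feed recipes behind the published comparisons are
not available, so `scenarios.py` ships *synthetic reconstructions* built
from the described operating conditions: a salt-sensitive ~4,400-nt
AG-initiating GC-rich construct (A/U/C/G = 880/880/1100/1540;
1.43 MDa, so 7 μM ↔ 10 g/L), k_off,1M = 10^3.93, catalysts 12 nM DNA +
100 nM polymerase, 11 boluses at 15-min spacing over 3 h, 1 mL starting
volume:

- *heuristic*: 5 mM each NTP, 25 mM tris·HCl, 16 mM Mg(OAc)₂, equimolar
  NaOH-neutralized NTP stocks, open-loop bolus sizes fixed by the initial
  rate;
- *optimized*: 2 mM NTP setpoint, 15 mM tris base (no chloride), 8 mM
  Mg(OAc)₂, sequence-matched tris-neutralized NTP stocks, predictive
  feeding (current deficit plus half the model-projected next-interval
  consumption), NaOH titrated to the pH target at each event.  The high-pH
  variant targets pH 8.0 throughout; the low-pH variant (the flagship
  protocol) only defends a 7.3 floor, letting the reaction relax there by
  the end, and feeds ~20% less Mg;
- *batch_capping*: 2 mM each NTP + 2 mM cap analog, no feeds;
- *continuous_feed_literature_like*: an ordinary construct
  (k_off,1M = 10^2.93) under constant continuous feeding.

The free constants of §2 (k_cat, k_on, n_salt, ω, Ksp) were calibrated
*once*, jointly with these reconstructions, so that the simulated protocols
reproduce the published qualitative record — heuristic collapse near
3 μM RNA, optimized persistence past 7 μM at roughly a third of the initial
rate, a ~25% supersaturation reduction from the low-pH strategy — and were
frozen before the test suite was written.  Passing tests therefore
demonstrate that the *model mechanisms* (salt accumulation, pH drop,
catalyst dilution, phosphate-driven supersaturation, capping competition)
are implemented coherently and can reproduce the published behaviors under
reconstructed conditions; they do not constitute an independent fit to raw
experimental data, and absolute numbers (e.g. σ values) inherit the Ksp and
ω choices.

Synthetic observations add Gaussian noise clamped to [0,1] for cap
fractions, multiplicative lognormal noise (stated CV) for concentrations,
and additive noise (default 0.05 units) for pH — emulating HPLC-style
offline measurements.  Real data would add autocorrelated drift,
measurement delay, and model mismatch, none of which are emulated.

## 7. Problem sizes and determinism

The suite and the acceptance script run the full 3-hour scenario
simulations (~190 output points each, sub-second per simulation after the
policy-construction solves), a 200-replicate calibration study, and
2000-draw Monte Carlo intervals; everything completes in a few minutes on
one CPU.  All simulations are deterministic; random pieces (noise
generation, random search, Monte Carlo) are driven by explicit integer
seeds.

## 8. Known limitations

- Ideal-solution activities; no ionic-strength dependence of constants.
- No crystallization kinetics: σ is a driving force, not a precipitation
  model, and Mg loss to solid is not fed back into the kinetics.
- Single lumped rate expression; no abortive initiation, dsRNA, or
  truncated-product channels.
- θ is weakly identified by two-experiment calibrations — the reported
  covariance is large along that direction, and prediction intervals
  propagate it honestly.
- Bolus-to-bolus NTP sawtooth is inherent to 15-min spacing; continuous
  feeding (supported) removes it.
- No CSTR outflow, temperature dynamics, or evaporation.
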