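# ivtkit

Mechanistic modeling and optimization of **fed-batch in vitro transcription
(IVT)** — the cell-free synthesis of (m)RNA from a DNA template by T7 RNA
polymerase, the workhorse reaction of RNA vaccine and therapeutics
manufacturing.

Fed-batch IVT promises higher RNA titers than batch operation, but in
practice the reaction rate collapses as the run progresses, and feeding
decisions (how much NTP, Mg, and base, and when) are hard to get right by
trial and error. `ivtkit` implements a process model that explains and
manages these effects, together with the model-based tools built on it:
feed-policy optimization, anti-precipitation pH strategies,
co-transcriptional capping prediction, maximum-likelihood calibration, and
D-optimal experiment design.

## The model

A set of ODEs for the enzymatic kinetics is coupled to nonlinear algebraic
equations for instantaneous ionic speciation.  At every instant the
acid–base and Mg-binding equilibria of the solution (NTPs, phosphate,
pyrophosphate, tris, acetate, the cap analog, water) are solved for the
free species, the pH, and two derived drivers:

- **Effective salt** — a weighted sum over ionic complexes,
  `[salt] = Σᵢ ω_ion,i [ionᵢ]`, which sets the polymerase–promoter
  detachment rate through a power law, `k_off = k_off,1M [salt]^n_salt`.
  Chloride-bearing species weigh more than acetate; free Mg²⁺ is highly
  disruptive.
- **Supersaturation** of magnesium phosphate,
  `σ = ln([Mg²⁺]³[PO₄³⁻]² / Ksp)` — the thermodynamic driving force for the
  Mg₃(PO₄)₂ precipitation that appears once pyrophosphatase has converted
  the released PPi into tens of millimolar orthophosphate.

The transcription rate is an elongation-limited lumped law,

```
r = k_cat · [DNA] · f_occ(salt) · Γ_pH · Π_i S(Mg·NTPᵢ)
```

with equilibrium promoter occupancy `f_occ` (dissociation constant
`k_off/k_on`), the classical diprotic pH response
`Γ_pH = (1 + [H⁺]/K_a + K_b/[H⁺])⁻¹`, and Michaelis saturation in each free
Mg·NTP complex.  Transcription consumes NTPs stoichiometrically, releases
phosphate, and acidifies the solution — the falling pH of a progressing
reaction emerges from the speciation charge balance.

Co-transcriptional capping is a competition at initiation between the AG
trinucleoside cap analog (one step) and ATP+GTP (two steps); quasi-steady
state collapses it to two identifiable composites λ (M⁻¹) and θ (mM):

```
CFᵢ = [cap] / ([cap] + λ[ATP][GTP] / (1 + [GTP]/θ))
```

Feed policies (initial composition plus bolus or continuous feeds) are
optimized against a setpoint-tracking objective

```
min_F  ν_NTP Σ_N Σ_t ([NTP]_t − NTP_sp)² + ν_pH Σ_t (pH_t − pH_sp)² − ν_RNA [RNA]_tf
```

and (λ, θ) are calibrated by Gaussian MLE from batch cap-fraction
measurements chosen by D-optimal (max det Fisher information) design.

## Worked example

```bash
python examples/simulate_fedbatch.py
```

```
heuristic_fedbatch
  final RNA        3.44 uM (4.9 g/L)
  effective salt   161 -> 419 mM
  final pH         7.84
  residual rate    2.4% of initial

optimized_fedbatch_lowpH
  final RNA        7.85 uM (11.2 g/L)
  effective salt   56 -> 220 mM
  final pH         7.29
  residual rate    25.8% of initial

optimized / heuristic RNA yield: 2.28x
```

The conventional protocol (5 mM NTP starting point, tris·HCl buffer,
open-loop boluses) accumulates counterions until promoter occupancy — and
with it the rate — collapses near 3.5 μM RNA.  The model-optimized protocol
(2 mM NTP setpoint, low-chloride tris-base buffer, predictive feeding, pH
relaxed to 7.3 by the end to suppress Mg₃(PO₄)₂ supersaturation) passes
7 μM RNA (≈10 g/L) while retaining a third of its initial rate, more than
doubling the yield at identical catalyst input.

Other examples: `speciation_basics.py` (equilibrium picture of a reaction
mix), `rate_decline_decomposition.py` (which factor kills the rate, when),
`calibrate_capping.py` (MLE fit, λ = 20.9 M⁻¹, θ = 12.6 mM, and a 0.985
cap-fraction prediction for a 2 mM-each batch), `design_experiments.py`
(the D-optimal design separates GTP levels high/low), and
`optimize_policy.py` (a small policy search).

There is also a thin CLI exposing the same operations:

```bash
ivtkit speciate --recipe recipe.yaml --out results/
ivtkit simulate --policy policy.yaml --out results/
ivtkit optimize --seed 1 --budget 20
ivtkit fit-capping --data calibration_table.csv
ivtkit design-experiments --n 2 --seed 1
ivtkit make-fixtures --out fixtures/
```

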