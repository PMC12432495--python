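# Methods

## Compartment models and their assumptions

All three models are linear, constant-coefficient mass balances for a
non-reactive aerosol from a single on/off point source.  Shared
assumptions:

1. all emitted mass originates at the source inside the near field (NF);
2. air within each compartment is instantaneously well mixed;
3. the NF and far field (FF) exchange air at a limited flow `β` (m³/min);
4. the only sinks are the general-ventilation exhaust (from the FF) and,
   where present, local extraction — no deposition, coagulation or
   size-resolved dynamics.  This is appropriate for welding fume, whose
   mass lies predominantly below 1 µm where gravitational settling is
   negligible over a shift;
5. supply air is clean (zero background) and both zones start at zero
   concentration.

General ventilation is specified as air changes per hour of the *whole*
room: `Q = ACH · V_room / 60` m³/min, unaffected by any control flow.

With local extraction, a capture efficiency `ε ∈ [0,1]` removes that
fraction of the emission at the source before it mixes into NF air
(`S_eff = S(1−ε)`).  A hood-type LEV additionally withdraws mixed NF air at
`Q_lev` to outdoors; the make-up flow comes from the FF (raising the FF→NF
flow to `β + Q_lev`) and the fresh-air supply to the FF rises by the same
amount, so air flows balance in both zones.  At steady state the removal
identity `Q·C_FF + Q_lev·C_NF = S(1−ε)` holds, which the tests verify.

**Torch extraction (FET) vs hood extraction (LEV).**  The two control
types move air in physically different ways, and the package models them
differently (`ScenarioSpec.extraction_mode`):

* a *fume extraction torch* draws 1–1.5 m³/min through nozzle openings
  millimetres from the arc.  That airflow is the capture stream itself —
  the fume it removes is exactly the ε-captured fraction — and it does not
  meaningfully flush the 1–7 m³ near field.  FET scenarios therefore apply
  source capture only (`capture_stream`): the concentration field is the
  uncontrolled two-box solution driven by `S(1−ε)`.
* a *fixed or movable hood* moves 2.5–20 m³/min of mixed near-field air,
  which both captures fume (ε) and dilutes the NF; LEV scenarios use the
  full bulk-extraction topology above (`bulk`).

Treating the torch flow as an additional bulk sink would overstate its
benefit precisely in the high-exposure tail (small rooms at low air-change
rates, where Q_lev would rival Q), biasing P95-based decisions optimistic.

## Solution method and time averaging

The 2×2 system is solved exactly by eigen-decomposition (the eigenvalues
are real and distinct because both off-diagonal terms are positive); the
one-box model is a scalar exponential.  Kernels evaluate concentration
*and* its running time integral in closed form and broadcast over arrays
of parameter draws, so a 50 000-iteration scenario costs a fraction of a
second and the shift TWA is exact rather than grid-quadrature.  The
grid-based API (`solve_*` + `time_weighted_average`) uses a default
0.5-min grid with trapezoidal integration and interpolated window
endpoints; tests confirm both paths agree and that the closed forms match
an independent stiff ODE integration to 1e-6 relative error.

Degenerate inputs: non-positive volumes/flows, `V_NF ≥ V_room`, ε outside
[0,1] and windows outside the series span raise typed errors; a zero
source yields identically zero concentrations; closed-form round-off can
leave O(1e-16) negative residue at C = 0, which the solvers clamp to zero.

## Scenario parameters

Conditions-of-use scenarios sample independent uniform distributions
(means in parentheses):

| parameter | range | units | basis |
|---|---|---|---|
| room volume | 30–120 (75) | m³ | single-welder workspace |
| general ventilation | 5–20 (12.5) | 1/h | workshop practice, excl. controls |
| NF volume | 1–7 (4.0) | m³ | hemisphere of radius 0.8–1.5 m |
| NF–FF exchange β | 9.5–30.8 (20.2) | m³/min | two-zone field measurements |
| wire feed speed | 50–250 (150) | mm/s | machine-settable range |
| arc-time fraction | 12–20 % of 480 min | — | active to intensive manual welding |
| FET: ε / flow | 0.80–0.98 / 1–1.5 | — / m³/min | torch angle 0–45°, face velocity > 0.5 m/s |
| LEV: ε / flow | 0.40–0.88 / 2.5–20 | — / m³/min | field capture studies / extractor capacity |

The per-iteration emission rate is `EF × ṁ(v) × 60` mg/min, where the
emission factor EF (mg fume per g wire) is held at the electrode's
*maximum* reported value — a worst-case assessment transferable to any
less-emitting parameter set — and the wire mass feed rate
`ṁ = π(d/2)²ρv` uses density 7.8 g/cm³.  V_NF is sampled directly as a
uniform volume on [1, 7] m³; the hemisphere geometry motivates the bounds
but the radius itself is not the sampled quantity.  The generation block
is placed at shift start and the worker is present for the whole 480-min
shift; placement does not affect the full-shift TWA materially because the
decay tail is integrated either way.  All parameters are sampled
independently (no correlation information exists for these ranges).

Validation scenarios reconstruct published performance-testing setups:
five single-room SMAW runs (62.1 m³, ACH 60.4 → 6.6, 60-min sample,
continuous arc, emission uniform 387–589 or point 329 mg/min for E6010 and
uniform 180–365 mg/min for E7018) and a two-zone boiler room (81 m³,
ACH 23, β = 21 m³/min point, 56-min arc split equally between the two
electrodes — per iteration `S = (S₁+S₂)/2` with each drawn from its own
uniform range — 325-min sample).  The boiler-room NF volume is not
reported; it is fixed at 4 m³, the CoU mid-range, to which the NF
steady-state level is insensitive (the NF–FF concentration difference
depends on S and β only).

## Monte Carlo size and summaries

`n = 50 000` iterations by default: the Monte Carlo standard error of GM
and P95 is then well below the two-significant-figure reporting precision,
and GM/P95 move by < 2 % against `n = 200 000`.  Summaries report
GM = exp(mean ln x), GSD = exp(sd ln x), the arithmetic mean, and
*empirical* linear-interpolation percentiles.  Because every determinant is
bounded, the simulated TWA distribution is sub-lognormal in the extreme
tail: empirical P99 falls below the parametric lognormal quantile
GM·GSD^2.326.  `ExposureSummary.lognormal_percentile()` provides the
parametric convention, which industrial-hygiene summaries frequently
report for extreme percentiles; the package defaults to empirical
quantiles everywhere.

## Sensitivity analysis

Determinant relevance is scored by Spearman rank correlation between each
sampled parameter and the zone TWA (ties by average rank; constant columns
flagged and excluded), with "contribution to variability" defined as
normalised squared coefficients, ρ²ᵢ/Σρ² × 100 — an ordering diagnostic,
not a variance decomposition (Sobol-type indices are out of scope).
Because the TWA distribution is strongly right-skewed, rank and raw-value
(product-moment) coefficients differ materially for dominant determinants
(e.g. −0.60 vs −0.54 for the LEV capture efficiency); `SensitivityResult`
reports both.  The generic relevance study samples one-decade uniform
spans (hi = 10·lo enforced) of emission rate, ventilation flow, room
volume, NF volume and β, with a continuous full-shift source.  Robust
findings: emission rate (+) and β (−) dominate the near field; ventilation
flow and room volume dominate the far field, where NF volume and β are
irrelevant; the NF level is nearly flat in NF volume (< 5 % over 1–10 m³)
because the small zone saturates within minutes at any size in that range.

## Decision rules

For OEL-based verdicts (default 5 mg/m³ total welding fume):

* ECHA/REACH: compliant if P90 < OEL; RCR = P90/OEL.
* AIHA categories on P95/OEL with inclusive upper bounds: ≤ 0.01
  non-existent (1), ≤ 0.1 highly controlled (2), ≤ 0.5 well controlled
  (3), ≤ 1 controlled (4), else poorly controlled (5).
* Measurement interval from GM/OEL: < 0.1 → 36 months, < 0.25 → 24,
  < 0.5 → 18, otherwise no periodic interval (reassessment required).
  The 18-month tier completes the standard's ladder beyond the two tiers
  the assessment itself exercises.
* Respirator nominal protection factor: the smallest of {4, 10, 20, 40,
  100} that is ≥ RCR (1 if compliant, none if RCR > 100).

## Emission-factor back-calculation

The NF P95 is strictly proportional to the emission factor (model
linearity with the factor applied to every draw), so the compliant maximum
EF is found by bisection on P95(EF) = OEL under common random numbers (one
draw set re-evaluated at each candidate), to 0.05 mg/g, then rounded
*down* to one decimal so the published limit is conservative.  Plug-back
under the same draws agrees with the OEL to < 2 % (rounding only), and
under fresh seeds to Monte Carlo tolerance.

## Synthetic field measurements

Model-performance workflows need measured concentrations, which the
validation literature reports only in summary form.  The synthetic
generator emulates their role: the model TWA at the scenario's midpoint
parameters, perturbed by multiplicative lognormal error with a chosen
geometric standard deviation (default 1.5, typical of shift-TWA sampling
variability).  This captures the positively-skewed, median-unbiased
structure of industrial-hygiene data but deliberately omits instrument
bias, autocorrelated within-shift fluctuations, background sources and
between-worker variance components — so passing recovery tests shows the
*inversion machinery* (modelled/measured GM ratios, steady-state β
estimation, linear least-squares emission-rate recovery) is correct and
adequately conditioned, not that any particular field dataset would be
recovered.  Recovery accuracy at noise GSD 1.2: median relative error of
the emission rate (50-point series) and of β (100 replicates per zone)
both ≤ 5 %.

## Known limitations

* Total fume mass is the assessed quantity; component-specific risks
  (e.g. hexavalent chromium, ozone, volatiles) need separate limits and
  are out of scope.
* The FET-vs-LEV extraction-mode split is a modelling judgement about how
  control airflow interacts with zone air; field evaluations of torch
  extraction under low-ventilation conditions would discriminate it
  directly.
* The hood-flow sensitivity coefficient is structurally tied to the bulk
  topology; reported field values for that single coefficient vary more
  than the exposure summaries do, and weaker-flush variants that would
  lower it are inconsistent with the LEV exposure levels this model
  reproduces.
* Single on/off emission block, one source, two zones; no background
  concentration; no parameter correlations; uniform distributions only.
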