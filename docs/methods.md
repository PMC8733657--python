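# Methods

## Scope and model structure

`cefapbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model of cefadroxil — a first-generation cephalosporin, PEPT1
substrate, renally excreted essentially unchanged — in mouse, rat, and
human, together with the analysis workflow used to qualify such models:
noncompartmental metrics, fold-error statistics, clearance calibration,
parameter-sensitivity sweeps, allometric scaling, and two in-silico
experiments (intestinal-transporter knockout and dissolution-rate
variation).

The disposition model has 16 compartments: venous and arterial blood pools,
lung, and 13 well-stirred, perfusion-rate-limited tissues (adipose, muscle,
liver, spleen, heart, brain, kidney, skin, reproductive organ, red and
yellow marrow, rest-of-body). For an ordinary tissue

    V_t dC_t/dt = Q_t (C_art − C_t/Kp_t),

venous outflow leaving at the tissue-to-plasma partition equilibrium
C_t/Kp_t. The lung sees the whole cardiac output between the venous and
arterial pools. The spleen and the portal (gut) flow drain through the
liver; the hepatic-artery inflow is the tabulated total liver outflow minus
the spleen and gut flows. The blood:plasma concentration ratio is 1, so
blood and plasma concentrations coincide and the measured Kp values (which
already embed plasma protein binding) are applied directly to total
concentrations; the unbound fraction fup is *not* reapplied inside the
systemic model.

### Renal elimination convention

The kidney is the only eliminating organ and the fitted renal clearance
(0.031, 0.18, 8.50 L/h in mouse, rat, human) is a *plasma* clearance — it
was estimated as Dose/AUC from plasma concentration–time data. The model
therefore applies it to the venous plasma pool the profiles are read from:

    elimination rate = CL_renal · C_venous.

Two properties motivated this choice over drawing the clearance flux
through the kidney tissue compartment:

1. the identity AUC(0–∞) = Dose/CL holds *exactly* for both venous and
   arterial plasma (integrating the linear system termwise shows the two
   AUCs are equal), which is how the fitted CL is defined; and
2. the rate is self-limited by the venous concentration, so every state
   stays non-negative for *any* clearance value. A flux of the form
   CL·C_art drawn from a tissue compartment turns unphysical as soon as CL
   exceeds that tissue's blood flow — which the standard 0.1–10×
   clearance-sensitivity sweep reaches in all three species (e.g. human
   10 × 8.5 = 85 L/h against a kidney flow of 79.6 L/h).

### Numerical self-consistency of the flow table

The tabulated per-tissue flows sum to the tabulated cardiac output only to
their printed rounding (relative mismatch up to ~1×10⁻⁵). The right-hand
side uses the *sum of the distribution flows* as the cardiac output for the
venous→lung→arterial chain, which makes the flow network exactly
conservative; with the printed value instead, mass leaks at the rounding
rate, which is harmless over 24 h but visible (≈1%) in a 48 h run with
elimination switched off. A 2% reconciliation check between the flow sum
and the printed cardiac output is enforced at load time.

## Gut absorption model

Oral dosing uses nine serial lumen compartments — stomach, duodenum,
jejunum 1–2, ileum 1–3, caecum, ascending colon — each carrying undissolved
and dissolved drug mass, with first-order transit at 1/transit_time.
Transit times and radii are standard fasted-human compartmental-transit
values (stomach 0.25 h; duodenum 0.26 h / 1.6 cm; jejunum 0.93 h / 1.45 cm
and 0.74 h / 1.3 cm; ileum 0.58 h / 1.2 cm, 0.42 h / 1.0 cm, 0.29 h /
0.9 cm; caecum 4.5 h / 3.5 cm; colon 13.5 h / 2.5 cm), all configurable in
`gut_human.params`. Resting fluid volumes are 40% of the anatomical
(πr²L) segment volume; the stomach fluid is set to 250 mL, the water a
fasted-state dose is taken with. At 250 mL the largest dose studied
(2,253 mg) stays below cefadroxil's 12.44 mg/mL solubility, so the
precipitation pathway (re-transfer of supersaturated solution to solid with
the 900 s mean precipitation time) is implemented but inert — it only
activates in the solubility sensitivity sweep.

Dissolved drug is absorbed by two parallel routes:

* **passive permeation**, first-order with
  ka = (2·Peff/r)·passive_scale, the cylindrical surface-to-volume form.
  Peff = 0.03×10⁻⁴ cm/s. `passive_scale` is 1.0 in the small intestine and
  0.2 in caecum/colon, a single coarse surrogate for the reduced colonic
  absorptive surface and fluid that commercial absorption-scale-factor
  machinery models in more detail. With these defaults the passive-only
  (transporter-knockout) fraction absorbed computes to 8.0%.
* **PEPT1-mediated uptake**, Michaelis–Menten in the lumen concentration,
  Km = 860.31 mg/L, with capacity distributed across duodenum→ileum 3 in
  proportion to the absolute expression contents 16.28, 87.84, 73.93,
  78.61, 63.41, 49.29 mg (zero in stomach, caecum, colon). The per-mg
  capacity 0.0025 μg/s/mg-PEPT1 combined with those expression masses
  under-produces absorption by orders of magnitude if taken at face value
  (the printed unit is ambiguous), so the capacity carries one dimensionless
  `global_scale` calibrated by bisection so that the fraction absorbed of
  an oral 1,126.5 mg dose is 99.9% — mirroring how the original model's
  Vmax was itself optimized. The calibrated value, 968.17, is frozen in the
  bundled parameter file; a test re-runs the calibration and checks the
  fixed point. Fa is monotone non-decreasing in the scale, so the bisection
  is guaranteed to converge; it targets the crossing Fa = 0.999 rather than
  a loose |Fa − target| criterion because Fa saturates at 1.

Dissolution is either *instant* (the dose starts dissolved in the stomach)
or *first-order* parameterized by T85%, the time to 85% dissolved:
k_d = ln(1/0.15)/T85%. The rate carries the linear driving force
(1 − C/Cs)⁺, which equals the nominal first-order rate in dilute solution
and closes continuously at the solubility limit Cs (a discontinuous on/off
gate at Cs makes the stiff integrator chatter). Instant mode re-dissolves
any precipitated solid at 500/h, fast enough never to be rate-limiting.

Absorbed flux enters the liver with the portal blood. Since the kidney is
the only eliminating organ there is no first-pass loss, and oral
AUC(0–∞) = Fa·Dose/CL to integration accuracy.

## Simulation and NCA

`simulate` integrates the coupled system with LSODA at rtol 1e-8 /
atol 1e-10 and reports 501 points on a log-spaced grid (t = 0 plus a
geometric grid from 1e-4 h): after an IV bolus the venous washout time
constant is a few seconds, three orders of magnitude faster than the
terminal phase, and a uniform grid of any affordable size mis-integrates
the spike. Default horizons are 24 h (rodent IV) and 48 h (human oral),
leaving an extrapolated AUC tail well under 1%. Halving the tolerances
moves AUC and Cmax by far less than 0.1% (tested).

NCA follows common practice: Cmax/Tmax from the grid maximum, AUC by
trapezoid, λz by log-linear regression on the last four positive points,
AUC(0–∞) = AUC(0–t) + C_last/λz, AUMC with the matching tail,
MRT = AUMC/AUC, and for IV bolus CL = Dose/AUC and Vss = Dose·AUMC/AUC².
When there is no terminal decline the extrapolation is refused
(λz = None) rather than silently extended. mg/L and μg/mL are numerically
identical and used interchangeably.

The structural (closed-form) steady-state volume of distribution is

    Vss = Σ_t Kp_t·V_t + (1 − Hct)·(V_arterial + V_venous),

the plasma — not whole-blood — share of the blood pools, with haematocrit
fixed at 0.45 for all species (not tabulated; the standard value, and the
one that reproduces the mouse and rat Vss to printed precision: 0.0121 and
0.158 L). The gut wall carries no distribution volume and is excluded. For
human this yields 22.10 L, which sits at the lower edge of the two reported
values (23.25 and 24.747 L); the difference is consistent with the original
software including additional volume terms (e.g. gut wall) not reproducible
from the printed tables, and both reported values are kept in view by the
bracketing acceptance band rather than silently preferring either.

Body weights are likewise not tabulated and are fixed from dose arithmetic:
0.025 kg (4.79 mg at 528 nmol/g × 363.39 g/mol = 191.87 μg/g), 0.31 kg
(0.62 mg at 2 mg/kg), 75.1 kg (375.5 mg at 5 mg/kg). With these weights the
natural-log OLS power-law fit Y = a·BW^b on the reported Vss and CL
triplets reproduces all four published constants to four decimals
(a = 0.4288/0.4108, b = 0.9476/0.7012).

## Qualification statistics

FE_i = Predicted_i/Observed_i per point; AFE = 10^(mean log₁₀|FE|);
AAFE = 10^(mean |log₁₀ FE|). A simulation qualifies when every FE is within
[0.3, 3] and AFE and AAFE are both < 2. Predicted curves are interpolated
log-linearly onto observed times; observed zeros are excluded with a
warning (the ratio is undefined). The absolute value inside AFE's log is
kept exactly as conventionally written, which for all-positive FE lists is
the ordinary geometric mean.

## Synthetic observed data

The generator emulates the assay error structure of published
concentration–time datasets: the true model profile sampled on
literature-like schedules (nine points to 120 min for mouse IV, eight
nonzero points to 240 min for rat IV, twelve nonzero points to 480 min for
human oral) and multiplied per point by exp(ε), ε ~ N(0, σ²),
σ = √ln(1+CV²), default CV 0.15. All draws flow through one seeded
generator. What passing the closure tests shows: the pipeline is
self-consistent (noiseless data validate perfectly; clearance is recovered
without bias at 10% CV over 100 replicates). What it does not show: real
datasets carry structure the generator omits — inter-subject variability,
correlated residuals, below-quantification censoring, actual sampling-time
deviations — so qualification against real data remains a separate
exercise.

## Parameter-sensitivity and dissolution experiments

PSA is one-at-a-time: a named parameter (any tissue Kp, renal CL,
transporter capacity, Peff, solubility) is multiplied by nine log-spaced
factors spanning 0.1–10× and Cmax / AUC(0–∞) are recorded. Two structural
results are enforced as tests: Kp changes leave IV AUC unchanged
(distribution does not alter total exposure in a linear model), and the
clearance sweep scales AUC exactly as 1/factor. In the human oral model,
exposure is insensitive to solubility and passive permeability (absorption
is carrier-dominated) and sensitive to renal CL and transporter capacity.

The dissolution-rate experiment simulates first-order release at
T85% ∈ {0.5, 1, 1.5, 2, 4, 6} h and reports the relative deviation of Cmax
and AUC from the T85% = 0.5 h reference. With this implementation the AUC
deviation stays within 20% through T85% = 2 h (8.4%), and the Cmax
deviation is within 20% at T85% = 1 and 1.5 h but reaches ≈22% at 2 h —
slightly above the 20% published for the original model. The gap is
consistent with two structural differences: the coarse per-segment
passive/colonic scaling used here in place of the original
absorption-scale-factor model, and a slightly slower calibrated absorption
(Tmax 1.43 h vs 1.25 h), which makes the simulated Cmax somewhat more
sensitive to delayed release. The deviation is reported as computed.

## Degenerate inputs and tie-breaks

Zero dose returns identically zero trajectories and a zero mass-balance
residual by convention. A trajectory truncated to its initial point has an
exact balance. Kp = 0 is accepted in the closed-form Vss (blood-only limit)
but rejected for simulation (the perfusion equations divide by Kp).
Transporter calibration raises if the passive floor already exceeds the
target or the target is unreachable within the bracket; clearance fitting
flags an optimum within 0.1% of a search bound instead of failing.

## Known limitations

* Renal reabsorption/secretion (PEPT2) and the resulting dose-dependent
  clearance are not modeled; clearance is linear.
* Rodent oral absorption is not parameterized (rodent models are IV-only).
* No blood–brain-barrier kinetics; brain is an ordinary perfused tissue.
* Solubility is treated as pH-independent across the GI tract (cefadroxil
  is highly soluble over the physiological pH range).
* Kp values are assumed species-invariant, inherited from the source
  model's cross-species assumption.
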