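# Methods

## The scientific question

Glucose-6-phosphate dehydrogenase (G6PD) deficiency impairs the only
NADPH source of the human erythrocyte and therefore its capacity to
detoxify hydrogen peroxide through the glutathione system.  Clinical
severity varies enormously between enzyme variants, and routine activity
assays measure the enzyme at rest, not its dynamic reserve under
oxidative load.  `rbcredox` simulates the dynamic response: it
parameterises a kinetic model of the red-cell antioxidant network with a
subject's six G6PD kinetic constants, perturbs the resting steady state
with a 0.1 mM H2O2 dose, and scores the excursion and recovery of the
GSH/GSSG redox ratio.

## The reduced network

The full published erythrocyte models (glycolysis, adenine-nucleotide
metabolism, ion transport, haemoglobin binding) are far larger than the
part that carries the redox response.  `rbcredox` deliberately ships a
*reduced closure*: the eight dynamic species and eleven reactions that
form the H2O2 → glutathione → NADPH → G6PD feedback loop, with everything
upstream lumped into clamped pools and constant fluxes.  Dynamic species
(µM): intracellular H2O2, superoxide, GSH, GSSG, NADPH, NADP, G6P,
6-phosphogluconolactone.  Clamped: extracellular H2O2, ATP (1600 µM),
2,3-BPG (5000 µM) and glucose (5000 µM) — the former enters through
membrane permeation, the latter three are effectors or lumped-flux
drivers only.

Rate laws:

| reaction | form | role |
|---|---|---|
| H2O2 permeation | `k·([H2O2]ext − [H2O2]in)` | dose coupling / efflux |
| O2⁻ generation | `k·[GLC]` | constant basal ROS source |
| SOD | first order, 2 O2⁻ → H2O2 | superoxide dismutation |
| CAT | first order, 2 H2O2 → products | bulk H2O2 clearance |
| GSHpx | bi-substrate MM, H2O2 + 2 GSH → GSSG | glutathione-coupled clearance |
| GR | bi-substrate MM, GSSG + NADPH → 2 GSH + NADP | ratio restoration |
| G6PD | full substrate/product/effector law | the patient-specific step |
| 2nd PPP step | first order in GL6P, saturable in NADP | second NADPH yield |
| G6P supply / drain | `k·[GLC]` / first order | glycolytic context |
| NADPH sink | MM, km = 1 µM | basal NADPH demand |

The G6PD velocity is

```
v = Vmax [NADP][G6P] / ( KmNADP·KmG6P·( 1 + ([NADP]/KmNADP)(1 + [G6P]/KmG6P)
        + [NADPH]/KiNADPH + [ATP]/KiATP + [2,3BPG]/Ki2,3BPG ) )
```

which is zero iff a substrate is absent, strictly below `Vmax`
everywhere, monotone increasing in each substrate and decreasing in each
inhibitor (property-tested).

Two design points deserve explanation:

- **Source fluxes scale with clamped glucose.**  Basal superoxide
  generation and G6P supply are written `k·[GLC]` rather than bare
  constants.  With glucose clamped at its default these *are* constants;
  writing them this way keeps the convention that every velocity
  vanishes in a fully empty state (a dead cell runs no flux) and gives a
  single knob for metabolic activity.
- **The basal NADPH sink is saturable** (MM with km = 1 µM), i.e.
  effectively a constant demand at physiological NADPH.  This choice is
  load-bearing: it makes each subject's resting NADPH the intersection
  of its G6PD supply curve with a *flat* demand, so the resting redox
  state ranks subjects by their supply curve in the regime where strong
  NADPH product inhibition (e.g. KiNADPH ≈ 0.9 µM) is felt.  A strictly
  first-order sink forces all deficient subjects into a low-NADPH regime
  where that inhibition is invisible and the published severity ordering
  cannot be reproduced.

Two moieties are conserved exactly by the stoichiometry and used as
solver diagnostics: total glutathione GSH + 2·GSSG (3209 µM) and total
nicotinamide NADP + NADPH (62 µM).  Glutathione synthesis/efflux and
NADP(H) turnover are outside the model's scope.

## Calibration

The non-G6PD constants are not transcriptions of any published model;
they are calibrated, deterministically and once, in two steps:

1. Structural constants (CAT rate, GSHpx capacity and its H2O2
   half-saturation, GR Michaelis constants, sink capacity) were chosen
   from a steady-state analysis plus a coarse scan so that the eleven
   reference subjects reproduce the published *qualitative* pattern:
   the severe subjects (patients 1, 4, 8) have the lowest resting
   GSH/GSSG and the longest recoveries, and the resting-ratio ordering
   of all eleven subjects matches the published table.
2. The glutathione-reductase capacity `vmax_gr` is then solved by a
   secant iteration (the `rbcredox calibrate` command) so the healthy
   control's resting GSH/GSSG equals the published 700.38 exactly.

With these defaults the control run gives: resting ratio 700.38, a dip
to 0.67 of baseline (amount of change 0.327) and recovery in 310 s; the
most severe subject (patient 1) rests near ratio 33, dips by only 2.8%
and does not regain 99% of baseline inside the 30-minute window.  The
absolute amount-of-change and recovery-time values differ from the
published table (0.20 and 235 s for the control) — a reduced network
cannot match a full metabolome model point-for-point, and only the
control resting ratio (±20%) and the qualitative orderings are treated
as calibration targets.  The fast CAT-dominated bolus clearance means
the post-dose GSSG increment is nearly subject-independent, which is
exactly the structure implied by the published indicator table (a single
increment Δ reproduces every printed amount of change via
Δ/(GSSG_ss + Δ)).

## The perturbation protocol

- Steady state: stiff BDF integration of the compiled ODE system to a
  10^6 s horizon, then a Newton polish of the right-hand side with one
  row per conserved moiety replaced by its linear constraint (removing
  the stoichiometric rank deficiency).  The result must satisfy
  ‖rhs‖∞ ≤ 1e-9 µM/s and conserve both moieties to 1e-6 relative.
- Dose: default `bolus_internal` — the intracellular H2O2 is raised by
  100 µM (0.1 mM) at t = 0, matching the "added a perturbation" reading;
  `clamp_external` holds the extracellular concentration at the dose for
  the window instead (both modes are provided because the dosing site
  is ambiguous in the source data).
- Integration: BDF with rtol 1e-8, atol 1e-10 µM, recorded every 1 s
  over an 1800 s window.  Linear conserved moieties are preserved to
  solver tolerance (measured drift ~1e-15 relative).  Solver states are
  clipped at zero for reporting only; a negative excursion beyond 1e-6
  µM raises an error rather than being silently clipped.

## Indicators

For each run: the resting ratio `[GSH]/[GSSG]_ss`; the amount of change
`(ratio_ss − ratio_min)/ratio_ss` with the minimum refined by a
parabolic fit around the discrete minimum; and the recovery time — the
first linear-interpolated crossing of `θ·ratio_ss` after the minimum,
with θ = 0.99 by default (the ratio approaches baseline asymptotically,
so exact return never occurs; θ is configurable and reported with every
value).  A subject that never crosses within the window receives the
`NOT_RECOVERED` sentinel (`inf`); cohort statistics either cap it at the
window length (default, 1800 s) or drop the row.  The window-cap default
is the treatment that reproduces the published recovery/amount
correlation over all eleven subjects.

## Cohorts and grids

- The reference cohort is the published set of ten deficient patients
  plus the healthy control, shipped verbatim in
  `cohorts.REFERENCE_PATIENTS`.
- Virtual patients draw the six parameters independently and uniformly
  from the published realistic intervals (Vmax 1–64, KmG6P 7–152 µM,
  KmNADP 3–155 µM, KiNADPH 1–56 µM, KiATP 125–11000 µM, Ki2,3BPG
  520–35000 µM).  Uniformity is the minimal-assumption reading of
  "randomly chosen"; no dependence structure is imposed (the source
  study imposed none either), and a log-uniform option exists for the
  wide inhibition-constant ranges.  All randomness flows through one
  `numpy.random.default_rng` seed; identical seeds give bit-identical
  cohorts.  The study convention is 500 patients per trial run and 15
  runs; the test suite and the acceptance script use reduced sizes
  (50×3 and 100×3) chosen to keep a full recomputation around a minute
  while leaving the trend statistics unambiguous.
- The Vmax × KmG6P grid fixes the other four constants at the control's
  values (the source figure does not state them; this is declared in
  every output header).  Axis zeros are evaluated at a floor of 0.01
  (a zero Vmax or Km makes the rate law degenerate) and the substitution
  is recorded.  Default steps are 1 (Vmax) and 2 (Km, even values);
  both are configurable, and coarser grids are used where runtime
  matters.

## What the synthetic generator does and does not emulate

The virtual-patient generator emulates the study's inputs exactly as
declared: independent uniform marginals over printed intervals.  It does
not model biologically coupled parameter distributions (e.g. low NADP
affinity co-occurring with weak NADPH inhibition), real variant
databases, or measurement error in the kinetic constants — so passing
cohort-level tests demonstrates correct machinery and trend logic, not
population realism.  The synthetic exponential-recovery traces
`r(t) = r0(1 − a·e^(−t/τ))` exist to give the recovery-time estimator a
closed-form oracle (`τ·ln(a/(1−θ))`); real trajectories are neither
exponential nor single-timescale.

## Numerical choices and degenerate inputs

- Steady-state residual tolerance 1e-9 µM/s; integration rtol 1e-8,
  atol 1e-10 µM; halving both changes recorded series by < 1e-5
  relative (tested).
- The recovery crossing is linearly interpolated; on monotone synthetic
  recoveries the error is below half the sampling step (tested).
- Ties/edges: a trajectory that never drops below threshold has
  recovery time 0; the parabolic minimum refinement is skipped at grid
  edges or non-convex triples; the minimum never exceeds the initial
  ratio by construction.
- Deeply collapsed grid cells (GSH-exhausted steady states at extreme
  Vmax/Km combinations) can have dips smaller than the threshold band,
  which degenerates their recovery time to 0; such cells are the
  reported violations of the surface-monotonicity trends.

## Known limitations

- The reduced network is a closure, not the full published erythrocyte
  model; absolute indicator values (other than the calibrated control
  resting ratio) are not comparable to the published table, only the
  orderings and trends are.
- ATP, 2,3-BPG and glucose are clamped: feedback from energy metabolism
  during oxidative stress is absent.
- Glutathione and nicotinamide totals are strictly conserved; transport
  and synthesis are not modelled.
- Only GSH/GSSG is scored; NADPH/NADP is recorded but carries no
  indicator.
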