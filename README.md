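# rbcredox

Kinetic simulation of glutathione redox homeostasis in the human red
blood cell under oxidative perturbation, with patient-specific
glucose-6-phosphate dehydrogenase (G6PD) kinetics.

G6PD-deficient erythrocytes cannot regenerate NADPH fast enough to keep
the glutathione pool reduced during an oxidative crisis, but clinical
severity varies widely between enzyme variants and resting-activity
assays do not predict the dynamic response.  `rbcredox` is for
modellers and translational researchers who want to ask: *given a
variant's kinetic constants, how does the cell's redox status
(GSH/GSSG) respond to a hydrogen-peroxide challenge?*

The package provides:

- a reduced kinetic ODE model of the erythrocyte antioxidant network
  (H2O2 permeation, superoxide generation, SOD, catalase, glutathione
  peroxidase, glutathione reductase, the oxidative pentose phosphate
  pathway) with the full G6PD rate law

  ```
  v = Vmax [NADP][G6P] / ( KmNADP·KmG6P·( 1 + ([NADP]/KmNADP)(1 + [G6P]/KmG6P)
          + [NADPH]/KiNADPH + [ATP]/KiATP + [2,3BPG]/Ki2,3BPG ) )
  ```

- the perturbation protocol: steady-state search, a 0.1 mM H2O2 dose at
  t = 0, and stiff integration over a 30-minute observation window;
- three indicators of redox imbalance per subject: initial GSH/GSSG,
  amount of change `(ratio_ss − ratio_min)/ratio_ss`, and recovery time
  (first return to θ·ratio_ss, θ = 0.99 by default, with a
  NOT_RECOVERED sentinel);
- cohort machinery: the eleven published reference subjects (ten
  G6PD-deficient patients + healthy control), uniform virtual-patient
  sampling from the published parameter ranges, indicator–parameter
  correlations, Vmax × KmG6P indicator surfaces and stratified trend
  summaries.

## Worked example

Simulate the healthy control and the most severe reference patient:

```sh
$ rbcredox simulate --subject Control --out runs/ctrl
Control: initial GSH/GSSG 700.38, amount of change 0.3274, recovery 310.05 s (theta=0.99)

$ rbcredox simulate --subject "Patient 1" --out runs/p1
Patient 1: initial GSH/GSSG 32.64, amount of change 0.0283, recovery NOT_RECOVERED (theta=0.99)
```

The control rests at a high redox ratio, dips by a third after the
0.1 mM dose and is back within 1% of baseline in ~5 minutes.  Patient 1
(Vmax 1.1, KmG6P 152 µM, KiNADPH 0.62 µM) rests at a ratio twenty-fold
lower, barely dips — its antioxidant flux is already saturated — and
fails to regain baseline inside the 30-minute window: the mild-dip /
slow-recovery signature of severe deficiency.  Each run writes
`trajectory.csv` (time courses of every species, flux and derived
ratio), `indicators.csv` and a `manifest.json` sufficient to reproduce
it.

The same pipeline in Python:

```python
from rbcredox import build_default_model, evaluate_subject, load_reference_patients

model = build_default_model()
ss, traj, ind = evaluate_subject(load_reference_patients()[-1], model)
print(ind.initial_ratio)   # 700.38
print(ind.recovery_time)   # 310.05 (s)
```

Other entry points: `rbcredox cohort --mode reference` (indicator table
for the eleven published subjects), `rbcredox cohort --mode virtual
--n 500 --runs 15 --seed 1` (virtual-patient trials), `rbcredox grid`
(Vmax × KmG6P surfaces), `rbcredox table3-check` (published-correlation
check) and `rbcredox calibrate` (re-fit of the GR capacity to the
control target, exporting a model-definition JSON).

The model itself is declarative: `save_model`/`load_model` read and
write a JSON definition (species with initial values and clamped flags,
reactions with stoichiometry, rate-law id and parameters, conserved
moieties), so alternative networks can be swapped in without code
changes.  See `docs/methods.md` for the model, its calibration and its
limitations.

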