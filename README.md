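# trenshsim

An electrical-network hemodynamic simulator of plexiform brain
arteriovenous malformations (bAVMs) and of **TRENSH** — *transvenous
retrograde nidus sclerotherapy under controlled hypotension* — for
researchers studying endovascular bAVM treatment strategies in silico.

A bAVM shunts arterial blood through a tangle of fragile microvessels (the
*nidus*) directly into draining veins. TRENSH proposes treating it
backwards: lower the systemic arterial pressure (optionally occluding a
feeder with a balloon), then inject a liquid sclerosant retrogradely
through a draining vein so that it permeates the nidus against the
weakened antegrade flow. `trenshsim` models the whole circulation as a
resistor network obeying the Hagen–Poiseuille law

```
Q = ΔP / R_v ,   R_v = 8Lμ / (πr⁴) ,   μ = 3.5 cP
```

and Kirchhoff's two circuit laws, with nine electromotive forces (systemic
pressure ESP, one per arterial feeder EAF1–4, one per draining vein
EDV1–3, and central venous pressure ECVP). On top of that it provides

* a **stochastic nidus generator** — compartmentalized, column-graded
  plexiform architectures (3–6 compartments × 3–7 columns, ~950 vessels on
  average) with an intranidal fistula from feeder AF2 to vein DV2;
* a **batched steady-state solver** (sparse LU, one factorization per
  balloon-occlusion topology, all pressure sets solved simultaneously);
* the **TRENSH scenario grids** — 4 hypotension levels × 2 CVP levels × 4
  feeder-occlusion states × 3 injection sites × 10/20/30 mmHg injections
  (320 pressure sets per architecture), fine 1-mmHg sweeps, and
  cardiac-phase (diastole/systole) variants;
* **outcome metrics** — reachability-based sclerosant filling (retrograde
  ingress + antegrade egress closure), the normalized rupture-risk
  statistic `ln(P_exp/P_min)/ln(P_max/P_min)·100 %`, and per-treatment
  animations;
* a **batch runner** with unpaired t-tests / one-way ANOVA, plus a thin
  `trenshsim` command-line interface (`generate`, `simulate`, `batch`,
  `stats`, `sweep`, `animate`).

## Worked example

`examples/03_trensh_filling.py` builds one stochastic AVM, then injects
sclerosant retrogradely through draining vein DV2 at three injection
pressures and three systemic pressure levels:

```
normo      filling at 10/20/30 mmHg via DV2:   0.0%    0.0%    1.3%
moderate   filling at 10/20/30 mmHg via DV2:   0.0%    5.7%   54.8%
profound   filling at 10/20/30 mmHg via DV2:  33.4%   74.7%   90.0%
```

At normotension the feeders' perfusion pressure keeps the sclerosant out of
the nidus almost entirely; under profound hypotension (mean arterial
pressure 25 mmHg) a 30-mmHg injection reverses the feeders and permeates
90 % of this architecture's 857 intranidal vessels. The other examples show
baseline hemodynamics (`01`, total nidal flow ≈ 349 mL/min for seed 1, with
the feeder→vein pressure cascade), generator variability (`02`), batch
statistics with a CVP-elevation t-test (`04`, p ≈ 0.001 at profound
hypotension), and treatment animation rendering (`05`).

The same functionality from the shell:

```bash
trenshsim generate --n 5 --seed 1 --out nets/
trenshsim batch --n-arch 10 --seed 1 --out results.csv
trenshsim stats --results results.csv --value pct_filling --factor cvp \
    --fixed hypotension=profound --fixed injection_mmHg=30.0 --fixed tbo=none
trenshsim animate --network nets/network_1.json --site DV2 --target 30 \
    --out-dir frames/ --stitch
```

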