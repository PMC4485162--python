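# xyleth

PBPK modelling of **m-xylene and ethanol co-exposure** in humans:
forward simulation of a coupled two-chemical physiologically based
pharmacokinetic model, time-resolved global sensitivity analysis, and
Bayesian calibration against biological-monitoring (BM) time series.

The package is written for toxicokinetic modellers and occupational-health
researchers who need to (a) predict venous-blood and end-exhaled m-xylene
and urinary 3-methylhippuric acid (3-MHA) during and after a controlled
inhalation exposure, (b) quantify which physiological and kinetic
parameters drive the variance of those predictions, and (c) tune the
sensitive, unmeasured parameters to measured BM data.

## The model

Two flow-limited PBPK models are interconnected at the liver, where both
chemicals compete for CYP2E1:

* **m-xylene** — inhalation uptake through a steady-state lung closure
  `C_art = (Q_alv·C_inh + QC·C_ven) / (Q_alv/P_ba + QC)`, four tissue
  groups (fat, rapidly perfused, slowly perfused, liver), hepatic
  Michaelis–Menten oxidation, and a **bladder compartment** that fills at
  the urine production rate and empties at the protocol's void times,
  producing the step-like urinary 3-MHA profile.
* **ethanol** — oral dosing into a stomach lumen whose emptying rate is
  itself inhibited by the ethanol load (sigmoidal `KE(A)` falling from
  `KE_max` to `KE_min`), first-order absorption into stomach/gut tissues
  draining via the portal circulation into the liver, and four saturable
  hepatic pathways (CYP2E1 + three ADH isoforms).

The interaction enters through the apparent Michaelis constants of
m-xylene oxidation, with the ethanol liver-venous concentration `I`:
competitive `Km(1 + I/KI)`, noncompetitive `Vmax/(1 + I/KI)`, or
uncompetitive (both scaled).  Whole-liver capacities come from in-vitro
rates by `Vmax[mg/h] = Vmax[pmol/min/mg] · 60 · MPY · m_liver · MW · 1e-9`,
where MPY is the microsomal protein yield (mg/g liver).

The analysis workflow mirrors how such models are developed: **Morris
elementary-effects screening** over the full 46-parameter prior space,
then **eFAST** main/total-effect indices (Si, STi) over time for each
monitored channel, summarised as Lowry plots; finally **random-walk
Metropolis MCMC** calibration of the sensitive parameters (MPY, the
m-xylene blood:air partition coefficient PBAXYL, and the inhibition
constant KI) under a lognormal error model.

## Worked example

```python
import numpy as np
import xyleth as xl

params = xl.ParameterSet.central()                  # published central values
scen0  = xl.default_study_scenario(with_ethanol=False, exposure_ppm=50)
scen1  = xl.default_study_scenario(with_ethanol=True,  exposure_ppm=50)

a = xl.simulate(params, scen0)
b = xl.simulate(params, scen1)
print(f"peak blood m-xylene: {a.obs.cv_xyl_umol.max():.2f} umol/L "
      f"(no ethanol) vs {b.obs.cv_xyl_umol.max():.2f} umol/L (0.8 g/kg ethanol)")
print(f"peak blood ethanol:  {b.obs.c_blood_eth.max():.0f} mg/L")
print("3-MHA voided by 8 h:  "
      f"{a.voids.query('t<=8').mha_mg.sum():.0f} mg vs "
      f"{b.voids.query('t<=8').mha_mg.sum():.0f} mg")
```

prints

```
peak blood m-xylene: 4.66 umol/L (no ethanol) vs 9.66 umol/L (0.8 g/kg ethanol)
peak blood ethanol:  1194 mg/L
3-MHA voided by 8 h:  325 mg vs 61 mg
```

i.e. prior ethanol ingestion roughly doubles circulating m-xylene and
delays the urinary appearance of its metabolite — the competitive-inhibition
signature the model is built around.  Calibration on a synthetic dataset:

```python
ds    = xl.generate_bm(params.copy(MPY=50.0), scen1, seed=7)   # noisy BM data
model = xl.PBPKCalibration(ds, base_params=params)
res   = model.fit(n_iter=5000, n_chains=2, seed=1)
print(res.summary())          # mean, sd, 95% interval, posterior mode, R-hat
```

A thin CLI wraps the same functions: `xyleth simulate`, `xyleth
sensitivity`, `xyleth calibrate`, `xyleth synth` (see `--help`).

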