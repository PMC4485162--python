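# Methods

This note documents the model, its parameterisation, the numerical and
statistical machinery, and the design decisions taken where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure

### m-xylene submodel

Four flow-limited tissue groups (adipose, rapidly perfused, slowly
perfused, liver) connected by cardiac output `QC = QCMC·BW^0.75`.  Gas
exchange uses the standard steady-state alveolar closure

    C_art = (Q_alv·C_inh + QC·C_ven) / (Q_alv/P_ba + QC),

with end-exhaled (alveolar) concentration `C_art/P_ba`; an optional
mixed-exhaled output adds 30 % dead-space inspired air (`DS = 0.3`),
because the monitored breath channel is end-tidal.  Tissue:blood partition
coefficients are tissue:air values divided by the measured blood:air
coefficient PBAXYL.  Metabolism is hepatic only, Michaelis–Menten on the
liver-venous concentration.  A fixed fraction `f_MHA` of metabolised
m-xylene appears (mass-scaled by MW_MHA/MW_xyl) in a 3-MHA body pool that
transfers to the bladder with first-order constant `K_1`; the bladder
fills with urine at `R_urine` and is emptied (recorded, then zeroed) at
each scheduled void.  Urinary concentration is reported per gram
creatinine using 113.12 mg/mmol.

### ethanol submodel

Six tissue groups (the four above plus stomach and gut tissue) and a
two-stage lumen.  The drink enters the stomach lumen at a constant rate
over the drinking interval; gastric emptying into the gut lumen is
inhibited by the ethanol load through a Hill function

    KE(A) = KE_min + (KE_max − KE_min) / (1 + (A/A50)^h),

with defaults A50 = 10 g and h = 2 chosen so that emptying is essentially
unimpaired for trace loads and strongly retarded at a full dose (no exact
published functional form was available for this mechanism; the Hill form
satisfies the required qualitative behaviour — bounded, strictly
decreasing in the load — and per-volunteer `Ke(max)` values can be
supplied directly).  Lumen ethanol is absorbed first-order (BELLYPERM, GIPERM)
into stomach/gut tissue, whose venous blood drains via the portal
circulation into the liver.  The hepatic flow fraction QLIC is **total**
liver flow; the arterial hepatic fraction is `QLIC − QSTC − QGUC`.  This
reading closes the circulation exactly (`QRPDC = 1 − QSPDC − QFAC − QLIC
= 0.48`, the printed value) and matches human portal physiology.  Liver
metabolism sums four saturable pathways (CYP2E1 and three ADH isoform
classes).  Ethanol tissue coefficients are tissue:blood surrogates used
directly.

### Coupling

The submodels interact only at the liver: the ethanol liver-venous
concentration is the inhibitor concentration `I` in the apparent
m-xylene kinetics — competitive `Km(1+I/KI)`, noncompetitive
`Vmax/(1+I/KI)`, uncompetitive both — with competitive as the default
mechanism.  With `I = 0` or `KI → ∞` all mechanisms collapse onto the
uninhibited model (verified to 1e-6 relative in the suite).

## Parameterisation

Central values and priors live in `src/xyleth/data/priors.yaml`
(46 varying parameters; fixed constants as point entries).  Noteworthy
choices:

* **In-vitro m-xylene Km** is stored as 11.8 µmol/L.  Read as mmol/L the
  whole-liver intrinsic clearance would be ~0.3 L/h against ~90 L/h of
  hepatic blood flow, metabolising under 1 % of absorbed m-xylene — which
  contradicts measurable urinary 3-MHA and the dominance of metabolic
  parameters in the outputs.  µM-scale CYP2E1 constants give ~75 %
  hepatic extraction.  The ethanol constants are genuinely mM-scale and
  stay so.
* **MPY prior**: lognormal, median 34 mg/g, log-sd 0.29 (≈30 % CV),
  consistent with reported between-individual variability of microsomal
  protein yield; the printed distribution for this parameter is not
  internally consistent and was re-derived.
* **VFAC prior**: lognormal, log-mean −1.59, log-sd 0.272 chosen to match
  the cohort's measured fat-fraction CV of 0.277; truncated at 0.6.
* Uniform bands re-centred where a printed band excluded its own central
  value (oral dose 800 mg/kg → U(640, 960); K_Mγγ → U(0.504, 0.756);
  QSTC → U(0.008, 0.012)), preserving the ±20 % width used throughout the
  ethanol table.
* Zero-truncation for all normal priors; fraction parameters additionally
  truncated at 1.
* External constants not in the source tables: ethanol density
  0.789 g/mL, creatinine molar mass 113.12 g/mol, gas molar volume
  24.45 L/mol at 25 °C, tissue density 1 kg/L, `f_MHA = 0.9`
  (3-MHA is the major but not sole metabolite; configurable).

Sampling a parameter set draws every varying parameter, then closes the
aggregated remainders — `QRPDC = 1 − (QSPDC+QFAC+QLIC)` and `VSPDC = VT −
(VRPDC+VFAC+VLIC)` — and rejects draws with a non-positive remainder or
portal flow exceeding total hepatic flow (the physiology derivation also
re-closes these sums for *any* parameter vector, so conservation holds for
every SA/MCMC evaluation, not just sampled sets).

## Numerics

State: 22 amounts (mg), volumes (L), hours.  The RHS is compiled with
numba.  Two drivers:

* **RK4** (default): fixed step, nominal `dt = 0.005 h`, capped at
  `2/λ_max` where `λ_max` is the fastest first-order rate constant implied
  by the parameter set (perfusion rates `Q/(V·P)`, low-concentration
  hepatic clearances `ΣVmax/Km` over the liver pool, lumen constants).
  The cap matters: at prior extremes the ethanol liver clearance rate
  reaches ~1400 h⁻¹ and an uncapped explicit step would cross the
  stability boundary and silently stall elimination.
* **LSODA** (scipy) as the adaptive stiff-capable reference, with
  `rtol = 1e-8`, `atol = 1e-10`.

Both drivers restart at every discontinuity (exposure on/off, the
drinking window, each void); inputs are constant within a segment.  The
suite checks RK4 against LSODA and against its own step-halving to
< 0.1 %, and mass balance of both chemicals and of the metabolite chain to
well below the 1e-3 contract.  The exposure window is half-open at the
start so samples taken at the nominal start time are pre-exposure.

## Global sensitivity analysis

Two phases, both operating on the priors' quantile scale so parameters
with different units are comparable; designs scan the 0.5th–99.5th
percentile band of each prior (the extreme tails of zero-truncated
normals are physiologically meaningless).

* **Morris screening**: r = 10 trajectories, p = 4 levels,
  Δ = p/(2(p−1)), elementary effects summarised as μ* (mean |EE|) and σ;
  outputs are the three monitored channels at their representative
  summary times (3/6 h for blood and breath, 6/10 h for urine).  The
  top-12 parameters by max μ* go forward; the rest are fixed at central
  values.
* **eFAST**: search curves `x(s) = 0.5 + arcsin(sin(ωs+φ))/π`, N = 257
  points per curve by default, M = 4 harmonics, Nr random-phase
  resamples.  The interest frequency is `ω_max = (N−1)/(2M+1)` — the
  margin below the classical `(N−1)/(2M)` keeps the M-th harmonic's
  sidebands under Nyquist, where they would otherwise alias straight back
  onto the harmonic and bias Si upward by interaction power (a one-line
  derivation that the Ishigami oracle exposed).  Complementary
  frequencies are ≤ ω_max/(2M) and coprime with ω_max.  Si sums spectral
  power at harmonics of ω_max; STi is one minus the complementary share.
  At very small N (≈65) STi retains an upward bias of order the
  complementary signal's high-harmonic content; Si is unbiased to ~0.006
  (the M-truncation floor).  Windows follow the phases of greatest
  change: 0–8 h for blood, 0–10 h for breath, 0–15 h for urine, on a
  0.25 h grid, one simulation per design point serving all channels and
  times.  Times with vanishing output variance report NaN indices.
* **Lowry data**: parameters ordered by STi; the cumulative plume is
  bounded below by ΣSi and above by min(ΣSTi, 1 − remaining Si).

Problem sizes (r = 10, N = 257, k = 12 → ≈3100 simulations per
configuration) are chosen so the full two-configuration analysis runs in
about a minute; N can be raised freely via the API/CLI.

## Calibration

`PBPKCalibration` (model) / `CalibrationResults` (results) follow the
model-object convention of the statistical-modelling ecosystem because
calibration genuinely is a fit of a model to data; the simulator and SA
stages remain plain functions.  The likelihood is lognormal per channel:
log-residuals are Gaussian with per-channel σ, estimated by default under
a U(0.01, 1.5) prior.  Below-LOD observations are dropped by default
(censored-at-LOD likelihood available); non-positive observations
(pre-exposure baselines) are uninformative under a lognormal model and
are excluded.  The calibrated set defaults to {MPY, PBAXYL, KI}: the
measured per-volunteer quantities (BW, VFAC, QPMC, R_urine, CREmmol) are
pinned, PBAXYL is calibrated despite being measured because blood:air
partitioning varies within and between days (e.g. with food), and KI is
calibrated because the literature in-vivo ethanol Km (575 mg/L) proved
far too weak an inhibition constant for this interaction — chains
therefore start at KI's prior central value (10 mg/L) inside its U(1, 20)
support.

The sampler is random-walk Metropolis on log-parameters (Jacobian
included).  During burn-in only (default 30 % of the chain) the proposal
adapts twice over: a global factor is tuned toward 30 % acceptance and
the per-parameter scale profile is re-estimated from the empirical spread
of the burn-in samples (diagonal adaptive Metropolis) — without the
latter, parameters with very different posterior widths share one
compromise step and the chains mix poorly (split-R̂ well above 1.1 in
replicate experiments; ≤1.07 with it).  ≥2 chains, fully reproducible
from a seed.  The posterior mode is the argmax over the stored trace;
rank-normalised split-R̂ and bulk ESS come from ArviZ.  A 5000-iteration,
2-chain fit costs tens of seconds because the likelihood only requires
the observation-time solution.

## Synthetic biological monitoring

The generator simulates a scenario, samples the protocol schedules
(blood 0–23 h, breath 0–24 h, urine voids 0–31 h), multiplies each value
by lognormal noise `exp(σZ)` with `σ = sqrt(ln(1+cv²))` (median-unbiased,
matching the calibration error model exactly), flags values below the
assay LODs (blood 0.1 µmol/L; urine 40 µmol/L converted through the
individual's creatinine), and can blank whole channels to reproduce the
campaign's missingness (most no-ethanol-day blood samples were lost;
only volunteers A, C, D retain that channel).  Channel CVs combine the
published intra- and inter-assay components in quadrature; the breath
channel has no published CV and uses 0.10 by assumption.  What passing
tests on these data show is that the *pipeline* is correct and the
parameters identifiable under the stated error model; they cannot show
that the model structure matches real human kinetics (no model
discrepancy, no within-day physiological drift, no assay drift is
emulated).

The virtual-cohort generator draws physiology from the measured cohort's
means/SDs (normal, or lognormal for the fat fraction) with BMI
accept-rejected into the 18.5–30 plausibility range.

## Acceptance experiment sizes

The acceptance script and suite use: Ishigami oracle at N = 1025, Nr = 5;
Morris oracle r = 10; 50 random parameter sets for conservation; the
two-phase SA at (r = 10, N = 257, k = 12); recovery at 3000 iterations ×
2 chains, with a 5-replicate coverage check at 10 % noise (the full
20-replicate experiment is a one-line loop over
`xyleth.calibration.recover_parameters`).

## Known limitations

* No extrahepatic metabolism, no dermal/oral m-xylene routes, single
  xylene isomer, volunteers at rest (no workload-dependent ventilation).
* 3-MHA formation is a fixed-fraction single step; intermediate
  metabolites have no kinetics of their own, so `K_1` absorbs the delay
  of the whole conjugation chain.
* The bladder empties at the scheduled void times, not by volume.
* End-exhaled air assumes instant alveolar–arterial equilibrium; the
  mixed-exhaled output is provided because end-tidal sampling tends to
  read lower than the alveolar prediction.
* The liver-volume fraction prior (printed N(0.036, 0.01²), 28 % CV) is
  broad and structurally degenerate with MPY in the scaled Vmax, so
  variance attribution between the two is partly a convention of the
  prior table.
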