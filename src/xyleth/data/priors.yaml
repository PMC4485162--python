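# Parameter catalogue for the coupled m-xylene + ethanol PBPK model.
#
# Each entry: central value (deterministic simulations), prior family and
# parameters (population variability for SA / calibration), unit, and which
# submodel it belongs to (shared / xylene / ethanol).
#
# family:
#   point     -> fixed constant (no variability)
#   normal    -> {mean, sd}, truncated to (lower, upper) if given
#   lognormal -> {mu, sigma} on the log scale, truncated if given
#   uniform   -> {lower, upper}
#   derived   -> computed by mass/flow rebalancing, never sampled directly
#
# Notes on in-vitro metabolic constants: Km values carry their concentration
# unit explicitly (umol/L for the xylene pathway, mmol/L for the four ethanol
# pathways); Vmax values are pmol/min/mg microsomal protein and are scaled to
# whole-liver mg/h via MPY and liver mass (IVIVE).
version: 1
parameters:
  # ---- shared anatomical / physiological (Table: common constants) ----
  MW_xyl:      {central: 106.17, unit: g/mol, family: point, group: shared}
  MW_MHA:      {central: 193.2,  unit: g/mol, family: point, group: shared}
  MW_eth:      {central: 46.07,  unit: g/mol, family: point, group: ethanol}
  BW:          {central: 76.2, unit: kg, family: normal, mean: 76.2, sd: 8.73, lower: 0.0, group: shared}
  VT:          {central: 0.91, unit: fraction of BW, family: point, group: shared}
  QCMC:        {central: 13.8, unit: L/h/kg^0.75, family: normal, mean: 13.8, sd: 2.5, lower: 0.0, group: shared}
  MPY:         {central: 34.0, unit: mg microsomal protein / g liver, family: lognormal, mu: 3.5264, sigma: 0.29, group: shared}
  QPMC:        {central: 390.4, unit: L/h, family: normal, mean: 390.4, sd: 54.9, lower: 0.0, group: shared}
  DS:          {central: 0.3, unit: fraction of respiration, family: point, group: shared}
  # flows, fractions of cardiac output; QRPDC is rebalanced to close the sum
  QRPDC:       {central: 0.48, unit: fraction of QC, family: derived, group: shared}
  QSPDC:       {central: 0.22, unit: fraction of QC, family: uniform, lower: 0.2, upper: 0.35, group: shared}
  QFAC:        {central: 0.05, unit: fraction of QC, family: normal, mean: 0.053, sd: 0.003, lower: 0.0, upper: 1.0, group: shared}
  QLIC:        {central: 0.25, unit: fraction of QC, family: normal, mean: 0.271, sd: 0.01, lower: 0.0, upper: 1.0, group: shared}
  # volumes, fractions of body mass; VSPDC is rebalanced to close the sum
  VRPDC:       {central: 0.09, unit: fraction of BW, family: point, group: shared}
  VSPDC:       {central: 0.604, unit: fraction of BW, family: derived, group: shared}
  VFAC:        {central: 0.19, unit: fraction of BW, family: lognormal, mu: -1.59, sigma: 0.2719, upper: 0.6, group: shared}
  VLIC:        {central: 0.0257, unit: fraction of BW, family: normal, mean: 0.036, sd: 0.01, lower: 0.0, upper: 1.0, group: shared}
  R_urine:     {central: 0.07, unit: L/h, family: normal, mean: 0.083, sd: 0.021, lower: 0.0, group: shared}
  CREmmol:     {central: 12.5, unit: mmol/L, family: normal, mean: 12.5, sd: 2.7, lower: 0.0, group: shared}
  K_1:         {central: 20.0, unit: 1/h, family: uniform, lower: 5.0, upper: 20.0, group: shared}

  # ---- m-xylene specific ----
  K_M2E1xyl:   {central: 11.8, unit: umol/L, family: normal, mean: 11.8, sd: 1.4, lower: 0.0, group: xylene}
  V_max2E1xyl: {central: 895.0, unit: pmol/min/mg, family: normal, mean: 895.0, sd: 68.0, lower: 0.0, group: xylene}
  KI:          {central: 10.0, unit: mg/L, family: uniform, lower: 1.0, upper: 20.0, group: xylene}
  PBAXYL:      {central: 18.5, unit: blood:air, family: normal, mean: 18.5, sd: 4.9, lower: 0.0, group: xylene}
  PRPDAXYL:    {central: 117.0, unit: tissue:air, family: uniform, lower: 50.0, upper: 150.0, group: xylene}
  PSPDAXYL:    {central: 53.0, unit: tissue:air, family: uniform, lower: 40.0, upper: 80.0, group: xylene}
  PFAAXYL:     {central: 1874.0, unit: tissue:air, family: uniform, lower: 1400.0, upper: 2200.0, group: xylene}
  PLIAXYL:     {central: 279.0, unit: tissue:air, family: uniform, lower: 150.0, upper: 350.0, group: xylene}

  # ---- ethanol specific ----
  # oral dose in mg/kg body mass (0.8 g/kg protocol dose); band is +/-20%
  PORALDOSE:   {central: 800.0, unit: mg/kg, family: uniform, lower: 640.0, upper: 960.0, group: ethanol}
  DRINKTIME:   {central: 0.25, unit: h, family: uniform, lower: 0.2, upper: 0.3, group: ethanol}
  DRINKVOL:    {central: 0.5, unit: L, family: uniform, lower: 0.4, upper: 0.6, group: ethanol}
  BELLYPERM:   {central: 0.685, unit: 1/h, family: uniform, lower: 0.548, upper: 0.822, group: ethanol}
  GIPERM:      {central: 21.1, unit: 1/h, family: uniform, lower: 20.8, upper: 30.12, group: ethanol}
  KE_max:      {central: 10.2, unit: 1/h, family: uniform, lower: 8.16, upper: 12.24, group: ethanol}
  KE_min:      {central: 0.005, unit: 1/h, family: uniform, lower: 0.004, upper: 0.006, group: ethanol}
  VSTC:        {central: 0.02, unit: fraction of BW, family: uniform, lower: 0.016, upper: 0.024, group: ethanol}
  VGUC:        {central: 0.085, unit: fraction of BW, family: uniform, lower: 0.068, upper: 0.102, group: ethanol}
  # +/-20% band re-centred on the printed central value
  QSTC:        {central: 0.01, unit: fraction of QC, family: uniform, lower: 0.008, upper: 0.012, group: ethanol}
  QGUC:        {central: 0.17, unit: fraction of QC, family: uniform, lower: 0.136, upper: 0.204, group: ethanol}
  K_M2E1eth:   {central: 12.5, unit: mmol/L, family: uniform, lower: 9.98, upper: 14.9, group: ethanol}
  V_max2E1eth: {central: 12060.0, unit: pmol/min/mg, family: uniform, lower: 9649.0, upper: 14473.0, group: ethanol}
  K_Maa:       {central: 4.2, unit: mmol/L, family: uniform, lower: 3.36, upper: 5.04, group: ethanol}
  V_maxaa:     {central: 18327.0, unit: pmol/min/mg, family: uniform, lower: 14661.0, upper: 21993.0, group: ethanol}
  K_Mbb:       {central: 0.05, unit: mmol/L, family: uniform, lower: 0.04, upper: 0.06, group: ethanol}
  V_maxbb:     {central: 5934.0, unit: pmol/min/mg, family: uniform, lower: 4747.0, upper: 7121.0, group: ethanol}
  # band widened so it brackets the central value (+/-20%)
  K_Mgg:       {central: 0.63, unit: mmol/L, family: uniform, lower: 0.504, upper: 0.756, group: ethanol}
  V_maxgg:     {central: 11895.0, unit: pmol/min/mg, family: uniform, lower: 9516.0, upper: 14274.0, group: ethanol}
  Pba_eth:     {central: 1265.0, unit: blood:air, family: uniform, lower: 1012.0, upper: 1518.0, group: ethanol}
  # ethanol tissue partition coefficients are tissue:blood (rat surrogates)
  Prpda_eth:   {central: 0.95, unit: tissue:blood, family: uniform, lower: 0.76, upper: 1.14, group: ethanol}
  Pspda_eth:   {central: 0.80, unit: tissue:blood, family: uniform, lower: 0.64, upper: 0.96, group: ethanol}
  Pfaa_eth:    {central: 0.11, unit: tissue:blood, family: uniform, lower: 0.088, upper: 0.132, group: ethanol}
  Plia_eth:    {central: 0.81, unit: tissue:blood, family: uniform, lower: 0.648, upper: 0.972, group: ethanol}
  Pst_eth:     {central: 0.81, unit: tissue:blood, family: uniform, lower: 0.648, upper: 0.972, group: ethanol}
  PGU_eth:     {central: 0.81, unit: tissue:blood, family: uniform, lower: 0.648, upper: 0.972, group: ethanol}

  # ---- model constants not listed in the source tables ----
  # fraction of metabolised m-xylene excreted in urine as 3-MHA
  f_MHA:       {central: 0.9, unit: fraction, family: point, group: xylene}
  # gastric-peristalsis inhibition: half-inhibition stomach load and steepness
  A50_gastric: {central: 10000.0, unit: mg ethanol in stomach, family: point, group: ethanol}
  hill_gastric: {central: 2.0, unit: dimensionless, family: point, group: ethanol}
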