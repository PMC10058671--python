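# Single-analyte minimal PBPK model of pyronaridine in the golden hamster.
# Physiology: measured/literature volumes (mL) and flows (mL/h); V_rest and
# Q_rest are derived, Q_trachea is 2.1% of cardiac output.
# Disposition: fitted biochemical parameters (CL/F in L/h).

[physiology]
V_total = 102.01
V_blood = 7.20
V_lung = 0.48
V_trachea = 0.06
Q_co = 1181.28
trachea_co_fraction = 0.021

[parent]
k_a = 0.03
CL_F = 0.21
K_lung = 26.06
K_trachea = 8.67
K_rest = 5.25e-7
k_tl = 1.01
k_lt = 0.92

[options]
kind = "single"
unit_mode = "mass_ng"
parent_name = "pyronaridine"

[[regimen]]
label = "low"
dose_per_kg = 180.0
body_weight = 0.10201
n_doses = 3
interval_tau = 24.0

[[regimen]]
label = "high"
dose_per_kg = 360.0
body_weight = 0.10201
n_doses = 3
interval_tau = 24.0
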