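# Parent-metabolite minimal PBPK model: artesunate and its active
# metabolite dihydroartemisinin in the golden hamster.  Molar units
# (amounts nmol, concentrations nmol/L); the parent clearance converts
# artesunate to dihydroartemisinin mole-for-mole in blood.

[physiology]
V_total = 102.01
V_blood = 7.20
V_lung = 0.48
V_trachea = 0.06
Q_co = 1181.28
trachea_co_fraction = 0.021

[parent]
k_a = 1.74
CL_F = 2517.70
K_lung = 10.33
K_trachea = 1.48
K_rest = 1.32
k_tl = 1.50
k_lt = 0.34
K_bp = 0.75

[metabolite]
CLm_F = 10.33
K_lung_m = 0.34
K_trachea_m = 1.08
K_rest_m = 1.21
k_tl_m = 6.98
k_lt_m = 0.35
K_bp_m = 0.75

[options]
kind = "parent_metabolite"
unit_mode = "molar_nmol"
metabolite_trachea_form = "as_printed"
parent_name = "artesunate"
metabolite_name = "dihydroartemisinin"

[[regimen]]
label = "low"
dose_per_kg = 60.0
body_weight = 0.10201
n_doses = 3
interval_tau = 24.0

[[regimen]]
label = "high"
dose_per_kg = 120.0
body_weight = 0.10201
n_doses = 3
interval_tau = 24.0
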