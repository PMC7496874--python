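# Fat-reserves model: roach-like consumer with an irreversible/reversible
# mass split, feeding on two zooplankton-like food sources.  Masses in g,
# densities in mg/L, rates per day.
#
# This preset is a calibrated parameterization, not a transcription of a
# published table.  It is tuned so the model operates in the reference
# regime for amphibian-like metamorphosis loss: a metamorphosing CSS with
# psi_L pinned at 0 across supply rates delta*X1_max in ~[0.0015, 0.01]
# mg/L/day at delta*X2_max = 0.0165, loss of metamorphosis via
# internalization near delta*X1_max ~ 0.0013, extinction of the
# metamorphosing branch without internalization at delta*X2_max = 0.0066,
# and loss of evolutionary stability of the direct-development strategy
# near delta*X1_max ~ 0.008.
delta: 0.1
X1_max: 0.03
X2_max: 0.165
w_min: 0.01
w_A: 0.5
A1_max: 230.0
A2_max: 2000.0
w_opt1: 0.05
w_opt2: 1.5
alpha1: 1.0
alpha2: 1.3
spec_exponent: 1.0
xi1: 0.01
xi2: 0.75
kappa_e: 0.5
food_to_mass: 0.001
maint_coef: 0.01
q_ratio: 0.74
q_starv: 0.2
kappa_adult: 0.0
egg_overhead: 0.008
egg_cost_per_gram: 1.5
rho: 0.2
meta_loss: 0.3
mu_larva: 0.02
mu_juvenile: 0.02
mu_adult: 0.02
mu_larval_habitat: 0.0
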