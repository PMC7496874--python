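# Deliberately symmetric two-resource configuration: identical supply,
# attack and hump parameters for both foods and no metamorphosis costs.
# With theta = 0, w_J < w_b (no metamorphosis event) and the mass traits
# frozen, the single evolving trait psi_L has its singular value at
# exactly 0.5 by the resource-exchange symmetry.
delta: 0.1
X1_max: 0.1
X2_max: 0.1
w_min: 0.0
w_A: 0.5
A1_max: 800.0
A2_max: 800.0
w_opt1: 0.3
w_opt2: 0.3
alpha1: 1.0
alpha2: 1.0
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
rho: 0.0
meta_loss: 0.0
mu_larva: 0.02
mu_juvenile: 0.02
mu_adult: 0.02
mu_larval_habitat: 0.0
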