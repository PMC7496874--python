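# Generic size-structured model parameterized for invertebrate-like
# consumers: body masses a fifth of the fat-reserves preset, most of the
# body treated as a single (mostly reversible) mass pool so that the
# metamorphic loss acts on nearly the whole body, and the same hump/
# handling shapes.  Qualitative behavior mirrors the fat-reserves preset.
delta: 0.1
X1_max: 0.03
X2_max: 0.165
w_min: 0.002
w_A: 0.1
A1_max: 46.0
A2_max: 400.0
w_opt1: 0.01
w_opt2: 0.3
alpha1: 1.0
alpha2: 1.3
spec_exponent: 1.0
xi1: 0.01495
xi2: 0.75
kappa_e: 0.5
food_to_mass: 0.001
maint_coef: 0.01
q_ratio: 4.0
q_starv: 0.2
kappa_adult: 0.0
egg_overhead: 0.0016
egg_cost_per_gram: 1.5
rho: 0.2
meta_loss: 0.3
mu_larva: 0.025
mu_juvenile: 0.025
mu_adult: 0.025
mu_larval_habitat: 0.0
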