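"""Locate and classify the metamorphosing singular strategy.

Finds the 4-trait strategy with vanishing selection gradient at the
default supply rates and classifies it (convergence + evolutionary
stability).  Larvae end up fully specialized on the primary food
(psi_L pinned at 0) with offspring mass below the secondary-food access
threshold: the classic metamorphosing life cycle.
"""

from metamorph import TraitVector, find_singular, load_preset

params = load_preset("fat_reserves")
s = find_singular(TraitVector(0.0, 1.0, 0.025, 0.006), params)

t = s.traits
print(f"singular strategy: psi_L={t.psi_L:.3f} theta={t.theta:.3f} "
      f"w_J={t.w_J:.4f} g  w_b={t.w_b:.5f} g")
print(f"classification: {s.classification}")
print(f"pinned at a trait-box edge: {list(s.pinned)}")
print(f"mutant Hessian eigenvalues: {s.hessian_eigs}")
print(f"gradient Jacobian eigenvalues: {s.jacobian_eigs.real}")
print(f"environment: X1*={s.environment.X1:.4f}, X2*={s.environment.X2:.4f}")
# Negative Hessian eigenvalues: no nearby mutant can invade; negative
# Jacobian eigenvalues: gradual evolution converges here (a CSS).  psi_L
# and theta sit on box edges with outward selection, hence "boundary-".
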