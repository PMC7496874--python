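"""Track the CSS while the larval habitat deteriorates.

Continues the metamorphosing singular strategy toward lower supply rates
of the primary (larval) food source.  Offspring mass rises, the mass at
metamorphosis falls, metamorphosis happens ever earlier -- until the
newborn mass reaches the post-metamorphic mass and the life cycle
internalizes metamorphosis: direct development evolves.
"""

from metamorph import TraitVector, continue_in_parameter, load_preset

params = load_preset("fat_reserves")  # delta*X2_max = 0.0165 (high)
curve = continue_in_parameter(
    TraitVector(0.0, 1.0, 0.03, 0.005), params, "X1_max",
    stop=0.008, step=0.003)

df = curve.to_frame()
df["supply_1"] = params.delta * df["X1_max"]
print(df[["supply_1", "w_b", "w_J", "age_at_metamorphosis", "b"]]
      .to_string(index=False, float_format=lambda v: f"{v:.5g}"))
lo, hi = curve.terminal_bracket
print(f"\nterminal event: {curve.terminal_event}")
print(f"metamorphosis is lost at delta*X1_max ~ "
      f"{params.delta * 0.5 * (lo + hi):.5f} mg/L/day")
# Each row is one evolutionary endpoint at a fixed supply rate; w_b
# (offspring mass) grows as supply falls while w_J shrinks, so the larval
# stage contracts until it disappears before birth.
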