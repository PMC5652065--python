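"""Equilibrium structure of the bistable deterministic chemostat.

Builds the substrate-inhibited chemostat with a dilution rate above the
break-even growth rate at the input concentration, so the washout state is
locally stable, yet two interior equilibria (a stable node and a saddle)
still exist: the culture's fate depends on where it starts.
"""

from stochemostat import all_equilibria, break_even_input, preset

pr = preset("bistable")
p = pr.params

print(f"dilution rate Q = {p.Q}, break-even growth rate mu(S0) = "
      f"{break_even_input(p):.4f}")
print("Q > mu(S0): washout is locally attracting, but not globally.\n")

for eq in all_equilibria(p):
    print(f"{eq.kind:<9} (S*, x*) = ({eq.S:.4f}, {eq.x:.4f})  -> {eq.stability}")

print("\nThe saddle's stable manifold separates initial conditions that "
      "reach the interior node (successful culture) from those that wash out.")
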