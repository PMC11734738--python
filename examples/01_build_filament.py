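"""Build a toy two-protofilament amyloid stack with disordered N-terminal
tails and work out its counterion requirement."""

from fuzzycoat.synth import (AB42_SEQUENCE, ToyFilamentSpec, build_toy_filament,
                             counterions_to_neutralize, formal_charge)
from fuzzycoat.model import write_pdb

spec = ToyFilamentSpec(n_chains_per_protofilament=12, n_protofilaments=2,
                       core_range=(9, 42), tail_range=(1, 8),
                       sequence=AB42_SEQUENCE, seed=0)
model = build_toy_filament(spec)
write_pdb("filament.pdb", model)

q = formal_charge(AB42_SEQUENCE)
n_ions, sign = counterions_to_neutralize(AB42_SEQUENCE, spec.n_chains)
print(f"chains: {len(model.chains)}  atoms: {model.n_atoms}")
print(f"formal charge per chain at neutral pH: {q:+d}")
print(f"counterions to neutralize {spec.n_chains} chains: "
      f"{n_ions} monovalent {'cations' if sign > 0 else 'anions'}")
# 24 chains at −3 each need +72: the charge the solvated system must absorb
# before any dynamics can be run.
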