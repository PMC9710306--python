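"""Build a collinear atom-exchange toy system and survey its reactive surface.

The system is A-B + C -> A + B-C on a pairwise-Morse potential (Cl-H + Br
by default).  The brute-force grid oracle maps the 2-D collinear surface
over (r_AB, r_BC), finds both wells and the minimax saddle between them,
and the resulting barrier is the number the full workflow must reproduce.
"""

from iacta import make_collinear_exchange

spec = make_collinear_exchange()  # symmetric Morse parameters
oracle = spec.oracle

print(f"system: {spec.label}")
print(f"reactant species: {spec.reactant_smiles}   product species: {spec.product_smiles}")
for name, ((r1, r2), e) in [("reactant well", oracle.reactant_well),
                            ("product well ", oracle.product_well)]:
    print(f"{name}: r_AB = {r1:.3f} A, r_BC = {r2:.3f} A, E = {e:.6f} Hartree")
r1, r2 = oracle.saddle_point
print(f"saddle       : r_AB = {r1:.3f} A, r_BC = {r2:.3f} A, E = {oracle.saddle_energy:.6f} Hartree")
print(f"barrier      : {oracle.barrier_kcal:.2f} kcal/mol above the reactant well")
print(f"reaction energy: {oracle.reaction_energy_kcal:+.2f} kcal/mol (symmetric -> ~0)")

# an asymmetric variant deepens the product bond: exothermic exchange
asym = make_collinear_exchange(asymmetry=0.3)
print(f"\nwith a 30% deeper product bond: barrier {asym.oracle.barrier_kcal:.2f} kcal/mol, "
      f"reaction energy {asym.oracle.reaction_energy_kcal:+.2f} kcal/mol")
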