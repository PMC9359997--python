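"""Is anaerobic oxidation of ethanol to acetate thermodynamically feasible?

Evaluates ethanol + H2O -> acetate- + H+ + 2 H2 at 310.15 K under the
shipped formation-energy constants, first at unit activities and then with
hydrogen drawn down as a syntrophic partner would.
"""

from acetotrace.thermo import delta_g, delta_g0_prime, ethanol_to_acetate, feasibility

rxn = ethanol_to_acetate()
print("ethanol + H2O -> acetate- + H+ + 2 H2 at 310.15 K")
print(f"  dG0' = {delta_g0_prime(rxn):+.2f} kJ/mol")
print(f"  dG (all activities 1) = {delta_g(rxn):+.2f} kJ/mol -> {feasibility(rxn)}")

for h2 in (1e-3, 1e-5):
    rxn_low = ethanol_to_acetate(activities={"H2": h2})
    print(
        f"  dG (H2 at {h2:g} bar)   = {delta_g(rxn_low):+.2f} kJ/mol -> "
        f"{feasibility(rxn_low)}"
    )

print(
    "\nPositive dG at standard hydrogen pressure means gut anaerobes cannot\n"
    "oxidise ethanol to acetate on their own; the conversion only becomes\n"
    "exergonic if H2 is kept very low by a hydrogen-consuming partner."
)
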