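"""Fragment-ion arithmetic: residue masses, series offsets, adducts.

Computes singly charged fragment m/z values for the lysozyme N-terminal
peptide KVFGRC under different ion series and adducts. The +Na/+H gap
is constant (21.98194 Da) and extending a fragment by one residue moves
any series by exactly that residue's mass — the two invariants that
make ladder reading work.
"""

from orbitag import default_table, fragment_mz, residue_mass

table = default_table()

print("residue masses (Da):")
for code in ("G", "A", "J", "K", "Q", "W"):
    print(f"  {code}: {residue_mass(code, table):.5f}")

peptide = "KVFGRC"
print(f"\nfragments of {peptide} (singly charged):")
for series in ("b", "a", "c", "y", "z+1"):
    row = ", ".join(
        f"{adduct}: {fragment_mz(peptide, series, adduct, table):.5f}"
        for adduct in ("+H", "+Na")
    )
    print(f"  {series:>4}  {row}")

gap = fragment_mz(peptide, "b", "+Na", table) - fragment_mz(peptide, "b", "+H", table)
print(f"\n+Na minus +H, any series: {gap:.5f} Da")
ext = fragment_mz(peptide + "E", "b", "+Na", table) - fragment_mz(peptide, "b", "+Na", table)
print(f"adding E to the chain moves b by: {ext:.5f} Da (= residue mass of E)")
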