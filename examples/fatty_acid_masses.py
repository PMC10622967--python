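"""Compute the chemistry behind the target panel.

Builds each fatty acid's formula from its C:D label, derives the
deprotonated-ion m/z observed in negative mode, and predicts the CO2-loss
fragment used for PRM identity confirmation.  The printed table should
match the published retention-time library's m/z column at its printed
precision.
"""

from vlcpufa import fragment_mz, load_reference_panel, mz_deprotonated, parse_species
from vlcpufa.chem import formula

panel = load_reference_panel()
print(f"{'species':10s} {'formula':10s} {'[M-H]- m/z':>12s} {'published':>10s} {'-CO2 frag':>11s}")
for _, row in panel.iterrows():
    sp = row["species"]
    f = formula(sp)
    frag = fragment_mz(sp, 0)
    printed = f"{row['mz_printed']:.4f}" if row["mz_printed"] == row["mz_printed"] else "--"
    print(
        f"{row['species_label']:10s} C{f['C']}H{f['H']}O{f['O']:<4d}"
        f" {mz_deprotonated(sp):12.4f} {printed:>10s} {frag:11.4f}"
    )

# the CH2 ladder that appears at increased collision energy
sp = parse_species("32:6")
ladder = [fragment_mz(sp, k) for k in range(4)]
print("\n32:6 fragment ladder (CO2 loss, then successive CH2 losses):")
print("  " + " -> ".join(f"{mz:.4f}" for mz in ladder))
print("  spacing:", round(ladder[0] - ladder[1], 4), "Th (nominal 14 Da, one CH2)")
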