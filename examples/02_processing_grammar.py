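"""Apply the prohormone-processing grammar to a precursor segment.

The starfish bombesin-type precursor yields a 14-residue amidated
peptide whose internal Arg-Arg pair can be cleaved again, giving a
10-residue C-terminal fragment — both are real products detected by
mass spectrometry in radial nerve extracts.
"""

from bombemine.annotate import derive_peptides, find_cleavage_sites

protein = "M" + "KR" + "EPRRNYNRVFGPTYG" + "KR" + "A"
sites = find_cleavage_sites(protein, dibasic_set=("KR", "RR"))
print(f"cleavage sites: {[(s.basic_pair, s.position) for s in sites]}")

for pep in derive_peptides(protein, None, sites, min_len=4, max_len=40):
    mods = []
    if pep.pyroglutamate:
        mods.append("pGlu")
    if pep.amidated:
        mods.append("amide")
    role = f"truncation of {pep.parent_peptide}" if pep.parent_peptide \
        else "full peptide"
    print(f"  {pep.sequence:18s} {len(pep):2d} aa  "
          f"[{', '.join(mods) or 'unmodified'}]  ({role})")

print()
print("The trailing Gly of each segment is consumed by amidation; the")
print("dibasic pairs are excised by convertase + carboxypeptidase action.")
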