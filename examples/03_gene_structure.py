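"""Recover exon/intron structure by spliced alignment.

Builds a synthetic three-intron gene emulating the echinoderm
bombesin-type precursor genes (a phase-1 intron inside the
peptide-coding region, a phylum-specific phase-0 intron, and a phase-0
intron near the 3' end), then recovers the structure from the cDNA and
genomic sequence alone.
"""

from bombemine.genestruct import intron_phases, spliced_align
from bombemine.synthetic import make_gene, make_precursor, reverse_translate

rec, truth = make_precursor(seed=3)
cds = reverse_translate(rec.residues)
L = len(cds)
intron_spec = [(22, 1, 40), ((L // 2) - (L // 2) % 3, 0, 35),
               ((L - 18) - (L - 18) % 3, 0, 72)]
genomic, truth_model, cdna = make_gene(cds, intron_spec, seed=3)

model = spliced_align(cdna, genomic.residues, cds=(40, L))
print(f"recovered exons: {model.exons}")
print(f"exact match to planted structure: {model.exons == truth_model.exons}")
for k, intron in enumerate(intron_phases(model, genomic.residues), 1):
    print(f"  intron {k}: {intron.length} nt, "
          f"{intron.donor_motif}...{intron.acceptor_motif}, "
          f"phase {intron.phase}")
print()
print("Phase = CDS nucleotides upstream mod 3. A shared phase-1 intron")
print("inside the peptide-coding region is a classical orthology marker.")
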