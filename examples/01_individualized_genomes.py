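"""Build individualized parental genomes and translate coordinates.

Constructs a toy reference, applies one parent's homozygous SNPs and
indels, and shows how positions and annotations move between the reference
frame and the individualized frame.
"""

from allelescope.genomes import (
    DELETED, INSERTED, VariantRecord, build_individualized_genome,
)

reference = {"chr1": "ACGTACGTACGTACGTACGT"}
variants = [
    VariantRecord("chr1", 2, "G", "T"),       # SNP
    VariantRecord("chr1", 5, "C", "CAA"),     # 2 bp insertion
    VariantRecord("chr1", 11, "TAC", "T"),    # 2 bp deletion
]

genome = build_individualized_genome(reference, variants, sample_id="sire")
print(f"reference      : {reference['chr1']} ({len(reference['chr1'])} bp)")
print(f"individualized : {genome.sequences['chr1']} "
      f"({len(genome.sequences['chr1'])} bp)")
print(f"variants applied: {genome.n_variants_applied}")

cm = genome.map.chroms["chr1"]
for ref_pos in (0, 4, 8, 12, 15):
    f = cm.forward(ref_pos)
    label = "deleted" if f is DELETED else f
    print(f"reference {ref_pos:>2} -> individualized {label}")
for ind_pos in (6, 7, 10):
    b = cm.back(ind_pos)
    label = "inserted" if b is INSERTED else b
    print(f"individualized {ind_pos:>2} -> reference {label}")

# The insertion adds +2 and the deletion removes -2: length is conserved
# exactly, and every surviving base round-trips to itself.
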