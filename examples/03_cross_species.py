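"""Classify editing-site conservation across three species.

A shared gene is aligned codon-aware (protein-level global alignment,
back-threaded to nucleotides) and every column edited in at least one
species is classified: edited in all, T in the non-editing species (the
dominant mode of editing-site loss), A/G there, or an unedited C.
"""

from mitoedit import HomologSet, SplicedCDS, classify_alignment, conservation_summary


def cds_of(name, seq):
    return SplicedCDS(name, seq, [(name, i + 1, "+") for i in range(len(seq))])


#                      M  A  P  C  L  K
seq_a = "ATGGCACCTTGCCTAAAA"          # reference species, edited at 7 and 13
seq_b = "ATGGCATCTTGCCTAAAA"          # position 7 already T: editing lost
seq_c = "ATGGCACCTTGCCTAAAA"          # position 7 unedited C; edited at 13

homologs = HomologSet(
    gene_name="demo",
    cds={"species_a": cds_of("demo", seq_a),
         "species_b": cds_of("demo", seq_b),
         "species_c": cds_of("demo", seq_c)},
    editing_positions={"species_a": {7, 13},
                       "species_b": {13},
                       "species_c": {13}},
)

columns = classify_alignment(homologs)
for col in columns:
    print(f"column {col.column}: {dict(col.residues)} edited in "
          f"{sorted(col.edited_species)} -> {col.category}")

summary = conservation_summary(columns)
print(f"\ntotal edited positions: {summary['total_edited_positions']}")
for cls, frac in summary["fractions"].items():
    print(f"  {cls:15s} {frac:.2f}")

# Column 13 is edited in every species (edited_all).  At column 7 one
# non-editing species carries T (the edited product hard-wired in the
# genome) while the other still carries a C it does not edit; since an
# unedited C is present, the column is classified unedited_C.
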