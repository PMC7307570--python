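"""Compute dEN/dES for a toy gene by hand-checkable counts.

Every cytosine in the CDS is a potential C-to-U editing site, classified
synonymous or nonsynonymous by substituting T and translating.  Observed
edits are classified the same way; dEN/dES = (EN/N) / (ES/S).
"""

from mitoedit import SplicedCDS, annotate_effect, count_potential_sites, den_des
from mitoedit.calling import EditingSite


def cds_of(name, seq):
    return SplicedCDS(name, seq, [(name, i + 1, "+") for i in range(len(seq))])


#            M  T  P  H  S  *
cds = cds_of("toy", "ATGACCCCTCATTCATAA")
potential = count_potential_sites(cds, "C_to_U")
print(f"CDS {cds.sequence} ({len(cds) // 3} codons)")
print(f"potential nonsynonymous C sites (N): {potential.N} "
      f"at {sorted(potential.nonsynonymous_positions)}")
print(f"potential synonymous C sites    (S): {potential.S} "
      f"at {sorted(potential.synonymous_positions)}")

# two observed edits: ACC->ACT (codon 2, synonymous) and CAT->TAT (codon 4)
observed = [
    EditingSite("toy", 6, "toy", 6, "+", "C", "T", "C_to_U", {"s1": (40, 0.8)}),
    EditingSite("toy", 10, "toy", 10, "+", "C", "T", "C_to_U", {"s1": (55, 0.6)}),
]
effects = [annotate_effect(site, cds) for site in observed]
for site, eff in zip(observed, effects):
    print(f"edit at {site.cds_position}: {eff.ref_codon}->{eff.alt_codon} "
          f"({eff.ref_aa}->{eff.alt_aa}, {eff.category})")

result = den_des(effects, potential)
print(f"EN={result.EN} ES={result.ES} N={result.N} S={result.S} "
      f"dEN/dES = {result.ratio:.3f}")

# A ratio above 1 means editing hits protein-changing positions more often
# than expected from the sequence's repertoire of editable cytosines.
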