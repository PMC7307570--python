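# mitoedit

Analysis of RNA editing and genome structure in plant mitochondrial genomes,
built for the awkward realities of organellar data: genes whose exons are
cis- or trans-spliced — sometimes across different chromosomes — genomes
that mix circular and linear molecules, and transcripts rewritten
post-transcriptionally by C-to-U (rarely A-to-G) editing.

It is a library first (with a thin `mitoedit` command-line wrapper) for
people studying organellar gene expression: given a genome FASTA, a GFF3
annotation with explicit exon ranks, and RNA-seq alignments to
*artificially spliced* coding sequences, it calls editing sites, annotates
their codon-level consequences, quantifies selection-like structure in the
editing repertoire, compares editing positions across species, and reads
chromosome topology out of mate-pair libraries.

## What it computes

**Editing-site calling.** Reads aligned to each spliced CDS are kept when at
least 80% of the read aligned with at least 90% identity; a CDS position is
called edited in a sample when it is covered by ≥ 20 filtered reads of which
≥ 10% differ from the genomic base (all thresholds inclusive and
configurable). Per-sample calls are merged into a union site list keyed by
(gene, CDS position, alt base), with a Venn-style occurrence table over
samples.

**Effect annotation.** Each site is placed in its codon and classified
synonymous / nonsynonymous / start_gained (e.g. an annotated ACG start
restored to ATG by editing) / stop_gained / stop_lost, with per-gene editing
density in sites per 100 bp of spliced CDS.

**dEN/dES.** The editing analogue of dN/dS. Every C in a CDS is a potential
C-to-U site, classified nonsynonymous (N) or synonymous (S) by substituting
T and translating; with EN and ES the observed edit counts in each class,

```
dEN/dES = (EN / N) / (ES / S)
```

and the per-gene ratios are summarised by their median. Values above 1 mean
editing is enriched at protein-changing positions.

**Cross-species conservation.** Shared genes are aligned at the protein
level (BLOSUM62, affine gaps) and back-threaded to codons; every alignment
column edited in at least one species is classified: edited in all species,
T in the non-editing species (editing site lost by replacement with the
edited product), A/G there, or an unedited C.

**Structure diagnostics.** A mate pair is proper when its reads map to one
chromosome, inward-facing, with outer span ≤ 20,000 bp; everything else
(different chromosomes, co-oriented, outward, over-long) is improper with a
reason. Per-position coverage / spanning-pair / mean-insert profiles feed a
terminal-coverage classifier that distinguishes a genuinely linear
chromosome (coverage tapering gradually to zero because copies differ in
terminal length) from the abrupt edge artifact of a circular origin.

**Synthetic data.** A fully deterministic generator produces the whole study
system with known ground truth: a circular plus linear chromosome pair,
genes with trans-spliced exons across chromosomes, planted editing sites
with per-site fractions and per-sample presence, RNA-seq SAMs with a base
error model (including reads built to fail the mapping filter), and
mate-pair libraries with Gaussian inserts (8,279 ± 2,583 bp by default) and
truncated linear ends.

## Worked example

```
python examples/01_call_editing_sites.py
```

prints (abridged):

```
planted sites:   112
called sites:    112
recovered:       112 (sensitivity 100.0%)
false calls:     0
median dEN/dES:  0.892

per-gene summary (sites per 100 bp of spliced CDS):
  gene  n_sites  cds_length  density_per_100bp  EN  ES
gene01       11         960             1.1458   5   6
gene02       12        1302             0.9217   9   3
...
```

Every planted editing event passed the 20×/10% rule in at least one sample
and nothing else did; densities around one site per 100 bp match the scale
seen in edited organellar genes. `examples/02_den_des.py`,
`examples/03_cross_species.py` and `examples/04_structure_diagnostics.py`
walk the other capabilities with the same print-and-explain style, and the
`mitoedit` command exposes `simulate`, `call-editing`, `cross-species` and
`structure` subcommands over files.

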