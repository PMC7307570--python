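# Methods

This note documents the models, conventions and numerical choices behind
`mitoedit`: what each statistic assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Spliced CDS reconstruction

Plant mitochondrial genes are represented as ordered exon parts with an
explicit integer `rank` attribute; splicing order is rank order, never
genomic order, because for trans-spliced genes — including genes whose
exons sit on different chromosomes — genomic order is undefined. The
spliced CDS is the concatenation of exon subsequences in rank order,
minus-strand exons reverse-complemented, with the GenBank-style
`codon_start` offset trimmed from the front. Every CDS carries a bijective
coordinate map back to (chromosome, position, strand); a property test
round-trips random cis/trans genes on both strands through this map.

External coordinates (GFF3, FASTA, TSV) are 1-based inclusive; all internal
arithmetic is 0-based half-open, with the conversion confined to the
readers and writers. Features crossing the origin of a circular chromosome
are represented as two exon parts with consecutive ranks. Ambiguity codes
degrade to N; codons containing N are excluded from all codon statistics.

## Editing-site calling

Alignments are reduced to (aligned fraction, identity, per-position base
calls). Aligned fraction is aligned length over full read length (soft
clips count as unaligned); identity is `(aligned_length − NM) /
aligned_length` from the alignment's edit-distance tag. The filter keeps
reads with aligned fraction ≥ 0.80 and identity ≥ 0.90 — deliberately
permissive so reads spanning splice junctions or editing-dense regions are
not lost. A site is called edited in a sample when depth ≥ 20 and the
*total* non-reference fraction is ≥ 0.10; the reported alt base is the
modal non-reference base (ties broken in fixed order A<C<G<T) with its own
fraction. All four thresholds are inclusive and configurable
(`CallerConfig`).

Two conventions were open and are fixed as follows. First, "differs from
the genomic base" is read as the total non-reference fraction, not the
modal base's fraction, matching how a generic variant caller triggers;
the two differ only at sites polluted by multiple alternative bases, which
at organellar depths are essentially always errors. Second, calling is
per-sample followed by a union across samples keyed on (gene, CDS
position, alt base) — the same position with a different alt base is a
different event — with a Venn-style occurrence table over sample subsets.
Indels are ignored: plant organellar editing is substitutional.

Because the mapping reference is the sense-strand spliced CDS, a genomic
C read as T is a C-to-U event regardless of the gene's genomic strand; no
strand flip is applied anywhere downstream.

## Effect annotation

Each site is annotated against its reference codon with the standard
genetic code (plant mitochondria use the universal code): identical amino
acid → synonymous; a non-ATG first codon becoming ATG → start_gained (the
biologically prominent case is an annotated ACG start restored by editing);
non-stop → stop → stop_gained; stop → non-stop → stop_lost; anything else
nonsynonymous. A joint mode annotates against the codon with co-occurring
edits already applied, for the rare codons carrying more than one site;
both views are available because the data do not say which edits co-occur
on one molecule. Editing density is sites per 100 bp of spliced CDS —
spliced length, not genomic span, since editing is a property of the
transcript.

## dEN/dES

For an edit class (C→U by default) every matching base in the CDS is one
potential site, classified by substituting the edited base and translating.
No Nei–Gojobori multi-path averaging is needed because only a single
substitution type exists per class, so each eligible base is counted
exactly once. Changes to or from a stop count as nonsynonymous, following
dN/dS convention; stop_gained and start_gained events count into EN. The
ratio (EN/N)/(ES/S) is undefined unless N > 0, S > 0 and ES > 0; genes with
an undefined ratio are excluded from the median (an undefined value cannot
participate in one), and non-C→U events are excluded from the C→U
statistic. These conventions matter when reproducing published medians and
are stated here because they are rarely printed alongside results.

Null behaviour: when sites are planted uniformly at random over C
positions the expected ratio is 1. The calibration experiment pools six
random 500-codon CDSs per replicate with each C edited at probability 0.5,
so EN and ES are in the hundreds and the Jensen bias of the
ratio-of-binomials (≈ var(ES)/E[ES]², about 10⁻³ at these counts) is small
against the sampling error of a 1,000-replicate mean. With small genes or
sparse editing the same estimator is noticeably biased upward — a caveat
for per-gene ratios on real data.

## Cross-species conservation

Homologous genes are matched by shared gene name (organellar gene
nomenclature is stable across flowering plants), translated, and aligned
globally with BLOSUM62 and affine gap penalties (open −10, extend −0.5,
end gaps penalised). Three or more species are merged center-star around
the first species; for the two- and three-species comparisons this is
equivalent to full MSA in practice because shared mitochondrial genes are
highly conserved. The protein alignment is back-threaded to nucleotides so
gaps always span whole codons, and per-species position↔column maps are
bijective off gaps.

Each column edited in at least one species is classified: edited in all →
`edited_all`; otherwise by the non-editing species' residues — all T →
`T_at_unedited` (the dominant mode of editing-site loss: the edited
product becomes genomically hard-wired), any A/G → `AG_at_unedited`, an
unedited C present → `unedited_C`; columns with gaps or other degeneracies
→ `mixed_other`, counted separately rather than silently dropped.

## Mate-pair structure diagnostics

A pair is proper iff both reads map to one chromosome, the leftmost read
is forward and the rightmost reverse (inward), and the outer span
(leftmost start to rightmost end — insert-size semantics of mate-pair
libraries) is ≤ `d_max` = 20,000 bp. Improper reasons have fixed
precedence: inter_chromosomal > same_orientation > outward > distant.
Outward-facing pairs are improper — only the inward orientation is
consistent with an intact fragment — and carry their own reason since they
are the signature of a circular junction in a linear mapping.

Profiles (read coverage, spanning proper pairs, mean outer span per
position) are computed with difference arrays in O(reads + length);
intervals overhanging the end of a circular chromosome wrap to the origin.

Terminal classification works on read coverage normalised by the interior
median, smoothed with a boundary-aware moving average (kernel = window/50).
An end is *flat* when smoothed terminal coverage is at least 0.35 of the
interior; otherwise it is *taper* when the depressed region spans at least
10% of the window (a gradual climb back to interior level, as produced by
chromosome copies of variable terminal length) and *abrupt* when the
deficit is concentrated nearer the edge (the mapping artifact at a
circular origin, e.g. a sharp several-fold drop). The flat threshold sits
below one half deliberately: mate-pair read coverage of a clean linear end
plateaus near half the interior level within one insert length of the
terminus (only one mate of an end-proximal fragment can land there), and
that plateau must not read as a taper. The window defaults to twice the
mean proper-pair insert; these detector parameters are exposed because the
underlying judgement is, in the literature, usually made by eye.

## Synthetic-data generator

The generator emulates the study system end to end with known truth, one
integer seed fixing every output byte:

- **Genome**: two chromosomes by default (35 kb linear + 15 kb circular,
  ~45% GC), ten protein genes of 300–500 codons with 1–3 exons, mixed
  strands, introns of 100–300 bp, and a configurable trans-splicing
  fraction with at least one gene split across the two chromosomes. One
  gene is written with a genomic ACG start whose ATG is restored by a
  planted C→U site at CDS position 2.
- **Editing truth**: each eligible C is edited with probability 0.03
  (A→G at ~1/99 of that rate), fractions uniform on [0.2, 1.0], present in
  all five samples with probability 0.85 and in a random proper subset
  otherwise. Sites are planted at least 30 bp from CDS termini: within
  ~20% of a read length of a reference end, local-alignment coverage is
  intrinsically reduced (reads overhanging further fail the 80%-aligned
  filter), so termini cannot reach the 20× calling floor at 100× depth —
  a property of mapping to CDS ends, not of editing biology, and one the
  truth set should not be charged with.
- **RNA-seq**: 150 nt reads, starts uniform with up to 20% soft-clipped
  overhang beyond either CDS end, mean interior depth 100×, uniform base
  error 0.001, five tissue-labelled samples; a 2% admixture of reads
  engineered to fail the mapping filter (half soft-clipped, or with
  exactly 15% mismatches) exercises the filter. Alignments are emitted
  directly with known coordinates — no mapper runs, by design, since
  mapping is upstream tooling.
- **Mate pairs**: Gaussian inserts, default mean 8,279 bp and sd 2,583 bp
  (the alternative preset 8,705 ± 2,537 describes the second library of
  the same design); reads 100 nt, inward. Linear chromosomes are sampled
  from copies whose ends are independently truncated by Uniform(0, 8 kb),
  producing the terminal taper; circular chromosomes are sampled with
  origin wrap-around, and origin-straddling reads overhang the reference
  end (written soft-clipped in SAM).

What the generator does **not** emulate: quality scores, adapter or
contamination sequence, coverage biases (GC, mappability), paralogy and
read mismapping, partial editing linkage along molecules, and genomic
repeats. Passing tests therefore demonstrate correctness of the
computations under a clean error model, not robustness to every real-data
pathology — in particular, real false-positive editing calls come mostly
from mismapping, which is out of the model by construction.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at the
default study scale (50 kb genome, 10 genes, 5 samples, 100× depth —
roughly 45,000 reads), 1,000 replicates of the null dEN/dES calibration,
200,000 mate pairs for the analytic improper-rate check, and 30,000 pairs
per taper scenario; these sizes put every stochastic check comfortably in
its asymptotic regime while keeping a complete run in tens of seconds.
Every stochastic computation takes an explicit seed or NumPy `Generator`;
identical configurations yield byte-identical FASTA/GFF3/SAM/TSV outputs,
and run manifests record config plus SHA-256 digests of inputs and
outputs.

## Known limitations

- The caller has no strand-aware error model and no statistical test per
  site; it is a faithful implementation of a threshold rule, so its false
  positive behaviour is governed entirely by the mapping filter upstream.
- Center-star MSA can be suboptimal for deeply diverged proteins; for the
  conserved organellar gene sets it targets, pairwise-to-center agreement
  is the dominant regime.
- dEN/dES per gene is a ratio of small counts on real data; medians across
  genes should be preferred and ES = 0 genes are necessarily dropped.
- Taper detection assumes a single dominant coverage regime per window;
  chromosomes with internal repeat-driven coverage steps near an end may
  need a hand-chosen window.
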