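"""Synthetic mitogenomes, transcriptome alignments and mate-pair libraries.

The generator emulates the study system every pipeline stage is meant to
handle: a two-chromosome plant mitogenome (one circular, one linear whose
copies differ in terminal length), protein genes with cis- and trans-spliced
exons on both strands — including a gene split across the two chromosomes —
planted editing sites (overwhelmingly C-to-U, rarely A-to-G) with per-site
editing fractions and per-sample presence, RNA-seq read alignments to the
spliced CDS references with a uniform base-error model, and a long-insert
mate-pair library with Gaussian insert sizes (defaults 8,279 +/- 2,583 bp).

Everything is driven by one integer seed: identical configurations produce
byte-identical FASTA/GFF3/SAM/TSV outputs.  Alignments are emitted directly
with known coordinates, so no read mapper is involved; reads engineered to
fail the aligned-fraction/identity filter are included to exercise it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .calling import CallerConfig
from .genome import (
    Chromosome,
    Exon,
    GeneModel,
    SplicedCDS,
    extract_cds,
    validate_annotation,
    write_annotation,
    write_fasta,
)
from .structure import MatePair, ReadPlacement, classify_mate_pair

__all__ = [
    "GeneConfig",
    "EditingConfig",
    "RnaSeqConfig",
    "MatePairConfig",
    "LinearEndConfig",
    "SimulationConfig",
    "TruthSite",
    "SimulatedGenome",
    "generate_genome",
    "plant_editing",
    "simulate_rnaseq",
    "simulate_matepairs",
    "simulate_all",
    "SimulationOutputs",
]

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_BASE_ARRAY = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneConfig:
    n_genes: int = 10
    codons_range: tuple[int, int] = (300, 500)
    exon_count_range: tuple[int, int] = (1, 3)
    minus_strand_prob: float = 0.5
    trans_splice_fraction: float = 0.2
    intron_length_range: tuple[int, int] = (100, 300)
    intergenic_range: tuple[int, int] = (200, 800)
    acg_start_gene: bool = True  # one gene whose ATG is restored by editing


@dataclass(frozen=True)
class EditingConfig:
    site_rate: float = 0.03  # per-eligible-C planting probability
    fraction_range: tuple[float, float] = (0.2, 1.0)
    c_to_u_weight: float = 0.99
    a_to_g_weight: float = 0.01
    all_sample_prob: float = 0.85  # most real events occur in every sample
    edge_margin: int = 30  # bp kept clear of CDS termini (see methods note)


@dataclass(frozen=True)
class RnaSeqConfig:
    mean_depth: float = 100.0
    base_error: float = 0.001
    read_length: int = 150
    samples: tuple[str, ...] = (
        "inflorescence",
        "anthers_1",
        "anthers_2",
        "ovules_1",
        "ovules_2",
    )
    junk_read_fraction: float = 0.02  # reads built to fail the 80%/90% filter


@dataclass(frozen=True)
class MatePairConfig:
    insert_mean: float = 8279.0
    insert_sd: float = 2583.0
    n_pairs: int = 20_000
    read_length: int = 100


@dataclass(frozen=True)
class LinearEndConfig:
    # per-copy terminal truncation ~ Uniform(0, max_truncation) on each end
    max_truncation: int = 8000


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chromosomes: tuple[tuple[int, str], ...] = ((35_000, "linear"), (15_000, "circular"))
    genes: GeneConfig = field(default_factory=GeneConfig)
    editing: EditingConfig = field(default_factory=EditingConfig)
    rnaseq: RnaSeqConfig = field(default_factory=RnaSeqConfig)
    matepair: MatePairConfig = field(default_factory=MatePairConfig)
    linear_end: LinearEndConfig = field(default_factory=LinearEndConfig)


@dataclass(frozen=True)
class TruthSite:
    """A planted editing event with its true per-read editing probability."""

    gene_name: str
    cds_position: int
    ref_base: str
    alt_base: str
    fraction: float
    samples: frozenset[str]
    edit_type: str


@dataclass
class SimulatedGenome:
    chromosomes: list[Chromosome]
    genes: list[GeneModel]
    cds: dict[str, SplicedCDS]


def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.45) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    middle = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in middle) + stop


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def generate_genome(cfg: SimulationConfig) -> SimulatedGenome:
    """Generate chromosomes and non-overlapping gene models, deterministically.

    When the trans-splice fraction is positive and there are at least two
    chromosomes, at least one gene is split across two chromosomes.  One gene
    (when configured) is written with a genomic ACG start codon whose ATG is
    restored by a planted C-to-U site.  Raises if the configured genes cannot
    be packed into the configured chromosome lengths.
    """
    rng = np.random.default_rng(cfg.seed)
    gc = cfg.genes
    chrom_ids = [f"chr{i + 1}" for i in range(len(cfg.chromosomes))]
    lengths = [int(length) for length, _ in cfg.chromosomes]
    backgrounds = [_random_sequence(rng, length) for length in lengths]

    multi = len(chrom_ids) >= 2
    trans_flags = rng.random(gc.n_genes) < gc.trans_splice_fraction
    if not multi:
        trans_flags[:] = False
    elif gc.trans_splice_fraction > 0 and not trans_flags.any():
        trans_flags[min(1, gc.n_genes - 1)] = True

    cursors = [int(rng.integers(gc.intergenic_range[0], gc.intergenic_range[1] + 1))
               for _ in chrom_ids]
    genes: list[GeneModel] = []
    for gi in range(gc.n_genes):
        n_codons = int(rng.integers(gc.codons_range[0], gc.codons_range[1] + 1))
        cds_seq = _random_cds(rng, n_codons)
        is_acg = gc.acg_start_gene and gi == 0
        n_exons = int(rng.integers(gc.exon_count_range[0], gc.exon_count_range[1] + 1))
        if trans_flags[gi]:
            n_exons = max(2, n_exons)
        # exon lengths: random proportions, each at least 30 bp
        weights = rng.random(n_exons) + 0.5
        raw = np.floor(weights / weights.sum() * len(cds_seq)).astype(int)
        raw = np.maximum(raw, 30)
        raw[-1] += len(cds_seq) - raw.sum()
        if raw[-1] < 30:
            raw[:] = len(cds_seq) // n_exons
            raw[-1] += len(cds_seq) - raw.sum()
        pieces = []
        offset = 0
        for ln in raw:
            pieces.append(cds_seq[offset : offset + ln])
            offset += ln
        # chromosome assignment per exon
        if trans_flags[gi]:
            pair = rng.choice(len(chrom_ids), size=2, replace=False)
            split = int(rng.integers(1, n_exons))
            exon_chrom = [int(pair[0])] * split + [int(pair[1])] * (n_exons - split)
        else:
            ci = int(rng.choice(len(chrom_ids), p=np.array(lengths) / sum(lengths)))
            exon_chrom = [ci] * n_exons
        strand_by_chrom = {
            ci: ("-" if rng.random() < gc.minus_strand_prob else "+")
            for ci in set(exon_chrom)
        }
        exons = []
        name = f"gene{gi + 1:02d}"
        for rank, (piece, ci) in enumerate(zip(pieces, exon_chrom), start=1):
            strand = strand_by_chrom[ci]
            written = piece
            if is_acg and rank == 1:
                written = piece[0] + "C" + piece[2:]  # ATG -> ACG in the genome
            if strand == "-":
                written = _revcomp(written)
            start0 = cursors[ci]
            end0 = start0 + len(piece)
            if end0 > lengths[ci]:
                raise ValueError(
                    f"infeasible packing: gene {name} exceeds {chrom_ids[ci]} "
                    f"length {lengths[ci]}"
                )
            arr = np.frombuffer(written.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=np.uint8)
            for bi, b in enumerate(b"ACGT"):
                lut[b] = bi
            backgrounds[ci][start0:end0] = lut[arr]
            exons.append(
                Exon(
                    chromosome_id=chrom_ids[ci],
                    start=start0 + 1,
                    end=end0,
                    strand=strand,
                    rank=rank,
                )
            )
            same_gene_next = rank < n_exons and exon_chrom[rank] == ci
            gap_range = gc.intron_length_range if same_gene_next else gc.intergenic_range
            cursors[ci] = end0 + int(rng.integers(gap_range[0], gap_range[1] + 1))
        genes.append(
            GeneModel(
                name=name,
                gene_type="protein",
                exons=exons,
                codon_start=1,
                annotated_start_is_ACG=is_acg,
            )
        )

    chromosomes = [
        Chromosome(
            id=chrom_ids[i],
            sequence="".join(_BASE_ARRAY[backgrounds[i]].tobytes().decode()),
            topology=cfg.chromosomes[i][1],
        )
        for i in range(len(chrom_ids))
    ]
    validate_annotation(genes, chromosomes)
    cds = {g.name: extract_cds(g, chromosomes) for g in genes}
    return SimulatedGenome(chromosomes=chromosomes, genes=genes, cds=cds)


def plant_editing(
    sim: SimulatedGenome, cfg: SimulationConfig, rng: np.random.Generator
) -> list[TruthSite]:
    """Plant editing sites on eligible bases of each spliced CDS.

    Sites land only on the reference base of their class, at least
    ``edge_margin`` bp from the CDS termini; each site gets a true editing
    fraction and a sample subset (all samples with probability
    ``all_sample_prob``, else a random non-empty proper subset).  The
    ACG-start gene always receives the start-restoring C-to-U site at CDS
    position 2, planted at high fraction in every sample.
    """
    ec = cfg.editing
    samples = cfg.rnaseq.samples
    lo, hi = ec.fraction_range
    a_rate = (
        ec.site_rate * ec.a_to_g_weight / ec.c_to_u_weight if ec.c_to_u_weight else 0.0
    )
    sites: list[TruthSite] = []

    def draw_samples() -> frozenset[str]:
        if len(samples) == 1 or rng.random() < ec.all_sample_prob:
            return frozenset(samples)
        k = int(rng.integers(1, len(samples)))
        idx = rng.choice(len(samples), size=k, replace=False)
        return frozenset(samples[i] for i in sorted(idx))

    for gene in sim.genes:
        if gene.gene_type not in ("protein", "orf"):
            continue
        cds = sim.cds[gene.name]
        length = len(cds)
        if gene.annotated_start_is_ACG and cds.sequence[1] == "C":
            sites.append(
                TruthSite(
                    gene_name=gene.name,
                    cds_position=2,
                    ref_base="C",
                    alt_base="T",
                    fraction=0.9,
                    samples=frozenset(samples),
                    edit_type="C_to_U",
                )
            )
        for pos in range(ec.edge_margin + 1, length - ec.edge_margin + 1):
            if pos == 2 and gene.annotated_start_is_ACG:
                continue
            base = cds.sequence[pos - 1]
            if base == "C" and rng.random() < ec.site_rate:
                ref, alt, etype = "C", "T", "C_to_U"
            elif base == "A" and a_rate > 0 and rng.random() < a_rate:
                ref, alt, etype = "A", "G", "A_to_G"
            else:
                continue
            sites.append(
                TruthSite(
                    gene_name=gene.name,
                    cds_position=pos,
                    ref_base=ref,
                    alt_base=alt,
                    fraction=float(lo + (hi - lo) * rng.random()),
                    samples=draw_samples(),
                    edit_type=etype,
                )
            )
    return sites


def _sam_header(references: dict[str, int]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in references.items()],
    }


def simulate_rnaseq(
    sim: SimulatedGenome,
    sites: list[TruthSite],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit one SAM of CDS-aligned reads per sample; returns sample -> path.

    Read starts are uniform over the reference, allowing up to 20% overhang
    beyond either CDS end (soft-clipped), so edge coverage resembles local
    alignment of transcript reads.  Covering reads show a planted site's alt
    base with probability equal to the site's true fraction (when the site is
    present in the sample), and every aligned base is flipped to a uniformly
    chosen other base with the configured error probability.  A small
    fraction of deliberately bad reads (half soft-clipped or mismatch-rich)
    exercises the aligned-fraction/identity filter downstream.
    """
    rc = cfg.rnaseq
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rl = rc.read_length
    clip = int(0.2 * rl)
    references = {name: len(c) for name, c in sim.cds.items()}
    header = _sam_header(references)
    ref_index = {name: i for i, name in enumerate(references)}
    by_gene: dict[str, dict[int, TruthSite]] = {}
    for site in sites:
        by_gene.setdefault(site.gene_name, {})[site.cds_position] = site

    base_list = np.array(list("ACGT"))
    paths: dict[str, Path] = {}
    for sample in rc.samples:
        path = out_dir / f"rnaseq_{sample}.sam"
        paths[sample] = path
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            for gene_name, cds in sim.cds.items():
                L = len(cds)
                gene_sites = {
                    pos: s
                    for pos, s in by_gene.get(gene_name, {}).items()
                    if sample in s.samples
                }
                a, b = -clip, L - rl + clip
                n_positions = b - a + 1
                n_reads = int(np.ceil(rc.mean_depth * n_positions / rl))
                starts = rng.integers(a, b + 1, size=n_reads)
                n_junk = int(round(rc.junk_read_fraction * n_reads))
                for ri in range(n_reads):
                    s = int(starts[ri])
                    ref_lo = max(0, s)
                    ref_hi = min(L, s + rl)
                    aligned_len = ref_hi - ref_lo
                    frag = list(cds.sequence[ref_lo:ref_hi])
                    # planted edits
                    for pos, site in gene_sites.items():
                        if ref_lo < pos <= ref_hi and rng.random() < site.fraction:
                            frag[pos - 1 - ref_lo] = site.alt_base
                    # sequencing errors
                    err = np.nonzero(rng.random(aligned_len) < rc.base_error)[0]
                    for e in err:
                        cur = frag[e]
                        others = [x for x in "ACGT" if x != cur]
                        frag[e] = others[int(rng.integers(0, 3))]
                    left_clip = ref_lo - s
                    right_clip = s + rl - ref_hi
                    seq = (
                        "".join(base_list[rng.integers(0, 4, size=left_clip)])
                        + "".join(frag)
                        + "".join(base_list[rng.integers(0, 4, size=right_clip)])
                    )
                    cigar = ""
                    if left_clip:
                        cigar += f"{left_clip}S"
                    cigar += f"{aligned_len}M"
                    if right_clip:
                        cigar += f"{right_clip}S"
                    nm = sum(
                        1
                        for k in range(aligned_len)
                        if frag[k] != cds.sequence[ref_lo + k]
                    )
                    aln = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
                    aln.query_name = f"{sample}.{gene_name}.{ri}"
                    aln.query_sequence = seq
                    aln.flag = 0
                    aln.reference_id = ref_index[gene_name]
                    aln.reference_start = ref_lo
                    aln.cigarstring = cigar
                    aln.mapping_quality = 60
                    aln.set_tag("NM", nm)
                    sam.write(aln)
                # deliberately bad reads: half-clipped and mismatch-rich
                junk_starts = rng.integers(0, max(1, L - rl), size=n_junk)
                for ji in range(n_junk):
                    s = int(junk_starts[ji])
                    if ji % 2 == 0:
                        # half soft-clipped: aligned fraction 0.5 < 0.8
                        half = rl // 2
                        aligned_len = rl - half
                        ref_part = list(cds.sequence[s : s + aligned_len])
                        n_mm = max(1, int(0.3 * aligned_len))
                        for k in rng.choice(aligned_len, size=n_mm, replace=False):
                            others = [x for x in "ACGT" if x != ref_part[k]]
                            ref_part[k] = others[int(rng.integers(0, 3))]
                        seq = (
                            "".join(base_list[rng.integers(0, 4, size=half)])
                            + "".join(ref_part)
                        )
                        cigar = f"{half}S{aligned_len}M"
                        ref_start = s
                        aligned = ref_part
                        lo = s
                    else:
                        # mismatch-rich: exactly 15% mismatches, identity 0.85 < 0.9
                        aligned_len = min(rl, L - s)
                        aligned = list(cds.sequence[s : s + aligned_len])
                        n_mm = max(1, int(np.ceil(0.15 * aligned_len)))
                        for k in rng.choice(aligned_len, size=n_mm, replace=False):
                            others = [x for x in "ACGT" if x != aligned[k]]
                            aligned[k] = others[int(rng.integers(0, 3))]
                        seq = "".join(aligned)
                        cigar = f"{aligned_len}M"
                        ref_start = s
                        lo = s
                    nm = sum(
                        1
                        for k in range(len(aligned))
                        if aligned[k] != cds.sequence[lo + k]
                    )
                    aln = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
                    aln.query_name = f"{sample}.{gene_name}.junk{ji}"
                    aln.query_sequence = seq
                    aln.flag = 0
                    aln.reference_id = ref_index[gene_name]
                    aln.reference_start = ref_start
                    aln.cigarstring = cigar
                    aln.mapping_quality = 20
                    aln.set_tag("NM", nm)
                    sam.write(aln)
    return paths


@dataclass(frozen=True)
class MatePairTruth:
    """Generator-side expectation for one emitted pair."""

    pair_index: int
    chromosome_id: str
    insert: int
    wrapped: bool
    expected_status: str  # proper | improper
    expected_reason: str


def simulate_matepairs(
    sim: SimulatedGenome | list[Chromosome],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sam_path: str | Path | None = None,
) -> tuple[list[MatePair], list[MatePairTruth]]:
    """Draw mate pairs from chromosome copies; optionally write a SAM.

    Linear chromosomes are sampled from copies whose two ends are
    independently truncated by Uniform(0, max_truncation) bp, producing the
    terminal coverage taper of a linear molecule with variable-length copies;
    circular chromosomes are sampled with origin wrap-around (a wrapped pair
    maps as an improper-looking pair, the real circular-junction artifact).
    Inserts are Gaussian; pairs whose insert does not fit the (truncated)
    copy are dropped.
    """
    chromosomes = sim.chromosomes if isinstance(sim, SimulatedGenome) else sim
    mc = cfg.matepair
    rl = mc.read_length
    total = sum(len(c) for c in chromosomes)
    pairs: list[MatePair] = []
    truths: list[MatePairTruth] = []
    for chrom in chromosomes:
        L = len(chrom)
        n = int(round(mc.n_pairs * L / total))
        inserts = np.rint(rng.normal(mc.insert_mean, mc.insert_sd, size=n)).astype(int)
        inserts = np.maximum(inserts, 2 * rl)
        if chrom.topology == "linear":
            tmax = cfg.linear_end.max_truncation
            tl = rng.integers(0, tmax + 1, size=n) if tmax > 0 else np.zeros(n, dtype=int)
            tr = rng.integers(0, tmax + 1, size=n) if tmax > 0 else np.zeros(n, dtype=int)
            u = rng.random(n)
            for i in range(n):
                lo, hi = int(tl[i]), L - int(tr[i])
                ins = int(inserts[i])
                if hi - lo < ins:
                    continue  # this copy is too short for the drawn insert
                s = lo + int(u[i] * (hi - lo - ins + 1))
                read1 = ReadPlacement(chrom.id, s + 1, s + rl, "F")
                read2 = ReadPlacement(chrom.id, s + ins - rl + 1, s + ins, "R")
                pairs.append(MatePair(read1=read1, read2=read2))
                truths.append(
                    MatePairTruth(
                        pair_index=len(pairs) - 1,
                        chromosome_id=chrom.id,
                        insert=ins,
                        wrapped=False,
                        expected_status="proper" if ins <= 20_000 else "improper",
                        expected_reason="none" if ins <= 20_000 else "distant",
                    )
                )
        else:  # circular: wrap sampling; origin-straddling reads overhang the end
            starts = rng.integers(0, L, size=n)
            for i in range(n):
                ins = int(inserts[i])
                s1 = int(starts[i])
                s2 = (s1 + ins - rl) % L
                wrapped = s1 + ins > L
                read1 = ReadPlacement(chrom.id, s1 + 1, s1 + rl, "F")
                read2 = ReadPlacement(chrom.id, s2 + 1, s2 + rl, "R")
                pairs.append(MatePair(read1=read1, read2=read2))
                if not wrapped:
                    status = "proper" if ins <= 20_000 else "improper"
                    reason = "none" if ins <= 20_000 else "distant"
                else:
                    cls = classify_mate_pair(MatePair(read1=read1, read2=read2))
                    status, reason = cls.status, cls.reason
                truths.append(
                    MatePairTruth(
                        pair_index=len(pairs) - 1,
                        chromosome_id=chrom.id,
                        insert=ins,
                        wrapped=wrapped,
                        expected_status=status,
                        expected_reason=reason,
                    )
                )
    if sam_path is not None:
        references = {c.id: len(c) for c in chromosomes}
        header = _sam_header(references)
        ref_index = {name: i for i, name in enumerate(references)}
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
            for pi, pair in enumerate(pairs):
                for mate_no, read in ((1, pair.read1), (2, pair.read2)):
                    other = pair.read2 if mate_no == 1 else pair.read1
                    aln = pysam.AlignedSegment(
                        header=pysam.AlignmentHeader.from_dict(header)
                    )
                    aln.query_name = f"mp{pi}"
                    aln.flag = (
                        0x1
                        | (0x40 if mate_no == 1 else 0x80)
                        | (0x10 if read.orientation == "R" else 0)
                        | (0x20 if other.orientation == "R" else 0)
                    )
                    aln.reference_id = ref_index[read.chromosome_id]
                    aln.reference_start = read.start - 1
                    chrom_len = references[read.chromosome_id]
                    read_len = read.end - read.start + 1
                    if read.end <= chrom_len:
                        aln.cigarstring = f"{read_len}M"
                    else:  # origin-straddling read on a circular chromosome
                        within = chrom_len - read.start + 1
                        aln.cigarstring = f"{within}M{read_len - within}S"
                    aln.query_sequence = None
                    aln.mapping_quality = 60
                    aln.next_reference_id = ref_index[other.chromosome_id]
                    aln.next_reference_start = other.start - 1
                    sam.write(aln)
    return pairs, truths


@dataclass
class SimulationOutputs:
    """Paths and in-memory objects of one full simulation run."""

    config: SimulationConfig
    genome: SimulatedGenome
    truth_sites: list[TruthSite]
    genome_fasta: Path
    annotation_gff3: Path
    cds_fasta: Path
    truth_sites_tsv: Path
    rnaseq_sams: dict[str, Path]
    matepair_sam: Path
    matepair_truth_tsv: Path
    manifest_json: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_all(cfg: SimulationConfig, out_dir: str | Path) -> SimulationOutputs:
    """Run the full generator and write every artifact plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = generate_genome(cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # genome already consumed cfg.seed
    truth_sites = plant_editing(sim, cfg, rng)

    genome_fasta = out_dir / "genome.fasta"
    write_fasta(sim.chromosomes, genome_fasta)
    annotation = out_dir / "annotation.gff3"
    write_annotation(sim.genes, annotation, chromosomes=sim.chromosomes)
    cds_fasta = out_dir / "cds.fasta"
    write_fasta(sim.cds.values(), cds_fasta)

    truth_tsv = out_dir / "truth_sites.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("gene\tcds_pos\tref\talt\tfraction\tedit_type\tsamples\n")
        for s in truth_sites:
            fh.write(
                f"{s.gene_name}\t{s.cds_position}\t{s.ref_base}\t{s.alt_base}\t"
                f"{s.fraction:.6f}\t{s.edit_type}\t{','.join(sorted(s.samples))}\n"
            )

    rnaseq_sams = simulate_rnaseq(sim, truth_sites, cfg, rng, out_dir)
    matepair_sam = out_dir / "matepairs.sam"
    pairs, mp_truth = simulate_matepairs(sim, cfg, rng, sam_path=matepair_sam)
    mp_tsv = out_dir / "matepair_truth.tsv"
    with open(mp_tsv, "w") as fh:
        fh.write("pair_index\tchromosome\tinsert\twrapped\texpected_status\texpected_reason\n")
        for t in mp_truth:
            fh.write(
                f"{t.pair_index}\t{t.chromosome_id}\t{t.insert}\t{int(t.wrapped)}\t"
                f"{t.expected_status}\t{t.expected_reason}\n"
            )

    files = {
        "genome_fasta": genome_fasta,
        "annotation_gff3": annotation,
        "cds_fasta": cds_fasta,
        "truth_sites_tsv": truth_tsv,
        "matepair_sam": matepair_sam,
        "matepair_truth_tsv": mp_tsv,
        **{f"rnaseq_{s}": p for s, p in rnaseq_sams.items()},
    }
    manifest = {
        "config": dataclasses.asdict(cfg),
        "files": {k: str(p.name) for k, p in files.items()},
        "sha256": {k: _sha256(p) for k, p in files.items()},
        "n_truth_sites": len(truth_sites),
        "n_mate_pairs": len(pairs),
    }
    manifest_json = out_dir / "manifest.json"
    with open(manifest_json, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SimulationOutputs(
        config=cfg,
        genome=sim,
        truth_sites=truth_sites,
        genome_fasta=genome_fasta,
        annotation_gff3=annotation,
        cds_fasta=cds_fasta,
        truth_sites_tsv=truth_tsv,
        rnaseq_sams=rnaseq_sams,
        matepair_sam=matepair_sam,
        matepair_truth_tsv=mp_tsv,
        manifest_json=manifest_json,
    )
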