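"""Genomes, gene models and spliced coding sequences.

Plant mitochondrial genes are frequently fragmented: exons may be separated
by cis-spliced introns, or lie on different strands or even different
chromosomes (trans-splicing, e.g. *nad5* with exons split between a linear
and a circular chromosome).  To analyse RNA editing against RNA-seq reads
without an intron-aware aligner, each gene is reduced to its *artificially
spliced CDS*: the exon sequences concatenated in splicing order, minus-strand
exons reverse-complemented, together with a bijective map from every CDS
position back to its genomic origin.

Coordinate conventions: external formats (GFF3, FASTA headers, TSV output)
are 1-based inclusive; all internal arithmetic is 0-based half-open, and the
conversion happens only in the readers/writers in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "Chromosome",
    "Exon",
    "GeneModel",
    "SplicedCDS",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "extract_cds",
    "sequence_stats",
    "validate_annotation",
]

_VALID_BASES = frozenset("ACGTN")
_IUPAC_EXTRA = frozenset("RYSWKMBDHVU")


def _normalize_sequence(seq: str, context: str) -> str:
    """Uppercase and coerce to the {A,C,G,T,N} alphabet.

    IUPAC ambiguity codes degrade to N (with a warning); anything else is an
    error.  U is treated as T so RNA input does not silently break.
    """
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if not bad:
        return seq
    if bad - _IUPAC_EXTRA:
        raise ValueError(
            f"{context}: invalid sequence characters {sorted(bad - _IUPAC_EXTRA)}"
        )
    warnings.warn(f"{context}: ambiguity codes {sorted(bad)} converted to N")
    table = str.maketrans({c: ("T" if c == "U" else "N") for c in bad})
    return seq.translate(table)


@dataclass(frozen=True)
class Chromosome:
    """A named genome sequence with declared topology."""

    id: str
    sequence: str
    topology: str = "linear"  # "circular" | "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chromosome {self.id!r}: empty sequence")
        object.__setattr__(
            self, "sequence", _normalize_sequence(self.sequence, f"chromosome {self.id!r}")
        )
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"chromosome {self.id!r}: bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Exon:
    """One exon part; coordinates 1-based inclusive on the chromosome."""

    chromosome_id: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"exon {self.chromosome_id}:{self.start}-{self.end}: bad coordinates"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"exon strand must be '+' or '-', got {self.strand!r}")
        if self.rank < 1:
            raise ValueError(f"exon rank must be >= 1, got {self.rank}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """A gene as an ordered list of exon parts.

    Splicing order is *rank* order, never genomic order: for a trans-spliced
    gene whose parts sit on different chromosomes, genomic order is undefined.
    ``codon_start`` is the GenBank-style reading-frame offset (1..3);
    ``annotated_start_is_ACG`` marks genes whose genomic first codon is ACG
    and whose canonical ATG is restored by C-to-U editing (the *nad4L* case).
    """

    name: str
    gene_type: str = "protein"  # protein | tRNA | rRNA | orf
    exons: list[Exon] = field(default_factory=list)
    codon_start: int = 1
    annotated_start_is_ACG: bool = False

    def __post_init__(self) -> None:
        if self.gene_type not in ("protein", "tRNA", "rRNA", "orf"):
            raise ValueError(f"gene {self.name!r}: bad gene_type {self.gene_type!r}")
        if self.codon_start not in (1, 2, 3):
            raise ValueError(f"gene {self.name!r}: codon_start must be 1..3")
        self.exons = sorted(self.exons, key=lambda e: e.rank)
        ranks = [e.rank for e in self.exons]
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"gene {self.name!r}: duplicate exon ranks {ranks}")
        if ranks and ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(
                f"gene {self.name!r}: exon ranks must be contiguous from 1, got {ranks}"
            )
        if self.gene_type in ("protein", "orf") and self.exons and self.length < 3:
            raise ValueError(f"gene {self.name!r}: protein gene shorter than one codon")

    @property
    def length(self) -> int:
        """Total exon length in bp (the spliced gene length)."""
        return sum(len(e) for e in self.exons)

    @property
    def chromosome_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.exons:
            seen.setdefault(e.chromosome_id, None)
        return list(seen)

    @property
    def is_trans_spliced(self) -> bool:
        return len(self.chromosome_ids) > 1


@dataclass
class SplicedCDS:
    """A sense-strand spliced CDS with its CDS<->genome coordinate map.

    ``coord_map[i]`` gives ``(chromosome_id, genomic_position_1based, strand)``
    for CDS position ``i + 1``; reading the genomic base there (reverse
    complemented on '-') reproduces ``sequence[i]``.
    """

    gene_name: str
    sequence: str
    coord_map: list[tuple[str, int, str]]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.coord_map):
            raise ValueError(
                f"{self.gene_name}: sequence length {len(self.sequence)} != "
                f"coord_map length {len(self.coord_map)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def genomic_location(self, cds_position: int) -> tuple[str, int, str]:
        """Map a 1-based CDS position to (chromosome, 1-based position, strand)."""
        if not 1 <= cds_position <= len(self.coord_map):
            raise IndexError(
                f"{self.gene_name}: CDS position {cds_position} outside 1..{len(self)}"
            )
        return self.coord_map[cds_position - 1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | Path, topologies: Mapping[str, str] | None = None
) -> list[Chromosome]:
    """Read chromosomes from FASTA.

    Topology is taken from a ``topology=circular|linear`` token in the record
    description, else from the ``topologies`` sidecar mapping, else linear.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = line
                break
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(f"{path}: line {lineno}: expected FASTA header '>'")
    chromosomes = []
    for record in SeqIO.parse(str(path), "fasta"):
        topology = "linear"
        for token in record.description.split():
            if token.startswith("topology="):
                topology = token.split("=", 1)[1]
        if topologies and record.id in topologies:
            topology = topologies[record.id]
        chromosomes.append(Chromosome(record.id, str(record.seq), topology))
    if not chromosomes:
        raise ValueError(f"{path}: no FASTA records")
    return chromosomes


def write_fasta(
    sequences: Iterable[Chromosome | SplicedCDS], path: str | Path, width: int = 70
) -> None:
    """Write chromosomes or spliced CDSs as FASTA (topology token on chromosomes)."""
    with open(path, "w") as fh:
        for item in sequences:
            if isinstance(item, Chromosome):
                fh.write(f">{item.id} topology={item.topology}\n")
            else:
                fh.write(f">{item.gene_name}\n")
            seq = item.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (dialect: gene lines keyed by ID, exon lines with Parent + rank;
# trans-spliced genes are discontinuous features sharing one gene ID)


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3.

    Exon parts of one gene share a ``Parent`` (or ``gene``) attribute and
    carry an explicit integer ``rank`` attribute giving splicing order; parts
    may sit on different seqids (trans-splicing).
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    for feature in gffutils.iterators.DataIterator(str(Path(path))):
        if feature.featuretype == "gene":
            gid = feature.attributes.get("ID", [feature.id])[0]
            info = genes.setdefault(gid, {"exons": [], "attrs": {}})
            if gid not in order:
                order.append(gid)
            for key in ("gene_type", "codon_start", "acg_start"):
                if key in feature.attributes:
                    info["attrs"][key] = feature.attributes[key][0]
        elif feature.featuretype == "exon":
            parent = (
                feature.attributes.get("Parent", None)
                or feature.attributes.get("gene", None)
            )
            if not parent:
                raise ValueError(f"exon at {feature.seqid}:{feature.start}: no Parent")
            gid = parent[0]
            if "rank" not in feature.attributes:
                raise ValueError(f"exon of {gid!r} at {feature.seqid}:{feature.start}: no rank")
            info = genes.setdefault(gid, {"exons": [], "attrs": {}})
            if gid not in order:
                order.append(gid)
            info["exons"].append(
                Exon(
                    chromosome_id=feature.seqid,
                    start=feature.start,
                    end=feature.end,
                    strand=feature.strand,
                    rank=int(feature.attributes["rank"][0]),
                )
            )
    models = []
    for gid in order:
        info = genes[gid]
        ranks = [e.rank for e in info["exons"]]
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"gene {gid!r}: duplicate exon rank in annotation")
        attrs = info["attrs"]
        models.append(
            GeneModel(
                name=gid,
                gene_type=attrs.get("gene_type", "protein"),
                exons=info["exons"],
                codon_start=int(attrs.get("codon_start", 1)),
                annotated_start_is_ACG=attrs.get("acg_start", "0") in ("1", "true"),
            )
        )
    return models


def write_annotation(
    genes: Sequence[GeneModel],
    path: str | Path,
    chromosomes: Sequence[Chromosome] | None = None,
) -> None:
    """Write gene models in the GFF3 dialect read by :func:`read_annotation`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chromosomes:
            for chrom in chromosomes:
                fh.write(
                    f"{chrom.id}\tmitoedit\tregion\t1\t{len(chrom)}\t.\t+\t.\t"
                    f"ID={chrom.id};topology={chrom.topology}\n"
                )
        for gene in genes:
            attrs = f"ID={gene.name};gene_type={gene.gene_type};codon_start={gene.codon_start}"
            if gene.annotated_start_is_ACG:
                attrs += ";acg_start=1"
            # one (possibly discontinuous) gene feature per chromosome part
            for chrom_id in gene.chromosome_ids:
                part = [e for e in gene.exons if e.chromosome_id == chrom_id]
                start = min(e.start for e in part)
                end = max(e.end for e in part)
                fh.write(
                    f"{chrom_id}\tmitoedit\tgene\t{start}\t{end}\t.\t"
                    f"{part[0].strand}\t.\t{attrs}\n"
                )
            for exon in gene.exons:
                fh.write(
                    f"{exon.chromosome_id}\tmitoedit\texon\t{exon.start}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\tParent={gene.name};rank={exon.rank}\n"
                )


def validate_annotation(
    genes: Sequence[GeneModel], chromosomes: Sequence[Chromosome]
) -> None:
    """Check every exon against its chromosome; raise on any mismatch."""
    by_id = {c.id: c for c in chromosomes}
    for gene in genes:
        for exon in gene.exons:
            chrom = by_id.get(exon.chromosome_id)
            if chrom is None:
                raise ValueError(
                    f"gene {gene.name!r}: exon references unknown chromosome "
                    f"{exon.chromosome_id!r}"
                )
            if exon.end > len(chrom):
                raise ValueError(
                    f"gene {gene.name!r}: exon {exon.start}-{exon.end} beyond "
                    f"{chrom.id} length {len(chrom)}"
                )


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds(
    gene: GeneModel, genome: Sequence[Chromosome] | Mapping[str, Chromosome]
) -> SplicedCDS:
    """Build the artificially spliced sense-strand CDS of a gene.

    Exon subsequences are concatenated in rank order; minus-strand exons are
    reverse-complemented.  The ``codon_start`` offset trims the leading
    ``codon_start - 1`` bases so the returned sequence begins in frame.
    """
    if isinstance(genome, Mapping):
        by_id = dict(genome)
    else:
        by_id = {c.id: c for c in genome}
    parts: list[str] = []
    coords: list[tuple[str, int, str]] = []
    for exon in gene.exons:
        chrom = by_id.get(exon.chromosome_id)
        if chrom is None:
            raise ValueError(
                f"gene {gene.name!r}: unresolvable chromosome {exon.chromosome_id!r}"
            )
        if exon.end > len(chrom):
            raise ValueError(
                f"gene {gene.name!r}: exon {exon.start}-{exon.end} out of bounds on "
                f"{chrom.id} (length {len(chrom)})"
            )
        sub = chrom.sequence[exon.start - 1 : exon.end]
        if exon.strand == "+":
            parts.append(sub)
            coords.extend((chrom.id, pos, "+") for pos in range(exon.start, exon.end + 1))
        else:
            parts.append(reverse_complement(sub))
            coords.extend((chrom.id, pos, "-") for pos in range(exon.end, exon.start - 1, -1))
    offset = gene.codon_start - 1
    return SplicedCDS(
        gene_name=gene.name,
        sequence="".join(parts)[offset:],
        coord_map=coords[offset:],
    )


# ---------------------------------------------------------------------------
# Stats


def sequence_stats(chromosome: Chromosome) -> dict:
    """Length and GC fraction of a chromosome (N excluded from the denominator).

    Returns ``gc_fraction = nan`` for an all-N sequence.
    """
    seq = chromosome.sequence
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        warnings.warn(f"chromosome {chromosome.id!r}: all-N sequence, GC undefined")
        gc = float("nan")
    else:
        gc = (counts["G"] + counts["C"]) / denom
    return {"id": chromosome.id, "length": len(seq), "gc_fraction": gc}
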