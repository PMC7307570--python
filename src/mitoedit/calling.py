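"""Editing-site calling from RNA-seq alignments to spliced CDS references.

The caller mirrors a conservative organellar-editing workflow: alignments are
kept only if at least 80% of the read aligned with at least 90% identity
(lenient enough for reads spanning splice junctions and editing-dense
regions), per-position base tallies are built on each spliced CDS, and a site
is called edited when it is covered by at least 20 filtered reads of which at
least 10% differ from the genomic base.  All four thresholds are inclusive
("at least") and configurable via :class:`CallerConfig`.

Because the reference is the *sense-strand* spliced CDS, a genomic C read as
T is a C-to-U event regardless of the gene's genomic strand; no strand flip
is applied here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from .genome import GeneModel, SplicedCDS

__all__ = [
    "AlignmentRecord",
    "CallerConfig",
    "SiteCounts",
    "EditingSite",
    "read_sam",
    "filter_alignments",
    "pileup",
    "call_editing_sites",
    "classify_edit_type",
    "merge_samples",
    "expression_level",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the editing caller (all comparisons inclusive)."""

    min_coverage: int = 20
    min_edit_fraction: float = 0.10
    min_aligned_fraction: float = 0.80
    min_identity: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.min_edit_fraction <= 1:
            raise ValueError("min_edit_fraction must be in (0, 1]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        for name in ("min_aligned_fraction", "min_identity"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class AlignmentRecord:
    """A mapped read reduced to what the caller needs.

    ``base_calls`` holds ``(reference_position_1based, base)`` for every
    aligned (non-indel) read base, positions strictly increasing.
    """

    read_id: str
    reference_id: str
    reference_start: int  # 1-based leftmost aligned reference position
    aligned_read_fraction: float
    identity: float
    base_calls: list[tuple[int, str]]
    sample_id: str = ""


@dataclass
class SiteCounts:
    """Per-position base tally on one reference, one sample."""

    reference_id: str
    position: int  # 1-based CDS position
    counts: dict[str, int]
    sample_id: str = ""

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class EditingSite:
    """A called editing event on a spliced CDS.

    ``per_sample`` maps sample id -> ``(depth, edited_fraction)`` for samples
    in which the site passed both thresholds.
    """

    gene_name: str
    cds_position: int
    chromosome_id: str
    genomic_position: int
    strand: str
    ref_base: str
    alt_base: str
    edit_type: str
    per_sample: dict[str, tuple[int, float]] = field(default_factory=dict)

    @property
    def samples_present(self) -> frozenset[str]:
        return frozenset(self.per_sample)

    @property
    def key(self) -> tuple[str, int, str]:
        """Site identity across samples: (gene, CDS position, alt base)."""
        return (self.gene_name, self.cds_position, self.alt_base)


# ---------------------------------------------------------------------------
# SAM input


def read_sam(path: str | Path, sample_id: str = "") -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM file of reads mapped to spliced CDSs.

    Aligned fraction is aligned length / full read length (soft clips count as
    unaligned); identity is derived from the NM tag as
    ``(aligned_length - NM) / aligned_length`` (1.0 when NM is absent).
    """
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            read_length = aln.infer_read_length() or len(aln.query_sequence)
            aligned = aln.query_alignment_length
            if aligned == 0 or read_length == 0:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            seq = aln.query_sequence
            base_calls = [
                (rpos + 1, seq[qpos])
                for qpos, rpos in aln.get_aligned_pairs(matches_only=True)
            ]
            yield AlignmentRecord(
                read_id=aln.query_name,
                reference_id=aln.reference_name,
                reference_start=aln.reference_start + 1,
                aligned_read_fraction=aligned / read_length,
                identity=max(0.0, (aligned - nm) / aligned),
                base_calls=base_calls,
                sample_id=sample_id,
            )


def filter_alignments(
    records: Iterable[AlignmentRecord], cfg: CallerConfig = CallerConfig()
) -> Iterator[AlignmentRecord]:
    """Keep records with aligned fraction and identity at or above thresholds."""
    for rec in records:
        if not (0 <= rec.aligned_read_fraction <= 1 and 0 <= rec.identity <= 1):
            raise ValueError(
                f"read {rec.read_id!r}: aligned fraction/identity outside [0, 1]"
            )
        if (
            rec.aligned_read_fraction >= cfg.min_aligned_fraction
            and rec.identity >= cfg.min_identity
        ):
            yield rec


# ---------------------------------------------------------------------------
# Pileup and calling


def pileup(
    records: Iterable[AlignmentRecord],
    reference: SplicedCDS,
    sample_id: str = "",
) -> list[SiteCounts]:
    """Tally base counts per covered reference position.

    Insertions never appear in ``base_calls``; deleted positions contribute no
    count.  N base calls are ignored with a warning.
    """
    length = len(reference)
    tally = np.zeros((4, length), dtype=np.int64)
    saw_n = False
    for rec in records:
        if rec.reference_id != reference.gene_name:
            raise ValueError(
                f"read {rec.read_id!r} aligned to {rec.reference_id!r}, "
                f"not {reference.gene_name!r}"
            )
        for pos, base in rec.base_calls:
            if not 1 <= pos <= length:
                raise ValueError(
                    f"read {rec.read_id!r}: base call at {pos} outside reference"
                )
            idx = _BASE_INDEX.get(base)
            if idx is None:
                saw_n = True
                continue
            tally[idx, pos - 1] += 1
    if saw_n:
        warnings.warn(f"{reference.gene_name}: non-ACGT base calls ignored")
    out = []
    for pos0 in np.nonzero(tally.sum(axis=0))[0]:
        counts = {
            _BASES[i]: int(tally[i, pos0]) for i in range(4) if tally[i, pos0] > 0
        }
        out.append(
            SiteCounts(
                reference_id=reference.gene_name,
                position=int(pos0) + 1,
                counts=counts,
                sample_id=sample_id,
            )
        )
    return out


def classify_edit_type(ref_base: str, alt_base: str) -> str:
    """Name the edit class: C>T is C-to-U, A>G is A-to-G (read as inosine)."""
    if ref_base == alt_base:
        raise ValueError("ref and alt base are equal; not an edit")
    if (ref_base, alt_base) == ("C", "T"):
        return "C_to_U"
    if (ref_base, alt_base) == ("A", "G"):
        return "A_to_G"
    return f"other_{ref_base}_{alt_base}"


def call_editing_sites(
    counts: Iterable[SiteCounts],
    reference: SplicedCDS,
    cfg: CallerConfig = CallerConfig(),
    sample_id: str | None = None,
) -> list[EditingSite]:
    """Call edited sites in one sample with the coverage/fraction rule.

    A site is emitted iff ``depth >= min_coverage`` and the total non-reference
    fraction ``(depth - count(ref)) / depth >= min_edit_fraction``.  The alt
    base is the modal non-reference base (ties broken A<C<G<T) and the
    reported edited fraction is the alt base's own fraction.
    """
    sites = []
    for sc in counts:
        ref_base = reference.sequence[sc.position - 1]
        if ref_base not in _BASE_INDEX:
            warnings.warn(
                f"{reference.gene_name}:{sc.position}: reference base {ref_base!r}; "
                "site skipped"
            )
            continue
        depth = sc.depth
        if depth < cfg.min_coverage:
            continue
        non_ref = depth - sc.counts.get(ref_base, 0)
        if non_ref / depth < cfg.min_edit_fraction:
            continue
        alt_base = max(
            (b for b in _BASES if b != ref_base),
            key=lambda b: (sc.counts.get(b, 0), -_BASE_INDEX[b]),
        )
        chrom, gpos, strand = reference.genomic_location(sc.position)
        sid = sample_id if sample_id is not None else sc.sample_id
        sites.append(
            EditingSite(
                gene_name=reference.gene_name,
                cds_position=sc.position,
                chromosome_id=chrom,
                genomic_position=gpos,
                strand=strand,
                ref_base=ref_base,
                alt_base=alt_base,
                edit_type=classify_edit_type(ref_base, alt_base),
                per_sample={sid: (depth, sc.counts.get(alt_base, 0) / depth)},
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Multi-sample merging


def merge_samples(
    per_sample: Mapping[str, Sequence[EditingSite]],
) -> tuple[list[EditingSite], dict[frozenset[str], int]]:
    """Union per-sample calls into multi-sample sites plus Venn occurrence counts.

    Sites are keyed by (gene, CDS position, alt base); the occurrence table
    maps every observed sample subset to the number of sites present in
    exactly that subset.  All samples appear in the table (zero cells for
    subsets with no site are omitted).
    """
    merged: dict[tuple, EditingSite] = {}
    for sid, sites in per_sample.items():
        for site in sites:
            existing = merged.get(site.key)
            if existing is None:
                merged[site.key] = EditingSite(
                    gene_name=site.gene_name,
                    cds_position=site.cds_position,
                    chromosome_id=site.chromosome_id,
                    genomic_position=site.genomic_position,
                    strand=site.strand,
                    ref_base=site.ref_base,
                    alt_base=site.alt_base,
                    edit_type=site.edit_type,
                    per_sample=dict(site.per_sample),
                )
            else:
                if existing.ref_base != site.ref_base:
                    raise ValueError(
                        f"{site.gene_name}:{site.cds_position}: conflicting reference "
                        f"base across samples ({existing.ref_base} vs {site.ref_base})"
                    )
                existing.per_sample.update(site.per_sample)
    sites = sorted(merged.values(), key=lambda s: (s.gene_name, s.cds_position, s.alt_base))
    occurrence: dict[frozenset[str], int] = {}
    for site in sites:
        subset = site.samples_present
        occurrence[subset] = occurrence.get(subset, 0) + 1
    return sites, occurrence


def expression_level(gene: GeneModel, mapped_pairs: int) -> float:
    """Expression as mapped read pairs per bp of spliced gene length."""
    if gene.length <= 0:
        raise ValueError(f"gene {gene.name!r}: zero length")
    return mapped_pairs / gene.length
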