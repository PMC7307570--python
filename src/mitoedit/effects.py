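"""Codon-level consequences of editing sites and per-gene editing density.

Each site is annotated against the reference codon by default (single-site
mode); an optional joint mode annotates against the codon with all *other*
co-occurring edits already applied, for codons carrying more than one edit.
Plant mitochondria translate with the standard genetic code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .calling import EditingSite
from .genome import SplicedCDS

__all__ = [
    "EditingEffect",
    "GeneEditingSummary",
    "annotate_effect",
    "editing_density",
    "edited_transcript",
    "translate_codon",
    "NONSYNONYMOUS_CATEGORIES",
]

# Categories that change the protein; used for dEN/dES event classification
# (premature stops and start gains follow the dN/dS convention of counting as
# nonsynonymous).
NONSYNONYMOUS_CATEGORIES = frozenset(
    {"nonsynonymous", "start_gained", "stop_gained", "stop_lost"}
)


# standard code, precomputed once (dict lookup is on the hot path)
_STANDARD_TABLE = dict(unambiguous_dna_by_id[1].forward_table)
_STANDARD_TABLE.update({stop: "*" for stop in unambiguous_dna_by_id[1].stop_codons})


def translate_codon(codon: str) -> str:
    """One codon to amino acid with the standard code; '*' for stop, 'X' for N."""
    aa = _STANDARD_TABLE.get(codon)
    if aa is None:
        return "X"
    return aa


@dataclass(frozen=True)
class EditingEffect:
    """Consequence of one editing site within its codon."""

    gene_name: str
    cds_position: int
    category: str  # synonymous | nonsynonymous | start_gained | stop_gained
    #               | stop_lost | non_coding
    codon_index: int  # 1-based codon number
    codon_position: int  # 1..3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str


@dataclass(frozen=True)
class GeneEditingSummary:
    """Per-gene editing burden; density is sites per 100 bp of spliced CDS."""

    gene_name: str
    n_sites: int
    cds_length: int
    density: float
    n_synonymous: int
    n_nonsynonymous: int


def _classify(codon_index: int, ref_codon: str, alt_codon: str) -> tuple[str, str, str]:
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if "N" in ref_codon or "N" in alt_codon:
        return "non_coding", ref_aa, alt_aa
    if ref_aa == alt_aa:
        category = "synonymous"
    elif codon_index == 1 and alt_codon == "ATG" and ref_codon != "ATG":
        category = "start_gained"
    elif alt_aa == "*":
        category = "stop_gained"
    elif ref_aa == "*":
        category = "stop_lost"
    else:
        category = "nonsynonymous"
    return category, ref_aa, alt_aa


def annotate_effect(
    site: EditingSite,
    cds: SplicedCDS,
    co_sites: Sequence[EditingSite] | None = None,
) -> EditingEffect:
    """Annotate one editing site's codon-level consequence.

    With ``co_sites`` given, other edits falling in the same codon are applied
    to the background before the focal substitution (joint mode); otherwise
    the unedited reference codon is the background.  Positions in a trailing
    partial codon are reported ``non_coding``.
    """
    pos = site.cds_position
    if not 1 <= pos <= len(cds):
        raise ValueError(f"{site.gene_name}: CDS position {pos} outside 1..{len(cds)}")
    codon_index = (pos - 1) // 3 + 1
    codon_position = (pos - 1) % 3 + 1
    codon_start0 = (codon_index - 1) * 3
    ref_codon = cds.sequence[codon_start0 : codon_start0 + 3]
    if len(ref_codon) < 3:
        warnings.warn(
            f"{site.gene_name}:{pos}: site in trailing partial codon; non-coding"
        )
        return EditingEffect(
            gene_name=site.gene_name,
            cds_position=pos,
            category="non_coding",
            codon_index=codon_index,
            codon_position=codon_position,
            ref_codon=ref_codon,
            alt_codon=ref_codon,
            ref_aa="",
            alt_aa="",
        )
    background = list(ref_codon)
    if co_sites:
        for other in co_sites:
            if other.cds_position == pos:
                continue
            offset = other.cds_position - 1 - codon_start0
            if 0 <= offset < 3:
                background[offset] = other.alt_base
    background_codon = "".join(background)
    alt = list(background)
    alt[codon_position - 1] = site.alt_base
    alt_codon = "".join(alt)
    category, ref_aa, alt_aa = _classify(codon_index, background_codon, alt_codon)
    return EditingEffect(
        gene_name=site.gene_name,
        cds_position=pos,
        category=category,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=background_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


def editing_density(
    sites: Sequence[EditingSite],
    cds: SplicedCDS,
    effects: Sequence[EditingEffect] | None = None,
) -> GeneEditingSummary:
    """Summarise a gene's editing: site count, density per 100 bp, syn/nonsyn split."""
    if len(cds) == 0:
        raise ValueError(f"{cds.gene_name}: empty CDS")
    if effects is None:
        effects = [annotate_effect(site, cds) for site in sites]
    n_syn = sum(1 for e in effects if e.category == "synonymous")
    n_nonsyn = sum(1 for e in effects if e.category in NONSYNONYMOUS_CATEGORIES)
    return GeneEditingSummary(
        gene_name=cds.gene_name,
        n_sites=len(sites),
        cds_length=len(cds),
        density=100.0 * len(sites) / len(cds),
        n_synonymous=n_syn,
        n_nonsynonymous=n_nonsyn,
    )


def edited_transcript(cds: SplicedCDS, sites: Iterable[EditingSite]) -> str:
    """Apply all editing sites to the CDS, yielding the mature transcript (as DNA)."""
    seq = list(cds.sequence)
    applied: dict[int, str] = {}
    for site in sites:
        pos = site.cds_position
        if not 1 <= pos <= len(seq):
            raise ValueError(f"{cds.gene_name}: site at {pos} outside CDS")
        if pos in applied and applied[pos] != site.alt_base:
            raise ValueError(
                f"{cds.gene_name}:{pos}: conflicting alt bases "
                f"{applied[pos]} vs {site.alt_base}"
            )
        applied[pos] = site.alt_base
        seq[pos - 1] = site.alt_base
    return "".join(seq)
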