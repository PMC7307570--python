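"""dEN/dES: nonsynonymous-to-synonymous editing, normalised by potential sites.

The statistic is the editing analogue of dN/dS: for a given edit class
(C-to-U by default), every base of that class in a CDS is a *potential* site,
classified nonsynonymous (N) or synonymous (S) by substituting the edited
base into its codon and translating.  With EN and ES the observed edit counts
in each class,

    dEN/dES = (EN / N) / (ES / S).

Values above 1 indicate editing enriched at protein-changing positions.
Because only one substitution type exists per edit class, each eligible base
is counted exactly once — no Nei–Gojobori multi-path averaging is needed.
Changes to or from a stop codon count as nonsynonymous, as in dN/dS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .effects import NONSYNONYMOUS_CATEGORIES, EditingEffect, translate_codon
from .genome import SplicedCDS

__all__ = [
    "PotentialSiteCounts",
    "DenDesResult",
    "count_potential_sites",
    "den_des",
    "median_den_des",
    "EDIT_SUBSTITUTIONS",
]

# edit class -> (reference base, substituted base) on the sense strand
EDIT_SUBSTITUTIONS = {"C_to_U": ("C", "T"), "A_to_G": ("A", "G")}


@dataclass(frozen=True)
class PotentialSiteCounts:
    """Potential edit-site counts of one gene for one edit class."""

    gene_name: str
    N: int
    S: int
    edit_type: str = "C_to_U"
    # positions kept for the observed-edit consistency check
    nonsynonymous_positions: frozenset[int] = frozenset()
    synonymous_positions: frozenset[int] = frozenset()


@dataclass(frozen=True)
class DenDesResult:
    """Observed and potential counts and the dEN/dES ratio of one gene.

    ``ratio`` is ``nan`` (undefined) unless N > 0, S > 0 and ES > 0.
    """

    gene_name: str
    EN: int
    ES: int
    N: int
    S: int
    ratio: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ratio)


def count_potential_sites(cds: SplicedCDS, edit_type: str = "C_to_U") -> PotentialSiteCounts:
    """Classify every potential edit site of a CDS as synonymous or nonsynonymous.

    A trailing partial codon is dropped.  For each base matching the edit
    class's reference base, the edited base is substituted and both codons
    translated; identical amino acids make a synonymous site, anything else
    (including gaining or losing a stop) a nonsynonymous site.  Codons
    containing N are excluded.
    """
    ref_base, alt_base = EDIT_SUBSTITUTIONS[edit_type]
    seq = cds.sequence
    n_codons = len(seq) // 3
    n_pos: list[int] = []
    s_pos: list[int] = []
    for ci in range(n_codons):
        codon = seq[3 * ci : 3 * ci + 3]
        if "N" in codon:
            continue
        for offset in range(3):
            if codon[offset] != ref_base:
                continue
            alt_codon = codon[:offset] + alt_base + codon[offset + 1 :]
            pos = 3 * ci + offset + 1
            if translate_codon(codon) == translate_codon(alt_codon):
                s_pos.append(pos)
            else:
                n_pos.append(pos)
    return PotentialSiteCounts(
        gene_name=cds.gene_name,
        N=len(n_pos),
        S=len(s_pos),
        edit_type=edit_type,
        nonsynonymous_positions=frozenset(n_pos),
        synonymous_positions=frozenset(s_pos),
    )


def den_des(
    effects: Sequence[EditingEffect],
    potential: PotentialSiteCounts,
    strict: bool = True,
) -> DenDesResult:
    """Compute dEN/dES for one gene from classified observed edits.

    ``effects`` should contain only edits of the class ``potential`` was
    computed for; with ``strict`` each observed edit must sit at a potential
    site of the matching class, otherwise the two inputs are inconsistent.
    """
    en = es = 0
    for eff in effects:
        if eff.category == "non_coding":
            continue
        if eff.category == "synonymous":
            expected = potential.synonymous_positions
            es += 1
        elif eff.category in NONSYNONYMOUS_CATEGORIES:
            expected = potential.nonsynonymous_positions
            en += 1
        else:
            raise ValueError(f"unknown effect category {eff.category!r}")
        if strict and expected and eff.cds_position not in expected:
            raise ValueError(
                f"{potential.gene_name}: observed {eff.category} edit at CDS position "
                f"{eff.cds_position} is not a potential {potential.edit_type} site of "
                "that class"
            )
    if potential.N > 0 and potential.S > 0 and es > 0:
        ratio = (en / potential.N) / (es / potential.S)
    else:
        ratio = float("nan")
    return DenDesResult(
        gene_name=potential.gene_name,
        EN=en,
        ES=es,
        N=potential.N,
        S=potential.S,
        ratio=ratio,
    )


def median_den_des(results: Sequence[DenDesResult]) -> float:
    """Median ratio over genes with a defined dEN/dES (even count: mean of middle two)."""
    defined = [r.ratio for r in results if r.defined]
    if not defined:
        raise ValueError("no gene has a defined dEN/dES ratio")
    return float(np.median(defined))
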