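"""Cross-species conservation of editing positions on codon-aware alignments.

Shared genes (matched by name across species' annotations) are aligned at
the protein level — global alignment with BLOSUM62 and affine gap penalties,
center-star merged for three or more species — and the alignment is
back-threaded to nucleotides so gaps fall on whole codons.  Each alignment
column carrying an editing site in at least one species is then classified:
edited in every species, or, in the non-editing species, occupied by T
(editing site lost by replacement with the edited product), by A/G, or by an
unedited C.  Columns with gaps or other degeneracies fall into a catch-all
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome import SplicedCDS

__all__ = [
    "HomologSet",
    "CodonAlignment",
    "AlignedColumnClass",
    "make_protein_aligner",
    "align_homologs",
    "classify_column",
    "classify_alignment",
    "conservation_summary",
    "COLUMN_CLASSES",
]

COLUMN_CLASSES = (
    "edited_all",
    "T_at_unedited",
    "AG_at_unedited",
    "unedited_C",
    "mixed_other",
)


@dataclass
class HomologSet:
    """One gene's CDSs and editing positions across two or more species."""

    gene_name: str
    cds: dict[str, SplicedCDS]
    editing_positions: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cds) < 2:
            raise ValueError(f"{self.gene_name}: need at least two species")
        for species, positions in self.editing_positions.items():
            if species not in self.cds:
                raise ValueError(f"{self.gene_name}: editing for unknown species {species!r}")
            length = len(self.cds[species])
            for pos in positions:
                if not 1 <= pos <= length:
                    raise ValueError(
                        f"{self.gene_name}/{species}: editing position {pos} outside CDS"
                    )

    @property
    def species(self) -> list[str]:
        return list(self.cds)


@dataclass
class CodonAlignment:
    """A codon-aware nucleotide alignment with per-species position/column maps.

    Columns are 1-based; ``pos_to_col[sp][i]`` is the column of CDS position
    ``i + 1`` and ``col_to_pos[sp]`` inverts it for non-gap columns.
    """

    gene_name: str
    nt_rows: dict[str, str]
    protein_rows: dict[str, str]
    pos_to_col: dict[str, list[int]]
    col_to_pos: dict[str, dict[int, int]]
    pairwise_scores: dict[str, float]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.nt_rows.values())))


def make_protein_aligner() -> Align.PairwiseAligner:
    """Global protein aligner: BLOSUM62, gap open -10, gap extend -0.5."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # the aggregate setters cover end gaps too: a true global alignment
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _translate(cds: SplicedCDS, gene: str, species: str) -> str:
    from .effects import translate_codon

    n_codons = len(cds) // 3
    if n_codons == 0:
        raise ValueError(f"{gene}/{species}: empty translation")
    return "".join(translate_codon(cds.sequence[3 * i : 3 * i + 3]) for i in range(n_codons))


def _merge_into_star(
    master_center: list[str],
    other_rows: dict[str, list[str]],
    gapped_center: str,
    gapped_new: str,
) -> tuple[list[str], dict[str, list[str]], list[str]]:
    """Merge one pairwise (center, new) alignment into the center-star MSA."""
    new_master: list[str] = []
    new_rows: dict[str, list[str]] = {sp: [] for sp in other_rows}
    new_row: list[str] = []
    i = j = 0
    while i < len(master_center) or j < len(gapped_center):
        master_gap = i < len(master_center) and master_center[i] == "-"
        pair_gap = j < len(gapped_center) and gapped_center[j] == "-"
        if master_gap:  # column without a center residue from earlier merges
            new_master.append("-")
            for sp in other_rows:
                new_rows[sp].append(other_rows[sp][i])
            new_row.append("-")
            i += 1
        elif pair_gap:  # new-species insertion relative to the center
            new_master.append("-")
            for sp in other_rows:
                new_rows[sp].append("-")
            new_row.append(gapped_new[j])
            j += 1
        else:  # both hold the same center residue
            new_master.append(master_center[i])
            for sp in other_rows:
                new_rows[sp].append(other_rows[sp][i])
            new_row.append(gapped_new[j])
            i += 1
            j += 1
    return new_master, new_rows, new_row


def align_homologs(homologs: HomologSet) -> CodonAlignment:
    """Codon-aware multiple alignment of one gene's CDSs across species.

    Proteins are aligned pairwise against the first species (the star
    center); additional species are merged by threading their pairwise
    alignments through the shared center row.  Gaps always span whole codons
    in the nucleotide view.
    """
    species = homologs.species
    proteins = {
        sp: _translate(homologs.cds[sp], homologs.gene_name, sp) for sp in species
    }
    aligner = make_protein_aligner()
    center = species[0]
    master: list[str] = list(proteins[center])
    rows: dict[str, list[str]] = {}
    scores: dict[str, float] = {}
    for sp in species[1:]:
        alignment = aligner.align(proteins[center], proteins[sp])[0]
        scores[sp] = float(alignment.score)
        master, rows, new_row = _merge_into_star(
            master, rows, str(alignment[0]), str(alignment[1])
        )
        rows[sp] = new_row
    protein_rows = {center: "".join(master)}
    protein_rows.update({sp: "".join(rows[sp]) for sp in species[1:]})

    nt_rows: dict[str, str] = {}
    pos_to_col: dict[str, list[int]] = {}
    col_to_pos: dict[str, dict[int, int]] = {}
    for sp in species:
        cds_seq = homologs.cds[sp].sequence
        chunks: list[str] = []
        p2c: list[int] = []
        c2p: dict[int, int] = {}
        aa_index = 0
        for col0, aa in enumerate(protein_rows[sp]):
            if aa == "-":
                chunks.append("---")
            else:
                codon = cds_seq[3 * aa_index : 3 * aa_index + 3]
                chunks.append(codon)
                for k in range(3):
                    nt_pos = 3 * aa_index + k + 1
                    nt_col = 3 * col0 + k + 1
                    p2c.append(nt_col)
                    c2p[nt_col] = nt_pos
                aa_index += 1
        nt_rows[sp] = "".join(chunks)
        pos_to_col[sp] = p2c
        col_to_pos[sp] = c2p
    return CodonAlignment(
        gene_name=homologs.gene_name,
        nt_rows=nt_rows,
        protein_rows=protein_rows,
        pos_to_col=pos_to_col,
        col_to_pos=col_to_pos,
        pairwise_scores=scores,
    )


@dataclass(frozen=True)
class AlignedColumnClass:
    """One edited alignment column and its conservation class."""

    gene_name: str
    column: int
    residues: Mapping[str, str]
    edited_species: frozenset[str]
    category: str


def classify_column(
    residues: Mapping[str, str],
    edited_species: frozenset[str] | set[str],
    all_species: Sequence[str],
    gene_name: str = "",
    column: int = 0,
) -> AlignedColumnClass:
    """Classify one column carrying at least one species' editing site.

    Edited in every species -> ``edited_all``; otherwise by the non-editing
    species' residues: all T -> ``T_at_unedited``, any A or G ->
    ``AG_at_unedited``, an unedited C present -> ``unedited_C``; gaps or
    anything degenerate -> ``mixed_other``.
    """
    edited = frozenset(edited_species)
    if not edited:
        raise ValueError("column has no edited species")
    unedited = [sp for sp in all_species if sp not in edited]
    if not unedited:
        category = "edited_all"
    else:
        bases = [residues.get(sp, "-") for sp in unedited]
        if any(b not in "ACGT" for b in bases):
            category = "mixed_other"
        elif all(b == "T" for b in bases):
            category = "T_at_unedited"
        elif any(b in "AG" for b in bases):
            category = "AG_at_unedited"
        elif any(b == "C" for b in bases):
            category = "unedited_C"
        else:
            category = "mixed_other"
    return AlignedColumnClass(
        gene_name=gene_name,
        column=column,
        residues=dict(residues),
        edited_species=edited,
        category=category,
    )


def classify_alignment(
    homologs: HomologSet, alignment: CodonAlignment | None = None
) -> list[AlignedColumnClass]:
    """Classify every alignment column edited in at least one species."""
    if alignment is None:
        alignment = align_homologs(homologs)
    species = homologs.species
    edited_by_column: dict[int, set[str]] = {}
    for sp in species:
        p2c = alignment.pos_to_col[sp]
        for pos in homologs.editing_positions.get(sp, set()):
            if pos <= len(p2c):  # positions in a dropped trailing codon are skipped
                edited_by_column.setdefault(p2c[pos - 1], set()).add(sp)
    out = []
    for col in sorted(edited_by_column):
        residues = {sp: alignment.nt_rows[sp][col - 1] for sp in species}
        out.append(
            classify_column(
                residues,
                edited_by_column[col],
                species,
                gene_name=homologs.gene_name,
                column=col,
            )
        )
    return out


def conservation_summary(
    columns: Sequence[AlignedColumnClass],
) -> dict:
    """Count edited columns per conservation class, with fractions of the total."""
    counts = {cls: 0 for cls in COLUMN_CLASSES}
    for col in columns:
        counts[col.category] += 1
    total = len(columns)
    fractions = {
        cls: (counts[cls] / total if total else 0.0) for cls in COLUMN_CLASSES
    }
    return {"total_edited_positions": total, "counts": counts, "fractions": fractions}
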