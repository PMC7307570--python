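"""End-to-end analyses composed from the individual stages.

Each runner validates its inputs up front, executes the stages in order,
writes TSV/JSON outputs plus a manifest with input digests, and removes any
partial outputs if a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calling import (
    CallerConfig,
    EditingSite,
    call_editing_sites,
    filter_alignments,
    merge_samples,
    pileup,
    read_sam,
)
from .crossspecies import (
    HomologSet,
    classify_alignment,
    conservation_summary,
)
from .dendes import DenDesResult, count_potential_sites, den_des, median_den_des
from .effects import EditingEffect, annotate_effect, editing_density
from .genome import (
    Chromosome,
    GeneModel,
    SplicedCDS,
    extract_cds,
    read_annotation,
    read_fasta,
    validate_annotation,
)
from .structure import (
    DEFAULT_MAX_INSERT,
    classify_mate_pair,
    detect_terminal_taper,
    position_profiles,
    read_matepairs_sam,
)

logger = logging.getLogger("mitoedit")

__all__ = [
    "EditingAnalysisResult",
    "StructureDiagnosticsResult",
    "CrossSpeciesResult",
    "run_editing_analysis",
    "run_structure_diagnostics",
    "run_cross_species",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _OutputTracker:
    """Removes everything written so far when a stage fails."""

    def __init__(self) -> None:
        self.paths: list[Path] = []

    def register(self, path: Path) -> Path:
        self.paths.append(path)
        return path

    def rollback(self) -> None:
        for path in self.paths:
            path.unlink(missing_ok=True)


@dataclass
class EditingAnalysisResult:
    sites: list[EditingSite]
    effects: dict[tuple[str, int, str], EditingEffect]
    occurrence: dict[frozenset[str], int]
    gene_summaries: pd.DataFrame
    dendes: list[DenDesResult]
    median_dendes: float
    cds: dict[str, SplicedCDS]
    out_dir: Path | None = None


def _write_sites_tsv(
    path: Path,
    sites: Sequence[EditingSite],
    effects: Mapping[tuple, EditingEffect],
    samples: Sequence[str],
) -> None:
    cols = [
        "gene", "cds_pos", "chrom", "genomic_pos", "strand", "ref", "alt",
        "edit_type", "effect",
    ]
    for s in samples:
        cols += [f"{s}_depth", f"{s}_fraction"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for site in sites:
            eff = effects[site.key]
            row = [
                site.gene_name, str(site.cds_position), site.chromosome_id,
                str(site.genomic_position), site.strand, site.ref_base,
                site.alt_base, site.edit_type, eff.category,
            ]
            for s in samples:
                if s in site.per_sample:
                    depth, frac = site.per_sample[s]
                    row += [str(depth), f"{frac:.4f}"]
                else:
                    row += [".", "."]
            fh.write("\t".join(row) + "\n")


def _write_sites_vcf(path: Path, sites: Sequence[EditingSite]) -> None:
    """VCF-style records against the spliced CDS coordinates, for interoperability."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=mitoedit {__version__}\n")
        fh.write('##INFO=<ID=ETYPE,Number=1,Type=String,Description="Edit class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for site in sites:
            fh.write(
                f"{site.gene_name}\t{site.cds_position}\t.\t{site.ref_base}\t"
                f"{site.alt_base}\t.\tPASS\tETYPE={site.edit_type}\n"
            )


def run_editing_analysis(
    genome_fasta: str | Path,
    annotation_gff3: str | Path,
    sam_by_sample: Mapping[str, str | Path],
    cfg: CallerConfig = CallerConfig(),
    out_dir: str | Path | None = None,
) -> EditingAnalysisResult:
    """Full editing analysis: spliced CDSs -> filter -> pileup -> call -> merge
    -> effects -> dEN/dES.

    Inputs are validated before any stage runs; on a stage failure partial
    outputs are removed and the error re-raised with the stage name.
    """
    logger.info(
        "editing analysis: min_coverage=%d min_edit_fraction=%.2f "
        "min_aligned_fraction=%.2f min_identity=%.2f",
        cfg.min_coverage, cfg.min_edit_fraction, cfg.min_aligned_fraction,
        cfg.min_identity,
    )
    tracker = _OutputTracker()
    stage = "validate"
    try:
        chromosomes = read_fasta(genome_fasta)
        genes = read_annotation(annotation_gff3)
        validate_annotation(genes, chromosomes)
        samples = list(sam_by_sample)

        stage = "extract_cds"
        cds = {
            g.name: extract_cds(g, chromosomes)
            for g in genes
            if g.gene_type in ("protein", "orf")
        }

        stage = "call"
        per_sample_sites: dict[str, list[EditingSite]] = {}
        for sample, sam_path in sam_by_sample.items():
            records = list(filter_alignments(read_sam(sam_path, sample), cfg))
            by_ref: dict[str, list] = {}
            for rec in records:
                by_ref.setdefault(rec.reference_id, []).append(rec)
            sites: list[EditingSite] = []
            for gene_name, recs in by_ref.items():
                if gene_name not in cds:
                    raise ValueError(
                        f"sample {sample!r}: alignments to unknown reference "
                        f"{gene_name!r}"
                    )
                counts = pileup(recs, cds[gene_name], sample)
                sites.extend(
                    call_editing_sites(counts, cds[gene_name], cfg, sample_id=sample)
                )
            per_sample_sites[sample] = sites
            logger.info("sample %s: %d sites", sample, len(sites))

        stage = "merge"
        merged, occurrence = merge_samples(per_sample_sites)

        stage = "effects"
        effects: dict[tuple, EditingEffect] = {}
        sites_by_gene: dict[str, list[EditingSite]] = {}
        for site in merged:
            sites_by_gene.setdefault(site.gene_name, []).append(site)
        for site in merged:
            effects[site.key] = annotate_effect(site, cds[site.gene_name])

        stage = "summaries"
        rows = []
        dendes_results = []
        for gene_name, gene_cds in cds.items():
            gene_sites = sites_by_gene.get(gene_name, [])
            gene_effects = [effects[s.key] for s in gene_sites]
            summary = editing_density(gene_sites, gene_cds, gene_effects)
            rows.append(
                {
                    "gene": gene_name,
                    "n_sites": summary.n_sites,
                    "cds_length": summary.cds_length,
                    "density_per_100bp": round(summary.density, 4),
                    "EN": summary.n_nonsynonymous,
                    "ES": summary.n_synonymous,
                }
            )
            potential = count_potential_sites(gene_cds, "C_to_U")
            ctu_effects = [
                effects[s.key] for s in gene_sites if s.edit_type == "C_to_U"
            ]
            dendes_results.append(den_des(ctu_effects, potential))
        gene_summaries = pd.DataFrame(rows)
        defined = [r for r in dendes_results if r.defined]
        median = median_den_des(dendes_results) if defined else float("nan")

        stage = "write"
        result = EditingAnalysisResult(
            sites=merged,
            effects=effects,
            occurrence=occurrence,
            gene_summaries=gene_summaries,
            dendes=dendes_results,
            median_dendes=median,
            cds=cds,
        )
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            result.out_dir = out_dir
            _write_sites_tsv(
                tracker.register(out_dir / "editing_sites.tsv"), merged, effects, samples
            )
            _write_sites_vcf(tracker.register(out_dir / "editing_sites.vcf"), merged)
            gene_summaries.to_csv(
                tracker.register(out_dir / "gene_summary.tsv"), sep="\t", index=False
            )
            with open(tracker.register(out_dir / "dendes.tsv"), "w") as fh:
                fh.write("gene\tEN\tES\tN\tS\tratio\n")
                for r in dendes_results:
                    ratio = f"{r.ratio:.4f}" if r.defined else "NA"
                    fh.write(f"{r.gene_name}\t{r.EN}\t{r.ES}\t{r.N}\t{r.S}\t{ratio}\n")
                fh.write(
                    f"#median\t\t\t\t\t{median:.4f}\n"
                    if not math.isnan(median)
                    else "#median\t\t\t\t\tNA\n"
                )
            with open(tracker.register(out_dir / "occurrence.tsv"), "w") as fh:
                fh.write("samples\tn_sites\n")
                for subset in sorted(occurrence, key=lambda s: (len(s), sorted(s))):
                    fh.write(f"{','.join(sorted(subset))}\t{occurrence[subset]}\n")
            manifest = {
                "tool_version": __version__,
                "config": {
                    "min_coverage": cfg.min_coverage,
                    "min_edit_fraction": cfg.min_edit_fraction,
                    "min_aligned_fraction": cfg.min_aligned_fraction,
                    "min_identity": cfg.min_identity,
                },
                "inputs": {
                    "genome": _sha256(Path(genome_fasta)),
                    "annotation": _sha256(Path(annotation_gff3)),
                    **{
                        f"sam_{s}": _sha256(Path(p)) for s, p in sam_by_sample.items()
                    },
                },
                "n_sites_total": len(merged),
                "n_sites_per_sample": {
                    s: len(v) for s, v in per_sample_sites.items()
                },
                "median_dendes": None if math.isnan(median) else round(median, 4),
                "outputs": [p.name for p in tracker.paths],
            }
            with open(out_dir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
        return result
    except Exception as exc:
        tracker.rollback()
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


@dataclass
class StructureDiagnosticsResult:
    classification_counts: dict[str, int]
    improper_fraction: float
    taper_verdicts: dict[str, dict[str, str]]  # linear chromosomes only
    profiles: dict[str, object]
    out_dir: Path | None = None


def run_structure_diagnostics(
    genome_fasta: str | Path,
    matepair_sam: str | Path,
    d_max: int = DEFAULT_MAX_INSERT,
    window: int | None = None,
    out_dir: str | Path | None = None,
) -> StructureDiagnosticsResult:
    """Mate-pair propriety, per-position profiles and terminal-taper verdicts.

    Taper detection runs only on chromosomes declared linear; the default
    window is twice the mean outer span of proper pairs, capped below half
    the chromosome length.
    """
    logger.info("structure diagnostics: d_max=%d", d_max)
    chromosomes = read_fasta(genome_fasta)
    pairs = read_matepairs_sam(matepair_sam)
    classifications = [classify_mate_pair(p, d_max=d_max) for p in pairs]
    counts: dict[str, int] = {}
    for c in classifications:
        counts[c.reason] = counts.get(c.reason, 0) + 1
    n_improper = sum(1 for c in classifications if c.status == "improper")
    improper_fraction = n_improper / len(pairs) if pairs else 0.0

    reads = [r for p in pairs for r in (p.read1, p.read2)]
    profiles = {}
    verdicts = {}
    spans = [p.outer_span for p, c in zip(pairs, classifications) if c.status == "proper"]
    mean_span = float(np.mean(spans)) if spans else 0.0
    for chrom in chromosomes:
        profile = position_profiles(chrom, reads=reads, pairs=pairs, d_max=d_max)
        profiles[chrom.id] = profile
        if chrom.topology == "linear":
            win = window if window is not None else int(2 * mean_span)
            win = min(win, len(chrom) // 2 - 1)
            if win > 0:
                verdicts[chrom.id] = detect_terminal_taper(profile, window=win)

    result = StructureDiagnosticsResult(
        classification_counts=counts,
        improper_fraction=improper_fraction,
        taper_verdicts=verdicts,
        profiles=profiles,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.out_dir = out_dir
        with open(out_dir / "matepair_summary.tsv", "w") as fh:
            fh.write("reason\tn_pairs\n")
            for reason in ("none", "inter_chromosomal", "same_orientation", "outward", "distant"):
                if reason in counts:
                    fh.write(f"{reason}\t{counts[reason]}\n")
            fh.write(f"#improper_fraction\t{improper_fraction:.6g}\n")
        for chrom_id, profile in profiles.items():
            _write_bedgraph(
                out_dir / f"coverage_{chrom_id}.tsv", chrom_id, profile.coverage
            )
            _write_bedgraph(
                out_dir / f"spanning_{chrom_id}.tsv", chrom_id, profile.spanning_pairs
            )
        with open(out_dir / "taper_verdicts.tsv", "w") as fh:
            fh.write("chromosome\tleft_end\tright_end\n")
            for chrom_id, v in verdicts.items():
                fh.write(f"{chrom_id}\t{v['left']}\t{v['right']}\n")
    return result


def _write_bedgraph(path: Path, chrom_id: str, values: np.ndarray) -> None:
    """Run-length-encoded BedGraph-style TSV (0-based half-open intervals)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tvalue\n")
        if len(values) == 0:
            return
        change = np.nonzero(np.diff(values))[0]
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [len(values)]))
        for s, e in zip(starts, ends):
            fh.write(f"{chrom_id}\t{s}\t{e}\t{values[s]}\n")


@dataclass
class CrossSpeciesResult:
    summary: dict
    columns: list
    skipped_genes: list[str] = field(default_factory=list)
    out_dir: Path | None = None


def run_cross_species(
    cds_fastas: Mapping[str, str | Path],
    editing_tsv: str | Path,
    out_dir: str | Path | None = None,
) -> CrossSpeciesResult:
    """Cross-species editing conservation over genes shared by all species.

    ``cds_fastas`` maps species to a FASTA of spliced CDSs (one record per
    gene, record id = gene name).  ``editing_tsv`` has columns
    species/gene/cds_pos[/ref/alt].  Genes missing in any species are
    skipped and logged.
    """
    from Bio import SeqIO

    species_cds: dict[str, dict[str, SplicedCDS]] = {}
    for species, path in cds_fastas.items():
        per_gene = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            per_gene[rec.id] = SplicedCDS(
                gene_name=rec.id,
                sequence=seq,
                coord_map=[(rec.id, i + 1, "+") for i in range(len(seq))],
            )
        species_cds[species] = per_gene
    editing = pd.read_csv(editing_tsv, sep="\t")
    positions: dict[str, dict[str, set[int]]] = {}
    for _, row in editing.iterrows():
        positions.setdefault(str(row["gene"]), {}).setdefault(
            str(row["species"]), set()
        ).add(int(row["cds_pos"]))

    all_species = list(species_cds)
    shared = sorted(
        set.intersection(*(set(per.keys()) for per in species_cds.values()))
    )
    skipped = sorted(
        set.union(*(set(per.keys()) for per in species_cds.values())) - set(shared)
    )
    for gene in skipped:
        logger.info("cross-species: gene %s missing in some species; skipped", gene)

    columns = []
    for gene in shared:
        hs = HomologSet(
            gene_name=gene,
            cds={sp: species_cds[sp][gene] for sp in all_species},
            editing_positions={
                sp: positions.get(gene, {}).get(sp, set()) for sp in all_species
            },
        )
        columns.extend(classify_alignment(hs))
    summary = conservation_summary(columns)
    result = CrossSpeciesResult(summary=summary, columns=columns, skipped_genes=skipped)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.out_dir = out_dir
        with open(out_dir / "conservation_columns.tsv", "w") as fh:
            fh.write("gene\tcolumn\tclass\tedited_species\t" + "\t".join(all_species) + "\n")
            for col in columns:
                fh.write(
                    f"{col.gene_name}\t{col.column}\t{col.category}\t"
                    f"{','.join(sorted(col.edited_species))}\t"
                    + "\t".join(col.residues[sp] for sp in all_species)
                    + "\n"
                )
        with open(out_dir / "conservation_summary.tsv", "w") as fh:
            fh.write("class\tcount\tfraction\n")
            for cls, count in summary["counts"].items():
                fh.write(f"{cls}\t{count}\t{summary['fractions'][cls]:.4f}\n")
            fh.write(f"#total_edited_positions\t{summary['total_edited_positions']}\t\n")
    return result
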