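"""Call C-to-U editing sites on a simulated mitogenome and check them
against the planted truth.

Generates a two-chromosome mitogenome (one linear, one circular) with ten
protein genes — one trans-spliced across both chromosomes — plants editing
sites, simulates RNA-seq alignments for five samples, and runs the full
calling pipeline: filter (>=80% aligned, >=90% identity), pileup, the
20x / 10% calling rule, multi-sample merge, effect annotation and dEN/dES.
"""

import tempfile
from pathlib import Path

from mitoedit import CallerConfig, SimulationConfig, run_editing_analysis, simulate_all

with tempfile.TemporaryDirectory() as tmp:
    sim = simulate_all(SimulationConfig(seed=42), Path(tmp))
    result = run_editing_analysis(
        sim.genome_fasta, sim.annotation_gff3, sim.rnaseq_sams, CallerConfig()
    )

    truth = {(s.gene_name, s.cds_position, s.alt_base) for s in sim.truth_sites}
    called = {s.key for s in result.sites}

    print(f"planted sites:   {len(truth)}")
    print(f"called sites:    {len(called)}")
    print(f"recovered:       {len(truth & called)} (sensitivity "
          f"{100 * len(truth & called) / len(truth):.1f}%)")
    print(f"false calls:     {len(called - truth)}")
    print(f"median dEN/dES:  {result.median_dendes:.3f}")
    print()
    print("per-gene summary (sites per 100 bp of spliced CDS):")
    print(result.gene_summaries.to_string(index=False))

# The sensitivity line says how many planted events passed the coverage and
# fraction thresholds; with 100x depth and fractions >= 0.2 essentially all
# do, with no false positives at 0.1% base error.  The median dEN/dES near 1
# reflects planting that ignores protein consequences; real organellar data
# typically sits slightly above 1.
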