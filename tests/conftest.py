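"""Shared fixtures: small helpers and one session-wide default simulation."""

from __future__ import annotations

import pytest

from mitoedit.calling import CallerConfig
from mitoedit.genome import SplicedCDS
from mitoedit.pipeline import run_editing_analysis
from mitoedit.simulate import SimulationConfig, simulate_all


def plain_cds(name: str, seq: str) -> SplicedCDS:
    """A CDS 'mapped to itself': trivial plus-strand coordinate map."""
    return SplicedCDS(name, seq, [(name, i + 1, "+") for i in range(len(seq))])


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The default study-scale simulation: ~50 kb two-chromosome genome,
    10 genes with a cross-chromosome trans-spliced one, 100x RNA-seq at
    0.1% base error, planted fractions >= 0.2, five samples."""
    out = tmp_path_factory.mktemp("default_sim")
    return simulate_all(SimulationConfig(seed=11), out)


@pytest.fixture(scope="session")
def default_analysis(default_sim, tmp_path_factory):
    """Full editing analysis of the default simulation, shared across tests."""
    out = tmp_path_factory.mktemp("default_analysis")
    return run_editing_analysis(
        default_sim.genome_fasta,
        default_sim.annotation_gff3,
        default_sim.rnaseq_sams,
        CallerConfig(),
        out_dir=out,
    )
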