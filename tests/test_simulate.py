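"""The synthetic-data generator: determinism, truth validity, sampling stats."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from mitoedit.calling import CallerConfig, call_editing_sites, filter_alignments, pileup, read_sam
from mitoedit.genome import validate_annotation
from mitoedit.simulate import (
    EditingConfig,
    GeneConfig,
    LinearEndConfig,
    MatePairConfig,
    RnaSeqConfig,
    SimulationConfig,
    generate_genome,
    plant_editing,
    simulate_all,
    simulate_matepairs,
    simulate_rnaseq,
)
from mitoedit.structure import position_profiles

SMALL = SimulationConfig(
    seed=5,
    chromosomes=((12_000, "linear"), (8_000, "circular")),
    genes=GeneConfig(n_genes=3),
    rnaseq=RnaSeqConfig(mean_depth=30, samples=("s1", "s2")),
    matepair=MatePairConfig(n_pairs=1500, insert_mean=2000, insert_sd=400),
    linear_end=LinearEndConfig(max_truncation=1500),
)


def _hash_dir(path: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.iterdir())
        if p.is_file()
    }


class TestGenerateGenome:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        out1 = simulate_all(SMALL, tmp_path / "a")
        out2 = simulate_all(SMALL, tmp_path / "b")
        assert _hash_dir(out1.genome_fasta.parent) == _hash_dir(out2.genome_fasta.parent)

    def test_different_seed_changes_outputs(self, tmp_path):
        import dataclasses

        out1 = simulate_all(SMALL, tmp_path / "a")
        out2 = simulate_all(dataclasses.replace(SMALL, seed=6), tmp_path / "b")
        assert (
            _hash_dir(out1.genome_fasta.parent) != _hash_dir(out2.genome_fasta.parent)
        )

    def test_trans_splice_fraction_zero_all_single_chromosome(self):
        cfg = SimulationConfig(
            seed=2, genes=GeneConfig(n_genes=6, trans_splice_fraction=0.0)
        )
        sim = generate_genome(cfg)
        assert all(not g.is_trans_spliced for g in sim.genes)

    def test_default_config_has_cross_chromosome_gene_and_validates(self):
        sim = generate_genome(SimulationConfig(seed=4))
        validate_annotation(sim.genes, sim.chromosomes)
        assert any(g.is_trans_spliced for g in sim.genes)
        assert [c.topology for c in sim.chromosomes] == ["linear", "circular"]
        # every CDS is a full reading frame starting at a (possibly ACG) start
        for g in sim.genes:
            cds = sim.cds[g.name]
            assert len(cds) % 3 == 0
            assert cds.sequence[:3] in ("ATG", "ACG")

    def test_acg_start_gene_written_as_acg(self):
        sim = generate_genome(SimulationConfig(seed=4))
        acg = [g for g in sim.genes if g.annotated_start_is_ACG]
        assert len(acg) == 1
        assert sim.cds[acg[0].name].sequence[:3] == "ACG"

    def test_infeasible_packing_errors(self):
        cfg = SimulationConfig(
            seed=1,
            chromosomes=((3_000, "linear"),),
            genes=GeneConfig(n_genes=8, trans_splice_fraction=0.0),
        )
        with pytest.raises(ValueError, match="packing"):
            generate_genome(cfg)


class TestPlantEditing:
    def test_sites_on_matching_reference_bases(self):
        cfg = SimulationConfig(seed=9)
        sim = generate_genome(cfg)
        sites = plant_editing(sim, cfg, np.random.default_rng(10))
        assert sites, "default config should plant sites"
        for s in sites:
            assert sim.cds[s.gene_name].sequence[s.cds_position - 1] == s.ref_base
            assert s.samples

    def test_pure_c_to_u_weighting(self):
        cfg = SimulationConfig(
            seed=9, editing=EditingConfig(c_to_u_weight=1.0, a_to_g_weight=0.0)
        )
        sim = generate_genome(cfg)
        sites = plant_editing(sim, cfg, np.random.default_rng(10))
        assert all(s.edit_type == "C_to_U" and s.ref_base == "C" for s in sites)

    def test_rate_zero_empty_truth(self):
        cfg = SimulationConfig(
            seed=9,
            genes=GeneConfig(acg_start_gene=False),
            editing=EditingConfig(site_rate=0.0, a_to_g_weight=0.0),
        )
        sim = generate_genome(cfg)
        assert plant_editing(sim, cfg, np.random.default_rng(10)) == []

    def test_point_mass_fraction(self):
        cfg = SimulationConfig(
            seed=9,
            genes=GeneConfig(acg_start_gene=False),
            editing=EditingConfig(fraction_range=(0.5, 0.5)),
        )
        sim = generate_genome(cfg)
        sites = plant_editing(sim, cfg, np.random.default_rng(10))
        assert sites and all(s.fraction == pytest.approx(0.5) for s in sites)


class TestSimulateRnaseq:
    def _call_one_gene(self, sim, sites, cfg, tmp_path, gene_name):
        paths = simulate_rnaseq(sim, sites, cfg, np.random.default_rng(3), tmp_path)
        sample = cfg.rnaseq.samples[0]
        records = [
            r
            for r in filter_alignments(read_sam(paths[sample], sample), CallerConfig())
            if r.reference_id == gene_name
        ]
        counts = pileup(records, sim.cds[gene_name], sample)
        return counts, call_editing_sites(counts, sim.cds[gene_name], CallerConfig())

    def test_error_free_fraction_one_all_reads_alt(self, tmp_path):
        cfg = SimulationConfig(
            seed=21,
            chromosomes=((8_000, "linear"),),
            genes=GeneConfig(n_genes=1, trans_splice_fraction=0, acg_start_gene=False),
            editing=EditingConfig(fraction_range=(1.0, 1.0), site_rate=0.02,
                                  a_to_g_weight=0.0),
            rnaseq=RnaSeqConfig(mean_depth=40, base_error=0.0, samples=("s1",),
                                junk_read_fraction=0.0),
        )
        sim = generate_genome(cfg)
        sites = plant_editing(sim, cfg, np.random.default_rng(2))
        assert sites
        gene = sim.genes[0].name
        counts, called = self._call_one_gene(sim, sites, cfg, tmp_path, gene)
        by_pos = {c.position: c for c in counts}
        for s in sites:
            tally = by_pos[s.cds_position]
            assert tally.counts.get(s.alt_base, 0) == tally.depth  # every read edited
        assert {c.cds_position for c in called} == {s.cds_position for s in sites}

    def test_error_free_no_sites_pileup_equals_reference(self, tmp_path):
        cfg = SimulationConfig(
            seed=22,
            chromosomes=((8_000, "linear"),),
            genes=GeneConfig(n_genes=1, trans_splice_fraction=0, acg_start_gene=False),
            editing=EditingConfig(site_rate=0.0, a_to_g_weight=0.0),
            rnaseq=RnaSeqConfig(mean_depth=30, base_error=0.0, samples=("s1",),
                                junk_read_fraction=0.0),
        )
        sim = generate_genome(cfg)
        gene = sim.genes[0].name
        counts, called = self._call_one_gene(sim, [], cfg, tmp_path, gene)
        seq = sim.cds[gene].sequence
        for c in counts:
            assert c.counts == {seq[c.position - 1]: c.depth}
        assert called == []

    def test_observed_fraction_within_binomial_interval(self, tmp_path):
        """A planted 0.5-fraction site at ~100x shows an observed alt fraction
        inside the 99% binomial interval around 0.5."""
        from scipy import stats

        cfg = SimulationConfig(
            seed=23,
            chromosomes=((8_000, "linear"),),
            genes=GeneConfig(n_genes=1, trans_splice_fraction=0, acg_start_gene=False),
            editing=EditingConfig(fraction_range=(0.5, 0.5), site_rate=0.01,
                                  a_to_g_weight=0.0),
            rnaseq=RnaSeqConfig(mean_depth=100, base_error=0.0, samples=("s1",),
                                junk_read_fraction=0.0),
        )
        sim = generate_genome(cfg)
        sites = plant_editing(sim, cfg, np.random.default_rng(2))
        gene = sim.genes[0].name
        counts, _ = self._call_one_gene(sim, sites, cfg, tmp_path, gene)
        by_pos = {c.position: c for c in counts}
        for s in sites:
            tally = by_pos[s.cds_position]
            k = tally.counts.get(s.alt_base, 0)
            lo, hi = stats.binom.interval(0.99, tally.depth, 0.5)
            assert lo <= k <= hi

    def test_junk_reads_fail_the_mapping_filter(self, tmp_path):
        cfg = SimulationConfig(
            seed=24,
            chromosomes=((8_000, "linear"),),
            genes=GeneConfig(n_genes=1, trans_splice_fraction=0, acg_start_gene=False),
            editing=EditingConfig(site_rate=0.0),
            rnaseq=RnaSeqConfig(mean_depth=10, samples=("s1",), junk_read_fraction=0.1),
        )
        sim = generate_genome(cfg)
        paths = simulate_rnaseq(sim, [], cfg, np.random.default_rng(3), tmp_path)
        records = list(read_sam(paths["s1"], "s1"))
        junk = [r for r in records if "junk" in r.read_id]
        assert junk
        kept = list(filter_alignments(junk, CallerConfig()))
        assert kept == []


class TestSimulateMatepairs:
    def test_empirical_insert_mean_within_3se(self):
        """Sampled insert sizes reproduce the configured 8,279 +/- 2,583 bp
        library within three standard errors."""
        cfg = SimulationConfig(
            seed=31,
            chromosomes=((120_000, "linear"),),
            genes=GeneConfig(n_genes=2),
            matepair=MatePairConfig(n_pairs=4000),
            linear_end=LinearEndConfig(max_truncation=0),
        )
        sim = generate_genome(cfg)
        pairs, truth = simulate_matepairs(sim, cfg, np.random.default_rng(1))
        inserts = np.array([t.insert for t in truth])
        se = cfg.matepair.insert_sd / np.sqrt(len(inserts))
        assert abs(inserts.mean() - cfg.matepair.insert_mean) < 3 * se

    def test_no_truncation_uniform_coverage_no_taper(self):
        cfg = SimulationConfig(
            seed=32,
            chromosomes=((60_000, "linear"),),
            genes=GeneConfig(n_genes=2),
            matepair=MatePairConfig(n_pairs=20_000),
            linear_end=LinearEndConfig(max_truncation=0),
        )
        sim = generate_genome(cfg)
        pairs, _ = simulate_matepairs(sim, cfg, np.random.default_rng(1))
        reads = [r for p in pairs for r in (p.read1, p.read2)]
        profile = position_profiles(sim.chromosomes[0], reads=reads, pairs=pairs)
        from mitoedit.structure import detect_terminal_taper

        verdicts = detect_terminal_taper(profile, window=16_000)
        # fragments start uniformly over the full molecule, so only the
        # outermost read-length shows edge loss: not a taper
        assert "taper" not in verdicts.values()

    def test_circular_wrap_coverage_flat_through_origin(self):
        cfg = SimulationConfig(
            seed=33,
            chromosomes=((60_000, "circular"),),
            genes=GeneConfig(n_genes=2),
            matepair=MatePairConfig(n_pairs=20_000),
        )
        sim = generate_genome(cfg)
        pairs, _ = simulate_matepairs(sim, cfg, np.random.default_rng(1))
        reads = [r for p in pairs for r in (p.read1, p.read2)]
        profile = position_profiles(sim.chromosomes[0], reads=reads, pairs=pairs)
        cov = profile.coverage
        interior = np.median(cov)
        # wrap sampling keeps the origin indistinguishable from the interior
        assert cov[:200].mean() > 0.7 * interior
        assert cov[-200:].mean() > 0.7 * interior

    def test_sam_roundtrip_preserves_pairs(self, tmp_path):
        from mitoedit.structure import read_matepairs_sam

        cfg = SimulationConfig(
            seed=34,
            chromosomes=((30_000, "linear"),),
            genes=GeneConfig(n_genes=2),
            matepair=MatePairConfig(n_pairs=300),
            linear_end=LinearEndConfig(max_truncation=0),
        )
        sim = generate_genome(cfg)
        sam = tmp_path / "mp.sam"
        pairs, _ = simulate_matepairs(sim, cfg, np.random.default_rng(1), sam_path=sam)
        loaded = read_matepairs_sam(sam)
        assert len(loaded) == len(pairs)
        got = {(p.read1.start, p.read2.start) for p in loaded}
        want = {(p.read1.start, p.read2.start) for p in pairs}
        assert got == want
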