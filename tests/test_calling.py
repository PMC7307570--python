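"""Alignment filtering, pileup, editing-site calling and sample merging."""

import itertools

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoedit.calling import (
    AlignmentRecord,
    CallerConfig,
    EditingSite,
    SiteCounts,
    call_editing_sites,
    classify_edit_type,
    expression_level,
    filter_alignments,
    merge_samples,
    pileup,
    read_sam,
)
from mitoedit.genome import Exon, GeneModel

from conftest import plain_cds


def rec(frac, ident, calls=(), ref="g", start=1, name="r", sample="s1"):
    return AlignmentRecord(
        read_id=name,
        reference_id=ref,
        reference_start=start,
        aligned_read_fraction=frac,
        identity=ident,
        base_calls=list(calls),
        sample_id=sample,
    )


class TestFilter:
    @pytest.mark.parametrize(
        "frac, ident, kept",
        [
            (0.85, 0.92, True),
            (0.70, 0.99, False),
            (0.80, 0.90, True),  # exact thresholds pass: "at least" semantics
            (0.79, 1.00, False),
            (1.00, 0.899, False),
        ],
    )
    def test_threshold_semantics(self, frac, ident, kept):
        out = list(filter_alignments([rec(frac, ident)], CallerConfig()))
        assert (len(out) == 1) == kept

    def test_order_preserved(self):
        records = [rec(0.9, 0.95, name=f"r{i}") for i in range(5)]
        out = list(filter_alignments(records, CallerConfig()))
        assert [r.read_id for r in out] == [f"r{i}" for i in range(5)]

    def test_out_of_range_values_error(self):
        with pytest.raises(ValueError):
            list(filter_alignments([rec(1.2, 0.9)], CallerConfig()))


class TestPileup:
    def test_base_tally(self):
        cds = plain_cds("g", "AAAAAAACAA")
        records = [
            rec(1, 1, calls=[(7, "C")]),
            rec(1, 1, calls=[(7, "C")]),
            rec(1, 1, calls=[(7, "T")]),
        ]
        (sc,) = pileup(records, cds)
        assert sc.position == 7
        assert sc.counts == {"C": 2, "T": 1}
        assert sc.depth == 3

    def test_uncovered_positions_absent(self):
        cds = plain_cds("g", "ACGTACGT")
        out = pileup([rec(1, 1, calls=[(2, "C"), (3, "G")])], cds)
        assert [sc.position for sc in out] == [2, 3]

    def test_deletion_contributes_to_neighbors_only(self):
        cds = plain_cds("g", "ACGTACGT")
        # read aligned over 4..6 with position 5 deleted
        out = pileup([rec(1, 1, calls=[(4, "T"), (6, "C")])], cds)
        assert [sc.position for sc in out] == [4, 6]

    def test_n_calls_ignored_with_warning(self):
        cds = plain_cds("g", "ACGT")
        with pytest.warns(UserWarning, match="non-ACGT"):
            out = pileup([rec(1, 1, calls=[(1, "N"), (2, "C")])], cds)
        assert [sc.position for sc in out] == [2]

    def test_depth_conservation(self):
        """Sum of pileup depths equals the number of aligned base calls."""
        rng = np.random.default_rng(7)
        cds = plain_cds("g", "".join(np.random.default_rng(1).choice(list("ACGT"), 50)))
        records = []
        for i in range(30):
            start = int(rng.integers(1, 40))
            calls = [(start + k, "ACGT"[rng.integers(0, 4)]) for k in range(10)]
            records.append(rec(1, 1, calls=calls, name=f"r{i}"))
        out = pileup(records, cds)
        assert sum(sc.depth for sc in out) == 300


def site_counts(pos, counts):
    return SiteCounts(reference_id="g", position=pos, counts=counts, sample_id="s1")


class TestCalling:
    def test_boundary_rule(self):
        """Inclusive 20x / 10% thresholds: (20, 0.10) and (200, 0.10) are called,
        (19, 1.0) fails coverage and (200, 0.095) fails the fraction."""
        cds = plain_cds("g", "CCCC")
        counts = [
            site_counts(1, {"C": 18, "T": 2}),
            site_counts(2, {"T": 19}),
            site_counts(3, {"C": 181, "T": 19}),
            site_counts(4, {"C": 180, "T": 20}),
        ]
        sites = call_editing_sites(counts, cds, CallerConfig())
        assert [s.cds_position for s in sites] == [1, 4]
        assert sites[0].per_sample["s1"] == (20, pytest.approx(0.10))

    def test_a_to_g_call(self):
        cds = plain_cds("g", "A")
        (site,) = call_editing_sites([site_counts(1, {"A": 80, "G": 20})], cds)
        assert site.edit_type == "A_to_G"
        assert site.per_sample["s1"] == (100, pytest.approx(0.20))

    def test_alt_is_modal_nonref_with_fixed_tiebreak(self):
        cds = plain_cds("g", "C")
        (site,) = call_editing_sites([site_counts(1, {"C": 10, "T": 6, "G": 4})], cds)
        assert site.alt_base == "T"
        (site,) = call_editing_sites([site_counts(1, {"C": 10, "A": 5, "G": 5})], cds)
        assert site.alt_base == "A"  # tie broken in base order A<C<G<T

    def test_nonref_fraction_is_total_not_modal(self):
        # 8% T + 4% G: no single alt reaches 10% but together they do
        cds = plain_cds("g", "C")
        (site,) = call_editing_sites([site_counts(1, {"C": 88, "T": 8, "G": 4})], cds)
        assert site.alt_base == "T"

    def test_n_reference_base_skipped(self):
        cds = plain_cds("g", "N")
        with pytest.warns(UserWarning, match="skipped"):
            assert call_editing_sites([site_counts(1, {"T": 30})], cds) == []

    @given(extra_alt=st.booleans())
    @settings(deadline=None, max_examples=20)
    def test_single_read_flips_boundary_call(self, extra_alt):
        """At depth 20 / fraction 0.10 the call is exactly threshold-determined:
        converting one alt read to reference (or dropping one read) flips it."""
        cds = plain_cds("g", "C")
        at_boundary = site_counts(1, {"C": 18, "T": 2})
        assert len(call_editing_sites([at_boundary], cds)) == 1
        if extra_alt:
            perturbed = site_counts(1, {"C": 19, "T": 1})  # one alt read now ref
        else:
            perturbed = site_counts(1, {"C": 17, "T": 2})  # one read lost: depth 19
        assert call_editing_sites([perturbed], cds) == []


class TestClassifyEditType:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [("C", "T", "C_to_U"), ("A", "G", "A_to_G"), ("G", "A", "other_G_A"),
         ("T", "C", "other_T_C")],
    )
    def test_enumeration(self, ref, alt, expected):
        assert classify_edit_type(ref, alt) == expected

    def test_equal_bases_error(self):
        with pytest.raises(ValueError):
            classify_edit_type("C", "C")


def make_site(gene, pos, sample, ref="C", alt="T"):
    return EditingSite(
        gene_name=gene,
        cds_position=pos,
        chromosome_id="chr1",
        genomic_position=pos,
        strand="+",
        ref_base=ref,
        alt_base=alt,
        edit_type=classify_edit_type(ref, alt),
        per_sample={sample: (50, 0.5)},
    )


class TestMergeSamples:
    def test_site_in_all_samples(self):
        per_sample = {s: [make_site("g", 10, s)] for s in ("s1", "s2", "s3")}
        merged, occurrence = merge_samples(per_sample)
        assert len(merged) == 1
        assert occurrence == {frozenset({"s1", "s2", "s3"}): 1}

    def test_disjoint_sites_diagonal_cells(self):
        per_sample = {f"s{i}": [make_site("g", i, f"s{i}")] for i in range(1, 4)}
        _, occurrence = merge_samples(per_sample)
        assert occurrence == {frozenset({f"s{i}"}): 1 for i in range(1, 4)}

    def test_venn_counts_match_bruteforce(self):
        """Occurrence cells equal brute-force set intersections for 5 samples."""
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(5)]
        truth = {}  # position -> set of samples
        for pos in range(1, 120):
            present = {s for s in samples if rng.random() < 0.4}
            if present:
                truth[pos] = present
        per_sample = {
            s: [make_site("g", pos, s) for pos, present in truth.items() if s in present]
            for s in samples
        }
        _, occurrence = merge_samples(per_sample)
        # brute force: enumerate every subset, count exact membership
        expected = {}
        for k in range(1, 6):
            for combo in itertools.combinations(samples, k):
                n = sum(1 for present in truth.values() if present == set(combo))
                if n:
                    expected[frozenset(combo)] = n
        assert occurrence == expected
        assert sum(occurrence.values()) == len(truth)

    def test_conflicting_reference_base_errors(self):
        per_sample = {
            "s1": [make_site("g", 5, "s1", ref="C", alt="T")],
            "s2": [make_site("g", 5, "s2", ref="A", alt="T")],
        }
        with pytest.raises(ValueError, match="conflicting reference"):
            merge_samples(per_sample)

    def test_different_alt_is_different_site(self):
        per_sample = {
            "s1": [make_site("g", 5, "s1", ref="C", alt="T")],
            "s2": [make_site("g", 5, "s2", ref="C", alt="G")],
        }
        merged, _ = merge_samples(per_sample)
        assert len(merged) == 2


class TestExpressionLevel:
    @pytest.mark.parametrize(
        "pairs, length, expected", [(200, 2000, 0.1), (0, 2000, 0.0), (4500, 1500, 3.0)]
    )
    def test_pairs_per_bp(self, pairs, length, expected):
        gene = GeneModel("g", exons=[Exon("c", 1, length, "+", 1)])
        assert expression_level(gene, pairs) == pytest.approx(expected)


class TestReadSam:
    def test_fraction_identity_from_cigar_and_nm(self, tmp_path):
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "g", "LN": 100}]}
        path = tmp_path / "t.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            a = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
            a.query_name = "r1"
            a.query_sequence = "A" * 20
            a.reference_id = 0
            a.reference_start = 9
            a.cigarstring = "5S15M"  # 75% aligned
            a.set_tag("NM", 3)  # identity 12/15 = 0.8
            sam.write(a)
        (record,) = list(read_sam(path, "s1"))
        assert record.aligned_read_fraction == pytest.approx(0.75)
        assert record.identity == pytest.approx(12 / 15)
        assert record.reference_start == 10
        assert len(record.base_calls) == 15
        assert list(filter_alignments([record], CallerConfig())) == []
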