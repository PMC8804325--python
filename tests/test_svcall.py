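"""Split-read clustering, the support filter, annotation and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgtsr import (
    GeneModel, SVDatabaseRecord, TranslocationSpec,
    annotate_breakpoint, call_translocations, cluster_chimeric_reads,
    db_overlap, make_derivatives, plant_junction_reads, reciprocal_overlap,
    segment_metrics,
)
from pgtsr.observe import AlignedSegment, SplitRead
from pgtsr.svcall import GeneInterval


def chimeric_read(read_id, chrom1, pos1, chrom2, pos2, span=5000):
    """A synthetic +/+ split read: [pos1-span..pos1] then [pos2..pos2+span]."""
    return SplitRead(
        read_id,
        [
            AlignedSegment(chrom1, pos1 - span + 1, pos1, "+", 1, span),
            AlignedSegment(chrom2, pos2, pos2 + span - 1, "+", span + 1, 2 * span),
        ],
        2 * span,
    )


class TestClustering:
    def test_empty_input_gives_empty_output(self):
        assert cluster_chimeric_reads([]) == []

    def test_single_segment_reads_are_ignored(self):
        read = SplitRead("r", [AlignedSegment("chr1", 100, 200, "+", 1, 101)], 101)
        assert cluster_chimeric_reads([read]) == []

    def test_jittered_reads_form_one_cluster_with_full_support(self, genome, derivatives):
        der_a, _ = derivatives
        reads = plant_junction_reads(der_a, 22, jitter=200, seed=3)
        clusters = cluster_chimeric_reads(reads, merge_window=1000)
        assert len(clusters) == 1
        (c,) = clusters
        assert c.support == 22
        assert abs(c.posA - 3_500_000) <= 500
        assert abs(c.posB - 4_200_001) <= 500

    def test_junctions_ten_kb_apart_stay_separate(self):
        reads = [chimeric_read(f"a{i}", "chr1", 100_000, "chr2", 500_000) for i in range(3)]
        reads += [chimeric_read(f"b{i}", "chr1", 110_000, "chr2", 510_000) for i in range(3)]
        clusters = cluster_chimeric_reads(reads, merge_window=1000)
        assert len(clusters) == 2

    def test_cluster_position_is_lower_median(self):
        positions = [100_000, 100_010, 100_400, 100_500]
        reads = [
            chimeric_read(f"r{i}", "chr1", p, "chr2", 500_000) for i, p in enumerate(positions)
        ]
        (c,) = cluster_chimeric_reads(reads, merge_window=1000)
        assert c.posA == 100_010  # lower median of an even-sized cluster

    def test_reciprocal_junctions_do_not_merge(self, genome, spec, derivatives):
        # der(A) and der(B) junctions sit ~1 bp apart in coordinates but have
        # distinct orientation classes
        der_a, der_b = derivatives
        reads = plant_junction_reads(der_a, 5, seed=1) + plant_junction_reads(
            der_b, 5, seed=2, id_prefix="b"
        )
        clusters = cluster_chimeric_reads(reads, merge_window=1000)
        assert len(clusters) == 2


class TestSupportFilter:
    def make_cluster_calls(self, n_reads):
        reads = [
            chimeric_read(f"r{i}", "chr1", 100_000, "chr2", 500_000) for i in range(n_reads)
        ]
        return call_translocations(cluster_chimeric_reads(reads))

    def test_support_two_passes(self):
        (call,) = self.make_cluster_calls(2)
        assert call.filter == "pass"

    def test_support_one_is_low_support(self):
        (call,) = self.make_cluster_calls(1)
        assert call.filter == "low_support"
        assert not call.passed

    def test_seventeen_reads_pass_with_support_seventeen(self):
        (call,) = self.make_cluster_calls(17)
        assert call.passed and call.support == 17

    def test_min_support_below_one_rejected(self):
        with pytest.raises(ValueError):
            call_translocations([], min_support=0)


class TestAnnotation:
    @pytest.fixture()
    def genes(self):
        return GeneModel(
            [
                GeneInterval("chr1", 244_500_000, 244_600_000, "+", "ADSS"),
                GeneInterval("chr2", 182_000_000, 182_200_000, "+", "LINC01934"),
                GeneInterval("chr2", 182_400_000, 182_600_000, "-", "ITGA4"),
            ]
        )

    def test_position_inside_gene_is_disrupted(self, genes):
        assert genes.annotate("chr1", 244_573_198) == "disrupted:ADSS"

    def test_position_between_genes_is_intergenic(self, genes):
        assert genes.annotate("chr2", 182_319_607) == "intergenic:LINC01934|ITGA4"

    def test_position_left_of_first_gene_has_no_left_neighbor(self, genes):
        assert genes.annotate("chr2", 100) == "intergenic:none|LINC01934"

    def test_unknown_chromosome_rejected(self, genes):
        with pytest.raises(KeyError):
            genes.annotate("chr9", 1)


class TestSegmentMetrics:
    @pytest.mark.parametrize(
        "chrom,pos,arm,mb,pct",
        [
            ("chr1", 244_573_198, "q", 4.68, 1.88),
            ("chr2", 182_319_607, "q", 60.88, 25.03),
            ("chr12", 5_959_384, "p", 5.96, 4.45),
            ("chr14", 66_307_382, "q", 41.04, 38.23),
        ],
    )
    def test_case_series_metrics_reproduce_to_two_decimals(self, hg19, chrom, pos, arm, mb, pct):
        m = segment_metrics(chrom, pos, hg19, arm)
        assert m.length_mb == mb
        assert m.percent == pct

    def test_arm_resolved_from_cytobands_when_not_given(self, hg19):
        assert segment_metrics("chr12", 5_959_384, hg19).arm == "p"

    def test_breakpoint_at_chromosome_end_gives_zero_segment(self, hg19):
        m = segment_metrics("chr1", hg19.length("chr1"), hg19, arm="q")
        assert m.length_bp == 0 and m.length_mb == 0.0 and m.percent == 0.0

    def test_position_outside_chromosome_rejected(self, hg19):
        with pytest.raises(ValueError):
            segment_metrics("chr1", 260_000_000, hg19, arm="q")

    def test_rounding_is_half_up(self, hg19):
        # 0.005 Mb boundaries round up, not banker-style
        from pgtsr.svcall import _round2

        assert _round2(1.885) == 1.89
        assert _round2(1.884999) == 1.88


class TestDatabaseOverlap:
    def test_half_reciprocal_overlap_matches(self):
        db = [SVDatabaseRecord("DEL", "chr1", 150, 250, "dbA")]
        assert db_overlap("DEL", "chr1", 100, 200, db) == ["dbA"]

    def test_reciprocal_overlap_value_by_brute_force(self):
        # 1-based inclusive: shared bases of [100,200] and [150,250]
        shared = len(set(range(100, 201)) & set(range(150, 251)))
        assert shared == 51
        assert reciprocal_overlap(100, 200, 150, 250) == pytest.approx(51 / 101)

    def test_ins_distance_boundary_flips_at_1000(self):
        db = [SVDatabaseRecord("INS", "chr1", 6_001, 6_001, "dbB")]
        assert db_overlap("INS", "chr1", 5_001, 5_001, db) == ["dbB"]  # distance 1000
        assert db_overlap("INS", "chr1", 5_000, 5_000, db) == []  # distance 1001

    def test_tra_matches_when_both_breakends_close(self):
        db = [SVDatabaseRecord("TRA", "chr1", 100_000, 100_000, "dbC", "chr2", 500_000)]
        assert db_overlap(
            "TRA", "chr1", 100_500, 100_500, db, chrom2="chr2", pos2=500_500
        ) == ["dbC"]
        assert db_overlap(
            "TRA", "chr1", 100_500, 100_500, db, chrom2="chr2", pos2=502_000
        ) == []

    def test_empty_database_gives_no_annotations(self):
        assert db_overlap("DEL", "chr1", 100, 200, []) == []

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        s1=st.integers(1, 10_000), l1=st.integers(1, 5_000),
        s2=st.integers(1, 10_000), l2=st.integers(1, 5_000),
    )
    def test_reciprocal_overlap_is_symmetric(self, s1, l1, s2, l2):
        a = reciprocal_overlap(s1, s1 + l1, s2, s2 + l2)
        b = reciprocal_overlap(s2, s2 + l2, s1, s1 + l1)
        assert a == b


class TestPlantedRecovery:
    def test_every_planted_junction_recovered_within_window(self, genome):
        # parameter-recovery across seeds and breakpoints
        rng = np.random.default_rng(99)
        for trial in range(8):
            pos_a = int(rng.integers(2_200_000, 4_800_000))
            pos_b = int(rng.integers(2_800_000, 6_000_000))
            spec = TranslocationSpec("chr1", pos_a, "chr2", pos_b)
            der_a, der_b = make_derivatives(genome, spec)
            reads = []
            for j, der in enumerate((der_a, der_b)):
                reads += plant_junction_reads(der, 6, jitter=150, seed=trial * 2 + j,
                                              id_prefix=f"d{j}_")
            calls = call_translocations(cluster_chimeric_reads(reads))
            passed = [c for c in calls if c.passed]
            assert len(passed) == 2
            for c in passed:
                assert min(abs(c.posA - pos_a), abs(c.posA - (pos_a + 1))) <= 500

    def test_noncarrier_reads_produce_no_pass_calls(self, genome):
        from pgtsr.observe import emit_longreads, molecules_for_individual

        mols = molecules_for_individual(genome, None, carrier=False)
        reads = emit_longreads(genome, mols, 3_000, mean_len=10_000, seed=5)
        calls = call_translocations(cluster_chimeric_reads(reads))
        assert [c for c in calls if c.passed] == []
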