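"""Type resolution, stage classification, single-counting and coverage filter."""

import numpy as np
import pytest

from inoseq.reads import (
    AMBIGUOUS,
    UNASSIGNED,
    CoverageFilter,
    GeneIndex,
    apply_coverage_filter,
    assign_reads,
    classify_stage,
    read_alignments,
    resolve_type,
    stage_proportions,
)
from inoseq.reference import FlankSpec, TrnaGene, parse_gene_table
from inoseq.simulate import load_truth

from conftest import write_sam


def _gene(gid, key, start, end, strand="+", chrom="chr1"):
    return TrnaGene(gid, key, chrom, strand, start, end, 33)


@pytest.fixture
def toy_index():
    genes = [
        _gene("val1", "Val-AAC", 200, 276),
        _gene("val2", "Val-AAC", 600, 676),
        _gene("ala1", "Ala-AGC", 1000, 1076),
    ]
    return genes, GeneIndex(genes, FlankSpec(50, 50))


def _toy_sam(tmp_path, records):
    return write_sam(tmp_path / "toy.sam", {"chr1": 2000}, records)


class TestResolveType:
    def _alns(self, tmp_path, records):
        sam = _toy_sam(tmp_path, records)
        return read_alignments(sam)

    def test_two_copies_of_same_type_resolve(self, tmp_path, toy_index):
        _, index = toy_index
        grouped = self._alns(
            tmp_path,
            [
                ("r1", 0, "chr1", 220, "40M", "A" * 40),
                ("r1", 256, "chr1", 620, "40M", "A" * 40),
            ],
        )
        status, _ = resolve_type(grouped["r1"], index)
        assert status == "Val-AAC"

    def test_two_types_is_ambiguous(self, tmp_path, toy_index):
        _, index = toy_index
        grouped = self._alns(
            tmp_path,
            [
                ("r1", 0, "chr1", 220, "40M", "A" * 40),
                ("r1", 256, "chr1", 1020, "40M", "A" * 40),
            ],
        )
        status, _ = resolve_type(grouped["r1"], index)
        assert status == AMBIGUOUS

    def test_no_gene_overlap_is_unassigned(self, tmp_path, toy_index):
        _, index = toy_index
        grouped = self._alns(tmp_path, [("r1", 0, "chr1", 1500, "40M", "A" * 40)])
        status, _ = resolve_type(grouped["r1"], index)
        assert status == UNASSIGNED

    def test_unknown_chrom_errors(self, tmp_path, toy_index):
        _, index = toy_index
        sam = write_sam(
            tmp_path / "bad.sam", {"chrZ": 2000}, [("r1", 0, "chrZ", 100, "40M", "A" * 40)]
        )
        grouped = read_alignments(sam)
        with pytest.raises(KeyError, match="chrZ"):
            resolve_type(grouped["r1"], index)


class TestClassifyStage:
    def test_leader_overlap_is_precursor(self):
        g = _gene("g", "Val-AAC", 100, 176)
        assert classify_stage((95, 130), g, FlankSpec()) == "precursor"

    def test_exact_mature_span_is_processed(self):
        g = _gene("g", "Val-AAC", 100, 176)
        assert classify_stage((100, 176), g, FlankSpec()) == "processed"

    def test_internal_fragment_is_processed(self):
        g = _gene("g", "Val-AAC", 100, 176)
        assert classify_stage((120, 150), g, FlankSpec()) == "processed"

    def test_flank_only_span_is_precursor(self):
        g = _gene("g", "Val-AAC", 100, 176)
        assert classify_stage((60, 90), g, FlankSpec()) == "precursor"

    def test_minus_strand_trailer_side(self):
        g = _gene("g", "Val-AAC", 100, 176, strand="-")
        # genomically left of mature_start = 3'-trailer for a minus gene
        assert classify_stage((90, 130), g, FlankSpec()) == "precursor"

    def test_disjoint_span_is_a_caller_bug(self):
        g = _gene("g", "Val-AAC", 100, 176)
        with pytest.raises(ValueError):
            classify_stage((500, 540), g, FlankSpec())

    def test_agrees_with_truth_for_every_synthetic_read(self, small_study):
        d = small_study["dir"]
        from pyfaidx import Fasta

        genes = parse_gene_table(d / "genes.tsv", Fasta(str(d / "genome.fa")))
        assigned, _ = assign_reads(d / "control.truth.sam", genes)
        truth = load_truth(d / "control.truth.tsv")
        truth_stage = dict(zip(truth["read_id"], truth["stage"]))
        truth_type = dict(zip(truth["read_id"], truth["type_key"]))
        assert assigned  # sanity
        for r in assigned:
            assert r.stage == truth_stage[r.read_id]
            assert r.type_key == truth_type[r.read_id]


class TestCountOnce:
    def test_within_type_multimapper_counted_once(self, tmp_path, toy_index):
        genes, _ = toy_index
        sam = _toy_sam(
            tmp_path,
            [
                ("r1", 0, "chr1", 220, "40M", "A" * 40),
                ("r1", 256, "chr1", 620, "40M", "A" * 40),
                ("r1", 256, "chr1", 230, "40M", "A" * 40),
            ],
        )
        assigned, acc = assign_reads(sam, genes)
        assert acc == {"total": 1, "counted": 1, "ambiguous": 0, "unassigned": 0}
        assert len(assigned) == 1
        assert assigned[0].gene_id == "val1"  # the primary record's copy

    def test_count_per_alignment_flag_restores_per_copy(self, tmp_path, toy_index):
        genes, _ = toy_index
        sam = _toy_sam(
            tmp_path,
            [
                ("r1", 0, "chr1", 220, "40M", "A" * 40),
                ("r1", 256, "chr1", 620, "40M", "A" * 40),
            ],
        )
        assigned, _ = assign_reads(sam, genes, count_per_alignment=True)
        assert len(assigned) == 2

    def test_two_reads_two_types(self, tmp_path, toy_index):
        genes, _ = toy_index
        sam = _toy_sam(
            tmp_path,
            [
                ("r1", 0, "chr1", 220, "40M", "A" * 40),
                ("r2", 0, "chr1", 1020, "40M", "A" * 40),
            ],
        )
        assigned, _ = assign_reads(sam, genes)
        assert {(r.read_id, r.type_key) for r in assigned} == {
            ("r1", "Val-AAC"),
            ("r2", "Ala-AGC"),
        }

    def test_partition_every_read_in_exactly_one_category(self, small_study):
        d = small_study["dir"]
        from pyfaidx import Fasta

        genes = parse_gene_table(d / "genes.tsv", Fasta(str(d / "genome.fa")))
        assigned, acc = assign_reads(d / "control.truth.sam", genes)
        assert acc["counted"] + acc["ambiguous"] + acc["unassigned"] == acc["total"]
        assert len(assigned) == acc["counted"]  # one (type, stage) per counted read
        assert len({r.read_id for r in assigned}) == acc["counted"]

    def test_truth_listed_ambiguous_reads_fully_excluded(self, small_study):
        """Zero-tolerance: exactly the reads whose truth lists two types drop out."""
        d = small_study["dir"]
        from pyfaidx import Fasta

        genes = parse_gene_table(d / "genes.tsv", Fasta(str(d / "genome.fa")))
        assigned, acc = assign_reads(d / "control.truth.sam", genes)
        truth = load_truth(d / "control.truth.tsv")
        amb_truth = set(truth.loc[truth["also_maps_to"] != "", "read_id"])
        assert amb_truth  # the fixture has an ambiguous pair
        counted_ids = {r.read_id for r in assigned}
        assert amb_truth.isdisjoint(counted_ids)
        assert acc["ambiguous"] == len(amb_truth)


class TestCoverageFilter:
    def test_threshold_is_strictly_below_ten(self):
        retained = apply_coverage_filter({"a": 9, "b": 10, "c": 11}, CoverageFilter(10))
        assert retained == {"b", "c"}

    def test_min_depth_one_keeps_any_covered_copy(self):
        assert apply_coverage_filter({"a": 1}, CoverageFilter(1)) == {"a"}

    def test_empty_input(self):
        assert apply_coverage_filter({}, CoverageFilter(10)) == set()

    def test_invalid_min_depth(self):
        with pytest.raises(ValueError):
            CoverageFilter(0)

    def test_matches_truth_anticodon_depth(self, tmp_path):
        """Retained set equals copies whose truth residue-34 depth >= min_depth."""
        from pyfaidx import Fasta

        from inoseq.pipeline import AnalysisParams, analyze
        from inoseq.pipeline import simulate_study
        from inoseq.simulate import SimConfig

        config = SimConfig(n_types=4, copies_per_type=2, depth_per_copy=12, error_rate=0.0)
        simulate_study(config, tmp_path, conditions=("control",), seed=21)
        res = analyze(
            tmp_path / "genes.tsv", tmp_path / "genome.fa", tmp_path / "control.truth.sam",
        )
        truth = load_truth(tmp_path / "control.truth.tsv")
        truth_depth = (
            truth[truth["covers_34"] == 1].groupby("gene_id").size().to_dict()
        )
        genes = parse_gene_table(tmp_path / "genes.tsv", Fasta(str(tmp_path / "genome.fa")))
        expect = {g.gene_id for g in genes if truth_depth.get(g.gene_id, 0) >= 10}
        assert res.retained_copies == expect


class TestStageProportions:
    def test_simple_fractions(self, small_study):
        d = small_study["dir"]
        from pyfaidx import Fasta

        genes = parse_gene_table(d / "genes.tsv", Fasta(str(d / "genome.fa")))
        assigned, _ = assign_reads(d / "control.truth.sam", genes)
        df = stage_proportions(assigned).set_index("type_key")
        truth = load_truth(d / "control.truth.tsv")
        unamb = truth[truth["also_maps_to"] == ""]
        for key, sub in unamb.groupby("type_key"):
            expect = (sub["stage"] == "precursor").mean()
            assert df.loc[key, "frac_precursor"] == pytest.approx(expect)
        row = df.loc["ALL"]
        assert row["frac_precursor"] + row["frac_processed"] == pytest.approx(1.0)

    def test_zero_total_reported_missing_not_zero(self):
        df = stage_proportions([])
        assert df.loc[df["type_key"] == "ALL", "frac_precursor"].isna().all()
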