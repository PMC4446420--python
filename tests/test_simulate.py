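"""Synthetic-data generator: determinism, conservation, truth and error models."""

import numpy as np
import pandas as pd
import pytest

from inoseq.pileup import build_pileup
from inoseq.reference import parse_gene_table, sense_sequence
from inoseq.simulate import (
    ANN_TYPES,
    SimConfig,
    build_genome,
    load_truth,
    simulate_reads,
    truth_summary,
)


def _sim(tmp_path, config, condition="control", seed=3):
    fasta, table = build_genome(config, tmp_path, seed=seed)
    return (fasta, table) + simulate_reads(
        fasta, table, config, condition, tmp_path, seed=seed
    )


class TestBuildGenome:
    def test_counts_by_construction(self, tmp_path):
        config = SimConfig(n_types=8, copies_per_type=3, error_rate=0.0)
        fasta, table = build_genome(config, tmp_path, seed=1)
        genes = parse_gene_table(table, fasta)
        assert len(genes) == 24
        assert len({g.type_key for g in genes}) == 8

    def test_ambiguous_pair_adds_two_identical_genes(self, tmp_path):
        config = SimConfig(ambiguous_pair=True)
        fasta, table = build_genome(config, tmp_path, seed=1)
        genes = parse_gene_table(table, fasta)
        extra = [g for g in genes if g.type_key not in ANN_TYPES]
        assert len(extra) == 2
        assert extra[0].type_key != extra[1].type_key
        from pyfaidx import Fasta

        fa = Fasta(str(fasta))
        assert sense_sequence(extra[0], fa) == sense_sequence(extra[1], fa)

    def test_copies_share_mature_sequence_across_strands(self, tmp_path):
        from pyfaidx import Fasta

        config = SimConfig(n_types=2, copies_per_type=3)
        fasta, table = build_genome(config, tmp_path, seed=2)
        genes = parse_gene_table(table, fasta)
        fa = Fasta(str(fasta))
        for key in {g.type_key for g in genes}:
            copies = [g for g in genes if g.type_key == key]
            assert {g.strand for g in copies} == {"+", "-"}
            seqs = {sense_sequence(g, fa) for g in copies}
            assert len(seqs) == 1

    def test_impossible_config_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_genome(SimConfig(copies_per_type=0), tmp_path, seed=1)

    def test_same_seed_is_byte_identical(self, tmp_path):
        config = SimConfig()
        f1, t1 = build_genome(config, tmp_path / "a", seed=9)
        f2, t2 = build_genome(config, tmp_path / "b", seed=9)
        assert f1.read_bytes() == f2.read_bytes()
        assert t1.read_bytes() == t2.read_bytes()


class TestSimulateReads:
    def test_determinism_bytes(self, tmp_path):
        config = SimConfig(depth_per_copy=60, n_types=3)
        out1 = _sim(tmp_path / "a", config, seed=5)
        out2 = _sim(tmp_path / "b", config, seed=5)
        for p1, p2 in zip(out1[2:], out2[2:]):
            assert p1.read_bytes() == p2.read_bytes()

    def test_conservation_fastq_sam_truth(self, small_study):
        d = small_study["dir"]
        truth = load_truth(d / "control.truth.tsv")
        fastq_ids = [
            line[1:].strip()
            for line in open(d / "control.reads.fastq")
            if line.startswith("@")
        ]
        assert len(fastq_ids) == len(truth)
        assert set(fastq_ids) == set(truth["read_id"])
        import pysam

        with pysam.AlignmentFile(str(d / "control.truth.sam"), "r") as sam:
            sam_ids = [rec.query_name for rec in sam.fetch(until_eof=True)]
        assert set(sam_ids) == set(truth["read_id"])

    def test_pi_one_forces_g_and_pi_zero_forces_a(self, tmp_path):
        for pi, base in ((1.0, "G"), (0.0, "A")):
            config = SimConfig(
                n_types=2, depth_per_copy=80, error_rate=0.0,
                pi_precursor=pi, pi_processed=pi,
            )
            *_, tsv = _sim(tmp_path / f"pi{pi}", config, seed=4)
            truth = load_truth(tsv)
            covered = truth[truth["covers_34"] == 1]
            assert (covered["base34"] == base).all()

    def test_binomial_recovery_of_pi_over_seeds(self, tmp_path):
        """Mean emitted G fraction at residue 34 tracks pi within 3 binomial SE."""
        config = SimConfig(
            n_types=2, copies_per_type=2, depth_per_copy=80, error_rate=0.0
        )
        counts = {}  # (type, stage) -> [n_G, n]
        for seed in range(10):
            *_, tsv = _sim(tmp_path / f"s{seed}", config, seed=100 + seed)
            truth = load_truth(tsv)
            covered = truth[truth["covers_34"] == 1]
            for (key, stage), sub in covered.groupby(["type_key", "stage"]):
                g, n = counts.get((key, stage), (0, 0))
                counts[(key, stage)] = (g + (sub["base34"] == "G").sum(), n + len(sub))
        for (key, stage), (g, n) in counts.items():
            pi = config.pi(key, stage)
            se = np.sqrt(pi * (1 - pi) / n)
            assert abs(g / n - pi) < 3 * se, (key, stage, g / n, pi, n)

    def test_error_model_rate_at_unedited_residue_35(self, tmp_path):
        """Residue 35 is never modified: its non-reference fraction estimates
        the per-base substitution rate epsilon."""
        eps = 0.02
        config = SimConfig(
            n_types=3, copies_per_type=2, depth_per_copy=400, error_rate=eps,
            pi_precursor=0.0, pi_processed=0.0,
        )
        fasta, table, _, sam, tsv = _sim(tmp_path, config, seed=6)
        from pyfaidx import Fasta

        genes = parse_gene_table(table, Fasta(str(fasta)))
        # compare sequenced base at residue 35 against the reference via pileups
        from inoseq.reads import assign_reads

        assigned, _ = assign_reads(sam, genes)
        by_gene = {}
        for r in assigned:
            by_gene.setdefault(r.gene_id, []).append(r)
        fa = Fasta(str(fasta))
        mismatch = total = 0
        for g in genes:
            mat = build_pileup(by_gene.get(g.gene_id, []), g, window=5)
            ref35 = sense_sequence(g, fa)[g.anticodon_offset + 1]
            row = mat.row(1)
            total += row.sum()
            mismatch += row.sum() - mat.count(1, ref35)
        rate = mismatch / total
        se = np.sqrt(eps * (1 - eps) / total)
        assert abs(rate - eps) < 3 * se, (rate, eps, total)

    def test_knockdown_scales_editing_down(self, tmp_path):
        config = SimConfig(n_types=2, depth_per_copy=400, error_rate=0.0, knockdown_factor=0.5)
        *_, tsv_c = _sim(tmp_path / "c", config, condition="control", seed=8)
        *_, tsv_k = _sim(tmp_path / "k", config, condition="knockdown", seed=8)
        for tsv, factor in ((tsv_c, 1.0), (tsv_k, 0.5)):
            truth = load_truth(tsv)
            covered = truth[(truth["covers_34"] == 1) & (truth["stage"] == "processed")]
            frac = (covered["base34"] == "G").mean()
            expected = 0.8 * factor
            se = np.sqrt(expected * (1 - expected) / len(covered))
            assert abs(frac - expected) < 4 * se

    def test_stage_span_invariants(self, small_study):
        truth = load_truth(small_study["dir"] / "control.truth.tsv")
        L = small_study["config"].mature_len
        processed = truth[truth["stage"] == "processed"]
        assert ((processed["local_start"] >= 0) & (processed["local_end"] <= L)).all()
        precursor = truth[truth["stage"] == "precursor"]
        assert ((precursor["local_start"] < 0) | (precursor["local_end"] > L)).all()
        assert (truth.loc[truth["edited_34"] == 1, "base34"] == "G").all()


class TestTruthSummary:
    def test_empty_truth(self):
        empty = pd.DataFrame(
            columns=["type_key", "stage", "condition", "also_maps_to",
                     "covers_34", "covers_35", "covers_37", "base34", "base35", "base37"]
        )
        assert truth_summary(empty).empty

    def test_counting_matches_manual_tally(self, small_study):
        truth = load_truth(small_study["dir"] / "control.truth.tsv")
        summ = truth_summary(truth)
        sub = truth[
            (truth["type_key"] == "Val-AAC")
            & (truth["stage"] == "processed")
            & (truth["covers_34"] == 1)
        ]
        for base in ("A", "G"):
            expect = (sub["base34"] == base).sum()
            got = summ[
                (summ["type_key"] == "Val-AAC") & (summ["stage"] == "processed")
                & (summ["residue"] == 34) & (summ["base"] == base)
            ]["count"]
            assert (got.iloc[0] if len(got) else 0) == expect

    def test_totals_conserved_across_stages(self, small_study):
        truth = load_truth(small_study["dir"] / "control.truth.tsv")
        summ = truth_summary(truth)
        unamb = truth[truth["also_maps_to"] == ""]
        n34 = summ[summ["residue"] == 34]["count"].sum()
        assert n34 == (unamb["covers_34"] == 1).sum()

    def test_malformed_stage_rejected_with_row_number(self, tmp_path, small_study):
        truth = load_truth(small_study["dir"] / "control.truth.tsv").head(5).copy()
        truth.loc[2, "stage"] = "larval"
        bad = tmp_path / "bad.tsv"
        truth.to_csv(bad, sep="\t", index=False)
        with pytest.raises(ValueError, match="row 4"):
            load_truth(bad)
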