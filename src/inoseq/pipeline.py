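"""End-to-end orchestration: simulate, analyze, compare.

``analyze`` chains the whole detection pipeline over one library: SAM
ingestion -> unique-type resolution -> precursor/processed classification
-> per-copy pileups -> anticodon coverage filter -> type-level aggregation
-> composition / editing tables.  ``compare_stages`` and
``compare_conditions`` run the Fisher/BH comparisons the study design calls
for.  All outputs are plain TSV and byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .pileup import (
    PileupMatrix,
    aggregate,
    build_pileup,
    composition_table,
    editing_fraction,
)
from .reads import (
    AssignedRead,
    CoverageFilter,
    apply_coverage_filter,
    assign_reads,
    stage_proportions,
)
from .reference import FlankSpec, TrnaGene, parse_gene_table, sense_sequence
from .simulate import SimConfig, build_genome, simulate_reads
from .stats import compare_editing, comparisons_frame

log = logging.getLogger("inoseq")

STAGES = ("precursor", "processed")


@dataclass
class AnalysisParams:
    """Tunable knobs of one analysis run."""

    flanks: FlankSpec = field(default_factory=FlankSpec)
    window: int = 50
    coverage: CoverageFilter = field(default_factory=CoverageFilter)
    include_introns: bool = False
    count_per_alignment: bool = False

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("window must be >= 3 to contain residues 34-37")


@dataclass
class AnalysisResult:
    """All per-library outputs of :func:`analyze`."""

    params: AnalysisParams
    genes: list[TrnaGene]
    assigned: list[AssignedRead]
    accounting: dict[str, int]
    copy_pileups: dict[tuple[str, str], PileupMatrix]  # (gene_id, stage)
    retained_copies: set[str]
    type_pileups: dict[tuple[str, str], PileupMatrix]  # (type_key, stage)
    window_refs: dict[str, str]  # type_key -> sense reference window (N outside mature)
    condition: str = ""

    def editing_counts(self, stage: str | None = None) -> dict[str, tuple[int, int]]:
        """Per-type (n_A, n_G) at residue 34; ``stage=None`` pools both stages."""
        out: dict[str, tuple[int, int]] = {}
        for (key, stg), mat in self.type_pileups.items():
            if stage is not None and stg != stage:
                continue
            est = editing_fraction(mat)
            a, g = out.get(key, (0, 0))
            out[key] = (a + est.n_A, g + est.n_G)
        return out

    def editing_table(self) -> pd.DataFrame:
        rows = []
        for (key, stg), mat in sorted(self.type_pileups.items()):
            est = editing_fraction(mat)
            rows.append(
                {
                    "type_key": key, "stage": stg, "condition": self.condition,
                    "n_A": est.n_A, "n_G": est.n_G, "n_C": est.n_C, "n_T": est.n_T,
                    "depth": est.depth, "editing_fraction": est.editing_fraction,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "type_key", "stage", "condition",
                "n_A", "n_G", "n_C", "n_T", "depth", "editing_fraction",
            ],
        )

    def composition(self) -> pd.DataFrame:
        mats = [m for _, m in sorted(self.type_pileups.items())]
        return composition_table(mats, self.window_refs)

    def stage_table(self) -> pd.DataFrame:
        return stage_proportions(self.assigned)


def _type_window_reference(gene: TrnaGene, fasta: Fasta, window: int) -> str:
    """Sense reference around residue 34, with N outside the mature span.

    Copies of a type share the mature sequence but not flanking genomic
    context, so a type-level reference is defined only inside the mature
    span.
    """
    seq = sense_sequence(gene, fasta, flank=window)
    a = gene.anticodon_offset
    chars = []
    for rel in range(-window, window + 1):
        i = a + rel
        chars.append(seq[window + i] if 0 <= i < gene.mature_length else "N")
    return "".join(chars)


def analyze(
    gene_table: str | Path,
    genome: str | Path,
    sam_path: str | Path,
    params: AnalysisParams | None = None,
    condition: str = "",
) -> AnalysisResult:
    """Run the full per-library pipeline on a SAM of tRNA alignments."""
    params = params or AnalysisParams()
    fasta = Fasta(str(genome))
    genes = parse_gene_table(gene_table, fasta)
    if not params.include_introns:
        genes = [g for g in genes if not g.has_intron]

    assigned, accounting = assign_reads(
        sam_path, genes, params.flanks, count_per_alignment=params.count_per_alignment
    )
    log.info(
        "reads: total=%d counted=%d ambiguous=%d unassigned=%d",
        accounting["total"], accounting["counted"],
        accounting["ambiguous"], accounting["unassigned"],
    )

    by_copy_stage: dict[tuple[str, str], list[AssignedRead]] = {}
    for r in assigned:
        by_copy_stage.setdefault((r.gene_id, r.stage), []).append(r)
    gene_by_id = {g.gene_id: g for g in genes}
    copy_pileups = {
        (gid, stg): build_pileup(
            rs, gene_by_id[gid], params.window, key=gid, stage=stg, condition=condition
        )
        for (gid, stg), rs in sorted(by_copy_stage.items())
    }

    depth_at_34: dict[str, int] = {}
    for (gid, _), mat in copy_pileups.items():
        depth_at_34[gid] = depth_at_34.get(gid, 0) + mat.depth(0)
    retained = apply_coverage_filter(depth_at_34, params.coverage)
    log.info("coverage filter: %d/%d copies retained", len(retained), len(depth_at_34))

    type_pileups: dict[tuple[str, str], PileupMatrix] = {}
    for (gid, stg), mat in copy_pileups.items():
        if gid not in retained:
            continue
        key = (gene_by_id[gid].type_key, stg)
        if key in type_pileups:
            type_pileups[key] = type_pileups[key] + mat
        else:
            type_pileups[key] = PileupMatrix(
                key=key[0], stage=stg, window=params.window,
                counts=mat.counts.copy(), condition=condition,
            )

    window_refs = {}
    for g in genes:
        if g.type_key not in window_refs:
            window_refs[g.type_key] = _type_window_reference(g, fasta, params.window)

    return AnalysisResult(
        params=params, genes=genes, assigned=assigned, accounting=accounting,
        copy_pileups=copy_pileups, retained_copies=retained,
        type_pileups=type_pileups, window_refs=window_refs, condition=condition,
    )


def write_analysis(result: AnalysisResult, outdir: str | Path) -> dict[str, Path]:
    """Write assignment, composition, editing and stage-proportion TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    assign_df = pd.DataFrame(
        [
            {
                "read_id": r.read_id, "type_key": r.type_key, "gene_id": r.gene_id,
                "stage": r.stage, "start": r.ref_start, "end": r.ref_end,
                "span_length": r.ref_end - r.ref_start,
            }
            for r in result.assigned
        ],
        columns=["read_id", "type_key", "gene_id", "stage", "start", "end", "span_length"],
    )
    for name, df in (
        ("assignments", assign_df),
        ("composition", result.composition()),
        ("editing", result.editing_table()),
        ("stage_proportions", result.stage_table()),
    ):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths


def compare_stages(
    result: AnalysisResult, family: Sequence[str] | None = None
) -> pd.DataFrame:
    """Precursor (group A) vs processed (group B) A/G comparison per type."""
    pre = result.editing_counts("precursor")
    pro = result.editing_counts("processed")
    if family is None:
        family = sorted(set(pre) & set(pro))
        if not family:
            raise ValueError("no tRNA type has counts in both stages")
    return comparisons_frame(compare_editing(pre, pro, family))


def compare_conditions(
    result_a: AnalysisResult,
    result_b: AnalysisResult,
    stage: str | None = None,
    family: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Condition A (e.g. control) vs condition B (e.g. knockdown) per type.

    Counts are pooled over stages by default (``stage`` restricts to one).
    """
    ca = result_a.editing_counts(stage)
    cb = result_b.editing_counts(stage)
    if family is None:
        family = sorted(set(ca) & set(cb))
        if not family:
            raise ValueError("the two runs share no tRNA types")
    return comparisons_frame(compare_editing(ca, cb, family))


def config_hash(config: SimConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def simulate_study(
    config: SimConfig,
    outdir: str | Path,
    conditions: Sequence[str] = ("control",),
    seed: int | None = None,
) -> dict:
    """Build a synthetic genome and simulate one library per condition.

    Writes ``genome.fa``, ``genes.tsv``, per-condition FASTQ/SAM/TSV and a
    ``manifest.json`` recording the seed and a hash of the resolved config.
    Rerunning with the same config and seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base_seed = config.seed if seed is None else seed
    fasta_path, table_path = build_genome(config, outdir, seed=base_seed)
    files: dict[str, dict[str, str]] = {}
    for i, condition in enumerate(conditions):
        ss = np.random.SeedSequence([base_seed, i])
        fq, sam, tsv = simulate_reads(
            fasta_path, table_path, config, condition, outdir,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        files[condition] = {"fastq": fq.name, "sam": sam.name, "truth": tsv.name}
    manifest = {
        "seed": base_seed,
        "config_sha256": config_hash(config),
        "genome": fasta_path.name,
        "gene_table": table_path.name,
        "conditions": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
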