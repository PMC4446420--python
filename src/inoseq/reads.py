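"""SAM ingestion, read-to-type resolution and maturation-stage classification.

A read is kept only when every reported alignment falls within the gene
windows (mature span plus leader/trailer flanks) of a *single* tRNA type —
reads touching two or more types are discarded as cross-type ambiguous,
reads touching none are unassigned.  Kept reads are counted once, at their
primary alignment, and labelled ``precursor`` when at least one aligned
base lies outside the mature span (i.e. in the leader/trailer window) or
``processed`` when the aligned span lies entirely within the mature
coordinates (full-length-like reads and internal fragments alike).

Soft-clipped bases are excluded from spans and base calls throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .reference import FlankSpec, TrnaGene, flank_intervals, gene_window

AMBIGUOUS = "AMBIGUOUS"
UNASSIGNED = "UNASSIGNED"

_CONSUMES_REF = {0, 2, 3, 7, 8}  # M, D, N, =, X
_ALIGNED = {0, 7, 8}  # M, =, X consume both read and reference


@dataclass(frozen=True)
class CoverageFilter:
    """Per-copy minimum read depth at the residue-34 genomic position."""

    min_depth: int = 10

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class Alignment:
    """One SAM record reduced to what assignment and pileups need."""

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    is_secondary: bool
    positions: np.ndarray  # aligned reference positions (soft-clips excluded)
    bases: np.ndarray  # genome-forward base per aligned position ('S1')


@dataclass
class AssignedRead:
    """A read resolved to one tRNA type with a maturation-stage label."""

    read_id: str
    type_key: str
    gene_id: str
    stage: str
    ref_start: int
    ref_end: int
    positions: np.ndarray
    bases: np.ndarray


class GeneIndex:
    """Per-chromosome lookup of gene windows (mature span + flanks)."""

    def __init__(self, genes: Iterable[TrnaGene], flanks: FlankSpec):
        self.flanks = flanks
        self.by_chrom: dict[str, list[tuple[int, int, TrnaGene]]] = {}
        self.by_id: dict[str, TrnaGene] = {}
        for g in genes:
            lo, hi = gene_window(g, flanks)
            self.by_chrom.setdefault(g.chrom, []).append((lo, hi, g))
            self.by_id[g.gene_id] = g
        for lst in self.by_chrom.values():
            lst.sort(key=lambda t: t[0])

    def overlapping(self, chrom: str, start: int, end: int) -> list[TrnaGene]:
        if chrom not in self.by_chrom:
            raise KeyError(f"alignment references unknown chromosome {chrom!r}")
        return [g for lo, hi, g in self.by_chrom[chrom] if start < hi and end > lo]


def _parse_record(rec: pysam.AlignedSegment) -> Alignment | None:
    if rec.is_unmapped or rec.query_sequence is None:
        return None
    positions: list[int] = []
    bases: list[str] = []
    rpos = rec.reference_start
    qpos = 0
    seq = rec.query_sequence
    for op, length in rec.cigartuples or []:
        if op in _ALIGNED:
            positions.extend(range(rpos, rpos + length))
            bases.extend(seq[qpos:qpos + length])
            rpos += length
            qpos += length
        elif op in _CONSUMES_REF:  # D, N
            rpos += length
        elif op in (1, 4):  # I, S consume the read only
            qpos += length
    if not positions:
        return None
    return Alignment(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        ref_start=positions[0],
        ref_end=positions[-1] + 1,
        is_secondary=rec.is_secondary,
        positions=np.asarray(positions, dtype=np.int64),
        bases=np.frombuffer("".join(bases).upper().encode(), dtype="S1").copy(),
    )


def read_alignments(sam_path: str | Path) -> dict[str, list[Alignment]]:
    """Group all mapped SAM records by read id (any sort order)."""
    grouped: dict[str, list[Alignment]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            aln = _parse_record(rec)
            if aln is not None:
                grouped.setdefault(aln.read_id, []).append(aln)
    return grouped


def resolve_type(
    alignments: Sequence[Alignment], index: GeneIndex
) -> tuple[str, dict[int, list[TrnaGene]]]:
    """Resolve a read's alignments to a unique tRNA type.

    Returns ``(type_key | AMBIGUOUS | UNASSIGNED, per-alignment gene hits)``.
    A read aligning (via any of its records) to genes of two or more types
    is ambiguous and excluded from all counts; a read whose alignments
    overlap no gene window is unassigned.
    """
    hits: dict[int, list[TrnaGene]] = {}
    keys: set[str] = set()
    for i, aln in enumerate(alignments):
        genes = index.overlapping(aln.chrom, aln.ref_start, aln.ref_end)
        hits[i] = genes
        keys.update(g.type_key for g in genes)
    if len(keys) == 0:
        return UNASSIGNED, hits
    if len(keys) > 1:
        return AMBIGUOUS, hits
    return next(iter(keys)), hits


def classify_stage(span: tuple[int, int], gene: TrnaGene, flanks: FlankSpec) -> str:
    """``precursor`` if >=1 aligned nt lies in a leader/trailer window, else ``processed``.

    A span lying wholly inside the mature coordinates (full-length or
    internal fragment) is processed; a span overlapping only a flank window
    still contains leader/trailer sequence and is precursor.
    """
    start, end = span
    if start >= gene.mature_start and end <= gene.mature_end:
        return "processed"
    (l_lo, l_hi), (t_lo, t_hi) = flank_intervals(gene, flanks)
    in_mature = start < gene.mature_end and end > gene.mature_start
    in_leader = start < l_hi and end > l_lo
    in_trailer = start < t_hi and end > t_lo
    if not (in_mature or in_leader or in_trailer):
        raise ValueError(f"span {span} is disjoint from gene {gene.gene_id}")
    return "precursor" if (in_leader or in_trailer) else "processed"


def _pick_counted(
    alignments: Sequence[Alignment],
    hits: Mapping[int, list[TrnaGene]],
    count_per_alignment: bool,
) -> list[tuple[Alignment, TrnaGene]]:
    """Select the alignment(s) a type-resolved read contributes to counts.

    Default: one record — the primary if present, else the first by
    coordinate (copies of a type are interchangeable).  With
    ``count_per_alignment`` every gene-overlapping record is counted.
    """
    candidates = [
        (alignments[i], genes[0]) for i, genes in sorted(hits.items()) if genes
    ]
    if count_per_alignment:
        return candidates
    primaries = [c for c in candidates if not c[0].is_secondary]
    pool = primaries if primaries else candidates
    return [min(pool, key=lambda c: (c[0].chrom, c[0].ref_start))]


def assign_reads(
    sam_path: str | Path,
    genes: Iterable[TrnaGene],
    flanks: FlankSpec = FlankSpec(),
    *,
    count_per_alignment: bool = False,
) -> tuple[list[AssignedRead], dict[str, int]]:
    """Run type resolution and stage classification over a whole SAM file.

    Returns the assigned reads and an accounting dict partitioning every
    input read into exactly one of ``counted``, ``ambiguous``,
    ``unassigned`` categories.
    """
    index = GeneIndex(genes, flanks)
    grouped = read_alignments(sam_path)
    assigned: list[AssignedRead] = []
    accounting = {"total": 0, "counted": 0, "ambiguous": 0, "unassigned": 0}
    for read_id in grouped:
        alignments = grouped[read_id]
        accounting["total"] += 1
        status, hits = resolve_type(alignments, index)
        if status == AMBIGUOUS:
            accounting["ambiguous"] += 1
            continue
        if status == UNASSIGNED:
            accounting["unassigned"] += 1
            continue
        accounting["counted"] += 1
        for aln, gene in _pick_counted(alignments, hits, count_per_alignment):
            stage = classify_stage((aln.ref_start, aln.ref_end), gene, flanks)
            assigned.append(
                AssignedRead(
                    read_id=read_id,
                    type_key=status,
                    gene_id=gene.gene_id,
                    stage=stage,
                    ref_start=aln.ref_start,
                    ref_end=aln.ref_end,
                    positions=aln.positions,
                    bases=aln.bases,
                )
            )
    return assigned, accounting


def stage_proportions(assigned: Iterable[AssignedRead]) -> pd.DataFrame:
    """Per-type and overall precursor/processed read fractions.

    Types with zero reads are absent; the read-weighted overall row uses the
    key ``ALL``.  Fractions are NaN only when a total is zero (never 0/0
    coerced to 0).
    """
    counts: dict[str, list[int]] = {}
    for r in assigned:
        row = counts.setdefault(r.type_key, [0, 0])
        row[0 if r.stage == "precursor" else 1] += 1
    rows = []
    tot_pre = tot_pro = 0
    for key in sorted(counts):
        pre, pro = counts[key]
        tot_pre += pre
        tot_pro += pro
        total = pre + pro
        rows.append(
            {
                "type_key": key,
                "n_precursor": pre,
                "n_processed": pro,
                "frac_precursor": pre / total if total else np.nan,
                "frac_processed": pro / total if total else np.nan,
            }
        )
    total = tot_pre + tot_pro
    rows.append(
        {
            "type_key": "ALL",
            "n_precursor": tot_pre,
            "n_processed": tot_pro,
            "frac_precursor": tot_pre / total if total else np.nan,
            "frac_processed": tot_pro / total if total else np.nan,
        }
    )
    return pd.DataFrame(rows)


def apply_coverage_filter(
    depth_at_34: Mapping[str, int], filt: CoverageFilter = CoverageFilter()
) -> set[str]:
    """Gene copies retained by the anticodon-depth filter.

    ``depth_at_34`` maps gene_id to the read depth at the residue-34 genomic
    position (pooled over stages).  A copy is retained iff its depth is at
    least ``min_depth``; removal happens per copy, before type aggregation.
    """
    return {gid for gid, d in depth_at_34.items() if d >= filt.min_depth}
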