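"""Per-position base counting around the anticodon and editing estimation.

All positions are expressed relative to residue 34 in tRNA sense
orientation (0 = residue 34, +1 = residue 35, +3 = residue 37); minus-strand
genes contribute complemented, sense-oriented base calls.  The editing
statistic is the A/G mismatch proportion G/(A+G) at position 0 — inosine is
read as G by the sequencer, so at a genomically encoded A34 the G fraction
estimates the inosine level.  C/T calls at the position are reported but
excluded from the fraction (they are error, not editing).

Cross-type comparisons of editing levels are deliberately not produced as a
ranked table: library biases against heavily structured/modified mature
tRNAs make between-type level comparisons misleading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import TrnaGene, anticodon_genomic_positions

_BASE_INDEX = {b"A"[0]: 0, b"C"[0]: 1, b"G"[0]: 2, b"T"[0]: 3}
BASES = ("A", "C", "G", "T")
_COMP_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G in _BASE_INDEX order


@dataclass
class PileupMatrix:
    """Base counts per position in a window centred on residue 34.

    ``counts`` has shape ``(2*window+1, 4)`` with columns A, C, G, T;
    row ``window + r`` holds relative position ``r``.
    """

    key: str
    stage: str
    window: int
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    condition: str = ""

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros((2 * self.window + 1, 4), dtype=np.int64)
        if self.counts.shape != (2 * self.window + 1, 4):
            raise ValueError("counts shape does not match window")

    def row(self, rel: int) -> np.ndarray:
        if abs(rel) > self.window:
            raise IndexError(f"relative position {rel} outside +/-{self.window} window")
        return self.counts[self.window + rel]

    def depth(self, rel: int) -> int:
        return int(self.row(rel).sum())

    def count(self, rel: int, base: str) -> int:
        return int(self.row(rel)[BASES.index(base)])

    def __add__(self, other: "PileupMatrix") -> "PileupMatrix":
        if self.window != other.window:
            raise ValueError("cannot add pileups with different windows")
        return PileupMatrix(
            key=self.key, stage=self.stage, window=self.window,
            counts=self.counts + other.counts, condition=self.condition,
        )


@dataclass
class CompositionRow:
    """Base composition at one relative position."""

    key: str
    stage: str
    position: int
    fraction_A: float
    fraction_C: float
    fraction_G: float
    fraction_T: float
    depth: int


@dataclass
class EditingEstimate:
    """A/G mismatch proportion at residue 34 for one (key, stage) cell."""

    key: str
    stage: str
    n_A: int
    n_G: int
    n_C: int
    n_T: int
    depth: int

    @property
    def editing_fraction(self) -> float:
        informative = self.n_A + self.n_G
        return self.n_G / informative if informative else float("nan")


def build_pileup(
    reads: Iterable,  # AssignedRead-like: positions, bases arrays
    gene: TrnaGene,
    window: int = 50,
    key: str | None = None,
    stage: str = "",
    condition: str = "",
) -> PileupMatrix:
    """Count aligned read bases in sense coordinates around the gene's residue 34.

    Every aligned base whose position falls within ``+/-window`` of the
    residue-34 genomic coordinate is counted; minus-strand genes flip the
    relative axis and complement the base.  Positions a read does not cover
    are untouched.  Non-ACGT calls (e.g. N) are ignored.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    mat = PileupMatrix(key=key or gene.gene_id, stage=stage, window=window, condition=condition)
    g34 = anticodon_genomic_positions(gene)[0]
    sign = 1 if gene.strand == "+" else -1
    for r in reads:
        rel = sign * (r.positions - g34)
        mask = np.abs(rel) <= window
        if not mask.any():
            continue
        rel = rel[mask]
        raw = r.bases[mask].view(np.uint8)
        idx = np.full(raw.shape, -1, dtype=np.int64)
        for byte, col in _BASE_INDEX.items():
            idx[raw == byte] = col
        valid = idx >= 0
        if gene.strand == "-":
            idx[valid] = _COMP_IDX[idx[valid]]
        np.add.at(mat.counts, (window + rel[valid], idx[valid]), 1)
    return mat


def aggregate(pileups: Sequence[PileupMatrix], key: str | None = None) -> PileupMatrix:
    """Element-wise sum of pileups (across gene copies and/or replicates).

    All inputs must share the same key (or the explicit ``key`` target),
    stage and window; the sum is associative and order-independent.
    """
    if not pileups:
        raise ValueError("nothing to aggregate")
    first = pileups[0]
    out_key = key if key is not None else first.key
    total = np.zeros_like(first.counts)
    for p in pileups:
        if key is None and p.key != out_key:
            raise ValueError(f"refusing to aggregate {p.key!r} into {out_key!r}")
        if p.stage != first.stage or p.window != first.window:
            raise ValueError("aggregation requires identical stage and window")
        total += p.counts
    return PileupMatrix(
        key=out_key, stage=first.stage, window=first.window,
        counts=total, condition=first.condition,
    )


def composition_at(matrix: PileupMatrix, position: int) -> CompositionRow:
    """Base fractions at a relative position; NaN fractions when depth is 0."""
    row = matrix.row(position)
    depth = int(row.sum())
    fr = row / depth if depth else np.full(4, np.nan)
    return CompositionRow(
        key=matrix.key, stage=matrix.stage, position=position,
        fraction_A=float(fr[0]), fraction_C=float(fr[1]),
        fraction_G=float(fr[2]), fraction_T=float(fr[3]), depth=depth,
    )


def editing_fraction(matrix: PileupMatrix) -> EditingEstimate:
    """A/G mismatch proportion at relative position 0 (residue 34)."""
    row = matrix.row(0)
    return EditingEstimate(
        key=matrix.key, stage=matrix.stage,
        n_A=int(row[0]), n_G=int(row[2]), n_C=int(row[1]), n_T=int(row[3]),
        depth=int(row.sum()),
    )


def position37_composition(matrix: PileupMatrix) -> CompositionRow:
    """Base composition at residue 37 (relative position +3).

    On types carrying the stepwise residue-37 modification (tRNA-Ala), an
    inosine 37 reads as G and a 1-methylinosine 37 as T, so the G and T
    fractions track the two modification states.
    """
    if matrix.window < 3:
        raise ValueError("window must be >= 3 to reach residue 37")
    return composition_at(matrix, 3)


def background_mismatch_profile(
    matrix: PileupMatrix, reference_window: str
) -> pd.DataFrame:
    """Per-position A-to-G proportion at every reference-A position in the window.

    ``reference_window`` is the sense reference sequence covering the whole
    window (length ``2*window+1``, centre = residue 34); positions whose
    reference base is not A (or is unknown, ``N``) are excluded.  Residue 34
    itself is flagged with ``is_34`` so callers can contrast the editing
    signal against the sequencing-error background at all other A positions.
    Columns: ``position, n_A, n_G, ag_proportion, is_34``.
    """
    w = matrix.window
    if len(reference_window) != 2 * w + 1:
        raise ValueError(f"reference window must have length {2 * w + 1}")
    rows = []
    for rel in range(-w, w + 1):
        if reference_window[w + rel].upper() != "A":
            continue
        n_a = matrix.count(rel, "A")
        n_g = matrix.count(rel, "G")
        prop = n_g / (n_a + n_g) if (n_a + n_g) else np.nan
        rows.append({"position": rel, "n_A": n_a, "n_G": n_g, "ag_proportion": prop, "is_34": rel == 0})
    return pd.DataFrame(rows, columns=["position", "n_A", "n_G", "ag_proportion", "is_34"])


def background_summary(profile: pd.DataFrame) -> dict[str, float]:
    """Max and mean background A->G proportion, excluding residue 34."""
    bg = profile[(~profile["is_34"]) & profile["ag_proportion"].notna()]
    if bg.empty:
        return {"max": float("nan"), "mean": float("nan")}
    return {"max": float(bg["ag_proportion"].max()), "mean": float(bg["ag_proportion"].mean())}


def composition_table(matrices: Iterable[PileupMatrix], reference_windows: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Long-format per-position composition for a set of pileups.

    Columns: key, condition, stage, position, ref_base, A, C, G, T, depth,
    fraction_A..fraction_T.  ``reference_windows`` optionally supplies the
    sense reference per key to fill ``ref_base`` (``.`` when unknown).
    """
    rows = []
    for m in matrices:
        ref = reference_windows.get(m.key) if reference_windows else None
        for rel in range(-m.window, m.window + 1):
            counts = m.row(rel)
            depth = int(counts.sum())
            if depth == 0:
                continue
            fr = counts / depth
            rows.append(
                {
                    "key": m.key, "condition": m.condition, "stage": m.stage,
                    "position": rel,
                    "ref_base": ref[m.window + rel] if ref else ".",
                    "A": int(counts[0]), "C": int(counts[1]),
                    "G": int(counts[2]), "T": int(counts[3]),
                    "depth": depth,
                    "fraction_A": fr[0], "fraction_C": fr[1],
                    "fraction_G": fr[2], "fraction_T": fr[3],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "key", "condition", "stage", "position", "ref_base",
            "A", "C", "G", "T", "depth",
            "fraction_A", "fraction_C", "fraction_G", "fraction_T",
        ],
    )
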