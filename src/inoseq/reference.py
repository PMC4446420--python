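"""tRNA gene models: annotation ingestion, type grouping, anticodon coordinates.

The unit of annotation is one genomic tRNA gene copy.  A tRNA *type*
(isodecoder group, e.g. ``Val-AAC``) usually has several near-identical
genomic copies, so reads from the mature body of the tRNA multi-map within
the type.  All genomic coordinates are 0-based half-open; residue numbers
follow conventional tRNA numbering, residue 34 being the first (wobble)
position of the anticodon.

The gene table is a BED-like TSV with columns::

    chrom  start  end  gene_id  score  strand  type_key  anticodon_offset  has_intron

where ``start``/``end`` delimit the mature (leader/trailer-excluded) span and
``anticodon_offset`` is the 0-based index of residue 34 within the mature
sense-strand sequence.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pyfaidx import Fasta

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(seq: str) -> str:
    """Complement of a nucleotide string (keeps orientation)."""
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse-complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


class GeneTableError(ValueError):
    """A gene table row is malformed or violates a gene invariant."""


@dataclass(frozen=True)
class TrnaGene:
    """One genomic tRNA gene copy.

    ``mature_start``/``mature_end`` span the mature sequence only;
    5'-leader and 3'-trailer windows are derived from a :class:`FlankSpec`.
    """

    gene_id: str
    type_key: str
    chrom: str
    strand: str
    mature_start: int
    mature_end: int
    anticodon_offset: int
    has_intron: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneTableError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.mature_start < self.mature_end:
            raise GeneTableError(
                f"{self.gene_id}: mature_start must be < mature_end "
                f"({self.mature_start} >= {self.mature_end})"
            )
        if not 0 <= self.anticodon_offset <= self.mature_length - 3:
            raise GeneTableError(
                f"{self.gene_id}: anticodon_offset {self.anticodon_offset} leaves no room "
                f"for residues 34-36 in a {self.mature_length} nt mature span"
            )

    @property
    def mature_length(self) -> int:
        return self.mature_end - self.mature_start

    @property
    def anticodon(self) -> str:
        """Annotated anticodon, taken from the ``AminoAcid-Anticodon`` type key."""
        return self.type_key.split("-", 1)[1].upper()


@dataclass(frozen=True)
class TrnaTypeGroup:
    """All genomic copies sharing one ``AminoAcid-Anticodon`` type key."""

    type_key: str
    gene_ids: frozenset[str]


@dataclass(frozen=True)
class FlankSpec:
    """Lengths (nt) of the 5'-leader and 3'-trailer windows flanking the mature span."""

    leader_len: int = 50
    trailer_len: int = 50

    def __post_init__(self) -> None:
        if self.leader_len < 0 or self.trailer_len < 0:
            raise ValueError("flank lengths must be >= 0")


def parse_gene_table(
    path: str | Path,
    genome: str | Path | Fasta,
    *,
    validate_anticodon: bool = True,
) -> list[TrnaGene]:
    """Load a tRNA gene table, validating each row against the genome FASTA.

    Malformed rows are collected and reported together with their line
    numbers.  Rows with ``has_intron`` set are loaded but flagged; callers
    analysing editing exclude them by default (their genomic anticodon
    coordinates are only valid for unspliced transcripts).

    Raises
    ------
    GeneTableError
        On any malformed row, a chromosome missing from the FASTA, a
        coordinate outside the chromosome, or (if ``validate_anticodon``)
        a sense-strand anticodon triplet disagreeing with the type key.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    genes: list[TrnaGene] = []
    errors: list[str] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                errors.append(f"line {lineno}: expected 9 columns, got {len(fields)}")
                continue
            chrom, start_s, end_s, gene_id, _score, strand, type_key, off_s, intron_s = fields
            try:
                start, end, offset = int(start_s), int(end_s), int(off_s)
                has_intron = intron_s.strip().lower() in ("1", "true", "yes")
                gene = TrnaGene(gene_id, type_key, chrom, strand, start, end, offset, has_intron)
            except (ValueError, GeneTableError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            if gene_id in seen_ids:
                errors.append(f"line {lineno}: duplicate gene_id {gene_id!r}")
                continue
            seen_ids.add(gene_id)
            if chrom not in fasta:
                raise GeneTableError(f"line {lineno}: chromosome {chrom!r} not found in genome FASTA")
            chrom_len = len(fasta[chrom])
            if end > chrom_len:
                raise GeneTableError(
                    f"line {lineno}: {gene_id} end {end} exceeds {chrom} length {chrom_len}"
                )
            if validate_anticodon:
                triplet = anticodon_sense_triplet(gene, fasta)
                if triplet != gene.anticodon:
                    errors.append(
                        f"line {lineno}: {gene_id} sense anticodon {triplet} does not match "
                        f"type key anticodon {gene.anticodon}"
                    )
                    continue
            genes.append(gene)
    if errors:
        raise GeneTableError("gene table errors:\n" + "\n".join(errors))
    return genes


def group_by_type(genes: Iterable[TrnaGene]) -> list[TrnaTypeGroup]:
    """Partition gene copies into type groups, ordered by type key."""
    by_key: dict[str, set[str]] = {}
    for g in genes:
        by_key.setdefault(g.type_key, set()).add(g.gene_id)
    return [TrnaTypeGroup(k, frozenset(v)) for k, v in sorted(by_key.items())]


def anticodon_genomic_positions(gene: TrnaGene) -> tuple[int, int, int]:
    """Genomic coordinates of anticodon residues 34, 35, 36 (in residue order)."""
    if gene.strand == "+":
        g34 = gene.mature_start + gene.anticodon_offset
        return (g34, g34 + 1, g34 + 2)
    g34 = gene.mature_end - 1 - gene.anticodon_offset
    return (g34, g34 - 1, g34 - 2)


def flank_intervals(
    gene: TrnaGene,
    spec: FlankSpec,
    chrom_length: int | None = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Genomic (leader, trailer) intervals, 0-based half-open, clipped at chrom bounds.

    The leader is 5' of the mature span *in tRNA sense*, so for a minus-strand
    gene it lies genomically downstream of ``mature_end``.
    """
    if gene.strand == "+":
        leader = (gene.mature_start - spec.leader_len, gene.mature_start)
        trailer = (gene.mature_end, gene.mature_end + spec.trailer_len)
    else:
        leader = (gene.mature_end, gene.mature_end + spec.leader_len)
        trailer = (gene.mature_start - spec.trailer_len, gene.mature_start)

    def _clip(iv: tuple[int, int]) -> tuple[int, int]:
        lo = max(iv[0], 0)
        hi = iv[1] if chrom_length is None else min(iv[1], chrom_length)
        return (lo, max(lo, hi))

    return _clip(leader), _clip(trailer)


def gene_window(gene: TrnaGene, spec: FlankSpec) -> tuple[int, int]:
    """Genomic interval covering mature span plus both flank windows."""
    (a, b), (c, d) = flank_intervals(gene, spec)
    lo = min(a, c, gene.mature_start)
    hi = max(b, d, gene.mature_end)
    return lo, hi


def local_to_genomic(gene: TrnaGene, i: int) -> int:
    """Map a sense-local index (0 = first mature base; negatives = leader) to genomic."""
    if gene.strand == "+":
        return gene.mature_start + i
    return gene.mature_end - 1 - i


def genomic_to_local(gene: TrnaGene, pos: int) -> int:
    """Inverse of :func:`local_to_genomic`."""
    if gene.strand == "+":
        return pos - gene.mature_start
    return gene.mature_end - 1 - pos


def sense_sequence(gene: TrnaGene, fasta: Fasta, flank: int = 0) -> str:
    """Sense-strand sequence of the mature span, optionally with ``flank`` nt each side.

    Indexing into the returned string at ``flank + i`` gives sense-local
    position ``i``.  Positions clipped at chromosome bounds are padded with
    ``N`` so the indexing stays aligned.
    """
    chrom_len = len(fasta[gene.chrom])
    lo, hi = gene.mature_start - flank, gene.mature_end + flank
    core = str(fasta[gene.chrom][max(lo, 0):min(hi, chrom_len)]).upper()
    core = "N" * (0 - min(lo, 0)) + core + "N" * max(hi - chrom_len, 0)
    return revcomp(core) if gene.strand == "-" else core


def anticodon_sense_triplet(gene: TrnaGene, fasta: Fasta) -> str:
    """Sense-strand bases at residues 34-36 as read from the genome."""
    seq = sense_sequence(gene, fasta)
    return seq[gene.anticodon_offset:gene.anticodon_offset + 3]


def find_anticodon_offset(mature_seq: str, anticodon: str) -> int:
    """Derive the residue-34 offset by unique substring search.

    Helper for annotations lacking an explicit offset.  Raises ``ValueError``
    if the anticodon is absent or occurs more than once in the mature
    sequence (ambiguous placement must be resolved by the annotator).
    """
    mature_seq, anticodon = mature_seq.upper(), anticodon.upper()
    first = mature_seq.find(anticodon)
    if first < 0:
        raise ValueError(f"anticodon {anticodon} not found in mature sequence")
    if mature_seq.find(anticodon, first + 1) >= 0:
        raise ValueError(f"anticodon {anticodon} occurs more than once; offset is ambiguous")
    return first
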