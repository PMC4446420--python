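"""Synthetic small-RNA-seq generator with per-read modification truth.

Emulates the structure of a tRNA-focused small-RNA-seq experiment at desk
scale: eight ANN tRNA types (anticodon starting with A, the substrates of
the heterodimeric A34 deaminase), each present as several genomic copies
with identical mature sequence but copy-specific leader/trailer context;
reads that either retain precursor leader/trailer sequence or lie fully
inside the mature span; Bernoulli A-to-I editing at residue 34 (sequenced
as G) whose rate depends on maturation stage; a stepwise residue-37 model
on Ala-AGC (inosine read as G, 1-methylinosine as T); uniform per-base
substitution error; and a knockdown condition that multiplies all editing
rates by a factor kappa.

Outputs are FASTQ (Phred-33, constant quality), a truth SAM (one alignment
per true origin, plus a secondary record at the partner gene for
cross-type-ambiguous reads), and a truth TSV with per-read ground truth.
All outputs are byte-deterministic for a fixed (config, condition, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .reference import TrnaGene, parse_gene_table, revcomp, sense_sequence
from pyfaidx import Fasta

#: The eight human tRNA types with a genomically encoded A34 (ANN anticodon).
ANN_TYPES = (
    "Ala-AGC",
    "Arg-ACG",
    "Ile-AAT",
    "Leu-AAG",
    "Pro-AGG",
    "Ser-AGA",
    "Thr-AGT",
    "Val-AAC",
)

#: Extra pair of types with identical mature sequence (cross-type ambiguity).
AMBIGUOUS_PAIR_TYPES = ("Cys-ACA", "Sec-ACA")

_BASES = np.frombuffer(b"ACGT", dtype="S1")

TRUTH_COLUMNS = [
    "read_id", "condition", "gene_id", "type_key", "stage",
    "local_start", "local_end", "covers_34", "covers_35", "covers_37",
    "edited_34", "base34", "base35", "base37", "also_maps_to",
]


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment.

    Editing probabilities ``pi_precursor``/``pi_processed`` may be scalars or
    per-type mappings; the defaults mimic substantial editing already present
    on early precursors and near-complete editing after end processing.
    ``knockdown_factor`` multiplies every editing probability in the
    knockdown condition.  ``error_rate`` is the per-base probability of
    substitution to one of the three other bases (uniformly).
    """

    n_types: int = 8
    copies_per_type: int = 3
    ambiguous_pair: bool = False
    pi_precursor: float | Mapping[str, float] = 0.2
    pi_processed: float | Mapping[str, float] = 0.8
    knockdown_factor: float = 0.5
    error_rate: float = 0.005
    depth_per_copy: float = 500.0
    stage_fraction_precursor: float = 0.7
    p_cover_anticodon: float = 0.8
    frag_len_min: int = 25
    frag_len_max: int = 60
    max_flank_ext: int = 15
    # residue-37 stepwise model, applied to types in pos37_types
    pos37_types: tuple[str, ...] = ("Ala-AGC",)
    p37_G_precursor: float = 0.3
    p37_T_precursor: float = 0.0
    p37_G_processed: float = 0.3
    p37_T_processed: float = 0.2
    mature_len: int = 76
    anticodon_offset: int = 33  # 0-based index of residue 34 in a canonical 76-mer
    flank_len: int = 50
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "stage_fraction_precursor": self.stage_fraction_precursor,
            "p_cover_anticodon": self.p_cover_anticodon,
            "p37_G_precursor": self.p37_G_precursor,
            "p37_T_precursor": self.p37_T_precursor,
            "p37_G_processed": self.p37_G_processed,
            "p37_T_processed": self.p37_T_processed,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.knockdown_factor <= 1.0:
            raise ValueError("knockdown_factor must be in (0,1]")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.p37_G_precursor + self.p37_T_precursor > 1.0:
            raise ValueError("precursor residue-37 outcome probabilities exceed 1")
        if self.p37_G_processed + self.p37_T_processed > 1.0:
            raise ValueError("processed residue-37 outcome probabilities exceed 1")
        if self.n_types < 1 or self.n_types > len(ANN_TYPES):
            raise ValueError(f"n_types must be in 1..{len(ANN_TYPES)}")
        if self.copies_per_type < 1:
            raise ValueError("copies_per_type must be >= 1")
        if self.depth_per_copy < 0:
            raise ValueError("depth_per_copy must be >= 0")
        if not 0 < self.frag_len_min <= self.frag_len_max:
            raise ValueError("fragment length bounds must satisfy 0 < min <= max")
        if self.max_flank_ext < 1 or self.max_flank_ext > self.flank_len:
            raise ValueError("max_flank_ext must be in 1..flank_len")
        if not 0 <= self.anticodon_offset <= self.mature_len - 4:
            raise ValueError("anticodon_offset must leave room for residues 34-37")
        for t, s in ((self.pi_precursor, "precursor"), (self.pi_processed, "processed")):
            vals = t.values() if isinstance(t, Mapping) else [t]
            for v in vals:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"pi_{s} values must lie in [0,1]")

    def pi(self, type_key: str, stage: str) -> float:
        """Editing probability at residue 34 for a type in a given stage."""
        table = self.pi_precursor if stage == "precursor" else self.pi_processed
        if isinstance(table, Mapping):
            return float(table.get(type_key, 0.0))
        return float(table)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pos37_types"] = list(self.pos37_types)
        return d


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def build_genome(
    config: SimConfig,
    outdir: str | Path,
    seed: int | None = None,
) -> tuple[Path, Path]:
    """Write a synthetic genome FASTA and matching gene table.

    One chromosome per type group; copies of a type carry an identical
    mature sequence (so mature-body reads multi-map within the type) in
    copy-specific random flanking context.  The second copy of each type is
    placed on the minus strand to exercise strand arithmetic.  With
    ``ambiguous_pair`` an extra chromosome holds two genes of *different*
    type key but identical mature sequence.

    Returns ``(fasta_path, table_path)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pad = max(120, config.flank_len + 20)
    off = config.anticodon_offset
    L = config.mature_len

    def _mature_for(anticodon: str) -> str:
        seq = list(_random_seq(rng, L))
        seq[off:off + 3] = anticodon
        seq[off + 3] = "A"  # residue 37 encoded A in all synthetic types
        return "".join(seq)

    chroms: list[tuple[str, str]] = []
    rows: list[str] = []
    type_keys = list(ANN_TYPES[: config.n_types])
    for type_key in type_keys:
        anticodon = type_key.split("-")[1]
        mature = _mature_for(anticodon)
        chrom = f"chr_{type_key}"
        parts: list[str] = []
        cursor = 0
        for j in range(config.copies_per_type):
            strand = "-" if j == 1 else "+"
            parts.append(_random_seq(rng, pad))
            cursor += pad
            start, end = cursor, cursor + L
            parts.append(revcomp(mature) if strand == "-" else mature)
            cursor = end
            gene_id = f"{type_key.replace('-', '')}-c{j + 1}"
            rows.append(
                f"{chrom}\t{start}\t{end}\t{gene_id}\t0\t{strand}\t{type_key}\t{off}\t0"
            )
        parts.append(_random_seq(rng, pad))
        chroms.append((chrom, "".join(parts)))

    if config.ambiguous_pair:
        mature = _mature_for(AMBIGUOUS_PAIR_TYPES[0].split("-")[1])
        chrom = "chr_ambpair"
        parts, cursor = [], 0
        for type_key in AMBIGUOUS_PAIR_TYPES:
            parts.append(_random_seq(rng, pad))
            cursor += pad
            start, end = cursor, cursor + L
            parts.append(mature)
            cursor = end
            gene_id = f"{type_key.replace('-', '')}-c1"
            rows.append(f"{chrom}\t{start}\t{end}\t{gene_id}\t0\t+\t{type_key}\t{off}\t0")
        parts.append(_random_seq(rng, pad))
        chroms.append((chrom, "".join(parts)))

    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for name, seq in chroms:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    table_path = outdir / "genes.tsv"
    header = "#chrom\tstart\tend\tgene_id\tscore\tstrand\ttype_key\tanticodon_offset\thas_intron"
    table_path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return fasta_path, table_path


def _sample_span(
    rng: np.random.Generator, config: SimConfig, stage: str
) -> tuple[int, int]:
    """Draw a sense-local read span [start, end) for one read.

    Processed spans lie inside [0, L); precursor spans include at least one
    leader or trailer nucleotide.  The span covers residue 34 with
    probability ``p_cover_anticodon`` (lengths are stretched or trimmed when
    a draw cannot otherwise satisfy the cover/miss outcome).
    """
    L, a = config.mature_len, config.anticodon_offset
    cover = rng.random() < config.p_cover_anticodon
    flen = int(rng.integers(config.frag_len_min, config.frag_len_max + 1))
    if stage == "processed":
        flen = min(flen, L)
        if cover:
            lo, hi = max(0, a - flen + 1), min(a, L - flen)
            if lo > hi:  # fragment too short to be placeable; stretch to cover
                flen = min(L, a + 1)
                lo, hi = max(0, a - flen + 1), min(a, L - flen)
            start = int(rng.integers(lo, hi + 1))
        else:
            choices = []
            if a - flen >= 0:
                choices.append(("left", 0, a - flen))
            if a + 1 <= L - flen:
                choices.append(("right", a + 1, L - flen))
            if not choices:  # cannot miss with this length: shorten upstream
                flen = min(flen, a)
                choices = [("left", 0, a - flen)]
            _, lo, hi = choices[int(rng.integers(len(choices)))]
            start = int(rng.integers(lo, hi + 1))
        return start, start + flen

    ext = int(rng.integers(1, config.max_flank_ext + 1))
    if rng.random() < 0.5:  # extends into the 5'-leader
        start = -ext
        flen = max(flen, ext + a + 1) if cover else min(flen, ext + a)
        end = min(start + flen, L)
        return start, end
    end = L + ext  # extends into the 3'-trailer
    flen = max(flen, ext + (L - a)) if cover else min(flen, ext + L - a - 1)
    start = max(end - flen, 0)
    return start, end


def _draw_base37(rng: np.random.Generator, config: SimConfig, stage: str) -> str:
    if stage == "precursor":
        p_g, p_t = config.p37_G_precursor, config.p37_T_precursor
    else:
        p_g, p_t = config.p37_G_processed, config.p37_T_processed
    u = rng.random()
    if u < p_g:
        return "G"
    if u < p_g + p_t:
        return "T"
    return "A"


def _inject_errors(rng: np.random.Generator, seq: list[str], rate: float) -> None:
    if rate <= 0.0:
        return
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        others = [b for b in "ACGT" if b != seq[i]]
        seq[i] = others[int(rng.integers(3))]


def simulate_reads(
    fasta_path: str | Path,
    table_path: str | Path,
    config: SimConfig,
    condition: str = "control",
    outdir: str | Path = ".",
    seed: int | None = None,
    prefix: str | None = None,
) -> tuple[Path, Path, Path]:
    """Simulate reads from a synthetic genome; write FASTQ, truth SAM, truth TSV.

    Per gene copy, the read count is Poisson(``depth_per_copy``).  Each read
    draws a maturation stage, a span (see :func:`_sample_span`), its truth
    bases at residues 34/35/37, and finally per-base substitution noise.
    In the ``knockdown`` condition every editing probability is multiplied
    by ``knockdown_factor``.

    Returns ``(fastq_path, sam_path, truth_tsv_path)``.
    """
    config.validate()
    if condition not in ("control", "knockdown"):
        raise ValueError(f"condition must be 'control' or 'knockdown', got {condition!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix if prefix is not None else condition

    fasta = Fasta(str(fasta_path))
    genes = parse_gene_table(table_path, fasta)
    genes.sort(key=lambda g: (g.chrom, g.mature_start, g.gene_id))
    F = config.flank_len
    ext_seqs = {g.gene_id: sense_sequence(g, fasta, flank=F) for g in genes}
    kappa = config.knockdown_factor if condition == "knockdown" else 1.0

    # cross-type partners: identical mature sequence, different type_key
    mature = {g.gene_id: ext_seqs[g.gene_id][F:F + g.mature_length] for g in genes}
    partner: dict[str, TrnaGene] = {}
    for g in genes:
        for h in genes:
            if h.gene_id != g.gene_id and h.type_key != g.type_key and mature[h.gene_id] == mature[g.gene_id]:
                partner[g.gene_id] = h

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(fasta[name])} for name in fasta.keys()],
    }
    fastq_path = outdir / f"{prefix}.reads.fastq"
    sam_path = outdir / f"{prefix}.truth.sam"
    tsv_path = outdir / f"{prefix}.truth.tsv"
    tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}

    truth_rows: list[str] = []
    counter = 0
    with open(fastq_path, "w") as fq, pysam.AlignmentFile(str(sam_path), "w", header=pysam.AlignmentHeader.from_dict(header)) as sam:
        for g in genes:
            ext = ext_seqs[g.gene_id]
            a_off = g.anticodon_offset
            n_reads = int(rng.poisson(config.depth_per_copy))
            for _ in range(n_reads):
                stage = "precursor" if rng.random() < config.stage_fraction_precursor else "processed"
                s, e = _sample_span(rng, config, stage)
                seq = list(ext[F + s:F + e])
                covers_34 = s <= a_off < e
                covers_35 = s <= a_off + 1 < e
                covers_37 = s <= a_off + 3 < e
                edited = False
                base34 = base35 = base37 = "."
                if covers_34:
                    edited = bool(rng.random() < config.pi(g.type_key, stage) * kappa)
                    base34 = "G" if edited else "A"
                    seq[a_off - s] = base34
                if covers_35:
                    base35 = seq[a_off + 1 - s]
                if covers_37:
                    if g.type_key in config.pos37_types:
                        base37 = _draw_base37(rng, config, stage)
                        seq[a_off + 3 - s] = base37
                    else:
                        base37 = seq[a_off + 3 - s]
                _inject_errors(rng, seq, config.error_rate)
                read_seq = "".join(seq)
                read_id = f"r{counter:07d}"
                counter += 1

                also = ""
                records: list[tuple[TrnaGene, bool]] = [(g, False)]
                if stage == "processed" and g.gene_id in partner:
                    records.append((partner[g.gene_id], True))
                    also = partner[g.gene_id].type_key
                nh = len(records)
                for target, secondary in records:
                    aln = pysam.AlignedSegment(sam.header)
                    aln.query_name = read_id
                    aln.reference_id = tid[target.chrom]
                    if target.strand == "+":
                        aln.reference_start = target.mature_start + s
                        aln.query_sequence = read_seq
                        aln.flag = 256 if secondary else 0
                    else:
                        aln.reference_start = target.mature_end - e
                        aln.query_sequence = revcomp(read_seq)
                        aln.flag = 16 | (256 if secondary else 0)
                    aln.mapping_quality = 1 if nh > 1 else 42
                    aln.cigarstring = f"{e - s}M"
                    aln.set_tag("NH", nh)
                    sam.write(aln)

                fq.write(f"@{read_id}\n{read_seq}\n+\n{'I' * len(read_seq)}\n")
                truth_rows.append(
                    "\t".join(
                        [
                            read_id, condition, g.gene_id, g.type_key, stage,
                            str(s), str(e),
                            str(int(covers_34)), str(int(covers_35)), str(int(covers_37)),
                            str(int(edited)), base34, base35, base37, also,
                        ]
                    )
                )
    tsv_path.write_text("\t".join(TRUTH_COLUMNS) + "\n" + "".join(r + "\n" for r in truth_rows))
    return fastq_path, sam_path, tsv_path


def load_truth(tsv_path: str | Path) -> pd.DataFrame:
    """Load a truth TSV, validating its schema row count."""
    df = pd.read_csv(
        tsv_path, sep="\t", dtype={"base34": str, "base35": str, "base37": str, "also_maps_to": str},
        keep_default_na=False,
    )
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"truth table missing columns: {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.stage not in ("precursor", "processed"):
            raise ValueError(f"truth row {i}: bad stage {row.stage!r}")
    return df


def truth_summary(truth: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Exact pre-error base counts by (type, stage, condition, residue).

    Counts the emitted base at residues 34, 35 and 37 for every read that
    covers the residue, excluding reads whose truth lists a second tRNA
    type (cross-type ambiguous reads never enter any pipeline count).
    Returns a long table with columns
    ``type_key, stage, condition, residue, base, count``.
    """
    df = truth if isinstance(truth, pd.DataFrame) else load_truth(truth)
    if df.empty:
        return pd.DataFrame(columns=["type_key", "stage", "condition", "residue", "base", "count"])
    df = df[df["also_maps_to"] == ""]
    pieces = []
    for residue, covcol, bcol in ((34, "covers_34", "base34"), (35, "covers_35", "base35"), (37, "covers_37", "base37")):
        sub = df[df[covcol] == 1]
        if sub.empty:
            continue
        counts = (
            sub.groupby(["type_key", "stage", "condition", bcol]).size().reset_index(name="count")
        )
        counts = counts.rename(columns={bcol: "base"})
        counts.insert(3, "residue", residue)
        pieces.append(counts)
    if not pieces:
        return pd.DataFrame(columns=["type_key", "stage", "condition", "residue", "base", "count"])
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["type_key", "stage", "condition", "residue", "base"]).reset_index(drop=True)
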