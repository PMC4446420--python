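"""In-silico counterparts of two biochemical inosine readouts.

Sanger readout: sequencing a deaminated pre-tRNA reads each inosine as a
clean G where the template encoded A, and the untreated transcript reads
the expected A — the chromatogram-level evidence that A34 was converted
to I34.

Endonuclease V (EndoV) digestion: EndoV cleaves at the second
phosphodiester bond 3' of an inosine, so the 5' product extends one
nucleotide past the inosine.  For a pre-tRNA with a 6-nt leader, a 76-nt
mature body carrying inosine at residue 34, and a 13-nt trailer
(95 nt total), digestion yields a 41-nt 5' arm and a 54-nt 3' arm; the
leader/trailer lengths of this canonical construct are back-derived from
that fragment arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: 5' product ends this many nucleotides after the inosine (second
#: phosphodiester bond 3' of the inosine).
ENDOV_CUT_OFFSET = 1


@dataclass(frozen=True)
class PreTrnaConstruct:
    """An in-vitro pre-tRNA: leader + mature + trailer, with inosine sites.

    ``inosine_mature_positions`` are 1-based residue indices within the
    mature sequence (residue 34 = index 34); each must index an A in the
    pre-deamination transcript.
    """

    leader_seq: str
    mature_seq: str
    trailer_seq: str
    inosine_mature_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for p in self.inosine_mature_positions:
            if not 1 <= p <= len(self.mature_seq):
                raise ValueError(f"inosine position {p} outside mature sequence")
            if self.mature_seq[p - 1].upper() != "A":
                raise ValueError(
                    f"inosine position {p} is {self.mature_seq[p - 1]!r}, not A"
                )

    @property
    def total_length(self) -> int:
        return len(self.leader_seq) + len(self.mature_seq) + len(self.trailer_seq)

    @property
    def full_sequence(self) -> str:
        return self.leader_seq + self.mature_seq + self.trailer_seq


@dataclass(frozen=True)
class CleavageResult:
    """EndoV digestion products, 5' to 3'."""

    fragment_lengths: tuple[int, ...]

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


def predict_sanger_readout(construct: PreTrnaConstruct, deaminated: bool) -> str:
    """Predicted full-length Sanger read of the construct.

    Deamination converts every marked A to inosine, which base-pairs like G
    and is read as G; without deamination the transcript reads back
    unchanged.
    """
    if not deaminated:
        return construct.full_sequence
    seq = list(construct.full_sequence)
    offset = len(construct.leader_seq)
    for p in construct.inosine_mature_positions:
        seq[offset + p - 1] = "G"
    return "".join(seq)


def endov_cleave(construct: PreTrnaConstruct, cut_offset: int = ENDOV_CUT_OFFSET) -> CleavageResult:
    """Fragment lengths after complete EndoV digestion, one cut per inosine.

    Each cut falls ``cut_offset`` nucleotides 3' of an inosine (default:
    the second phosphodiester bond, i.e. the 5' product ends one nucleotide
    after the inosine).  With no inosine the construct stays intact.
    Fragment lengths always sum to the construct length.
    """
    total = construct.total_length
    leader = len(construct.leader_seq)
    cuts = sorted(
        {
            min(leader + p + cut_offset, total)
            for p in construct.inosine_mature_positions
        }
    )
    cuts = [c for c in cuts if 0 < c < total]
    bounds = [0] + cuts + [total]
    return CleavageResult(tuple(b - a for a, b in zip(bounds, bounds[1:])))


def canonical_valine_construct() -> PreTrnaConstruct:
    """Synthetic stand-in for the in-vitro pre-tRNA-Val(AAC) construct.

    Length arithmetic (6-nt leader, 76-nt mature with A34 in an AAC
    anticodon, 13-nt trailer; 95 nt total) matches the canonical in-vitro
    construct; the sequence outside the anticodon is synthetic filler, so
    only length-level predictions are meaningful.
    """
    mature = list("GC" * 38)
    mature[33:36] = "AAC"  # residues 34-36
    return PreTrnaConstruct(
        leader_seq="GGGCGC",
        mature_seq="".join(mature),
        trailer_seq="GCGCGCGCGCGCG",
        inosine_mature_positions=frozenset({34}),
    )
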