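"""In-silico versions of the two biochemical inosine readouts.

Sanger readout: a deaminated pre-tRNA reads G where the template encoded
A34 (inosine pairs like G); the untreated transcript reads A.  EndoV
digestion: cleavage at the second phosphodiester bond 3' of the inosine
splits the 95-nt construct (6-nt leader + 76-nt mature + 13-nt trailer)
into a 41-nt 5' arm and a 54-nt 3' arm — the fragment sizes that confirm
the G seen by sequencing really is an inosine.
"""

from inoseq import (
    PreTrnaConstruct,
    canonical_valine_construct,
    endov_cleave,
    predict_sanger_readout,
)

construct = canonical_valine_construct()
pos34 = len(construct.leader_seq) + 33  # 0-based index of residue 34

untreated = predict_sanger_readout(construct, deaminated=False)
treated = predict_sanger_readout(construct, deaminated=True)
print(f"construct: {construct.total_length} nt "
      f"({len(construct.leader_seq)} leader + {len(construct.mature_seq)} mature "
      f"+ {len(construct.trailer_seq)} trailer)")
print(f"Sanger readout at residue 34: untreated={untreated[pos34]} "
      f"deaminated={treated[pos34]}")

result = endov_cleave(construct)
print(f"EndoV fragments (5'->3'): {result.fragment_lengths} nt "
      f"(sum {sum(result.fragment_lengths)})")
intact = PreTrnaConstruct(
    construct.leader_seq, construct.mature_seq, construct.trailer_seq, frozenset()
)
print("no inosine -> single full-length fragment:", endov_cleave(intact).fragment_lengths)
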