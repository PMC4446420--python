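"""Negative controls: residue 35 and the background A->G mismatch profile.

Residue 35 is never deaminated, so its A->G proportion (on types that
encode A35) should sit at the sequencing-error-implied rate eps/3 / (1 -
2*eps/3), not at the editing level.  Likewise, every other reference-A
position in the mature body provides a per-position background estimate;
residue 34 should tower above all of them.  These are the checks that
separate a real editing signal from sequencing noise.
"""

import tempfile
from pathlib import Path

from inoseq import SimConfig, analyze, simulate_study
from inoseq.pileup import background_mismatch_profile, background_summary

workdir = Path(tempfile.mkdtemp(prefix="inoseq_example_"))
eps = 0.005
config = SimConfig(error_rate=eps, depth_per_copy=800, seed=13)
simulate_study(config, workdir, conditions=("control",), seed=13)
result = analyze(workdir / "genes.tsv", workdir / "genome.fa", workdir / "control.truth.sam")

implied = (eps / 3) / (1 - eps + eps / 3)
print(f"error-implied A->G rate: {implied:.4f}")

w = result.params.window
for key in ("Val-AAC", "Ile-AAT"):  # both encode A at residue 35
    mat = result.type_pileups[(key, "processed")]
    n_a, n_g = mat.count(1, "A"), mat.count(1, "G")
    print(f"{key} residue 35: G/(A+G) = {n_g / (n_a + n_g):.4f}  (n={n_a + n_g})")
    prof = background_mismatch_profile(mat, result.window_refs[key])
    summ = background_summary(prof)
    signal = prof.loc[prof["is_34"], "ag_proportion"].iloc[0]
    print(f"{key} background A->G: mean={summ['mean']:.4f} max={summ['max']:.4f} "
          f"vs residue-34 signal {signal:.3f}")
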