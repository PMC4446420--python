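import textwrap
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def write_fasta(path: Path, chroms: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return path


def write_gene_table(path: Path, rows: list[tuple]) -> Path:
    """rows: (chrom, start, end, gene_id, strand, type_key, offset, has_intron)"""
    lines = ["#chrom\tstart\tend\tgene_id\tscore\tstrand\ttype_key\tanticodon_offset\thas_intron"]
    for chrom, start, end, gid, strand, key, off, intron in rows:
        lines.append(f"{chrom}\t{start}\t{end}\t{gid}\t0\t{strand}\t{key}\t{off}\t{int(intron)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_sam(path: Path, chrom_lengths: dict[str, int], records: list[tuple]) -> Path:
    """records: (read_id, flag, chrom, pos0, cigar, seq)."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for rid, flag, chrom, pos0, cigar, seq in records:
        lines.append(
            f"{rid}\t{flag}\t{chrom}\t{pos0 + 1}\t42\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small error-free simulated study with a cross-type-ambiguous pair."""
    from inoseq.pipeline import simulate_study
    from inoseq.simulate import SimConfig

    outdir = tmp_path_factory.mktemp("small_study")
    config = SimConfig(
        error_rate=0.0, depth_per_copy=120, ambiguous_pair=True, seed=11
    )
    manifest = simulate_study(config, outdir, conditions=("control",), seed=11)
    return {"dir": outdir, "config": config, "manifest": manifest}
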