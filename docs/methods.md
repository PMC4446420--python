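# Methods

## Detection model

Inosine pairs like guanosine, so a sequencer reads I as G. At a genomically
encoded A34 the per-type editing level is estimated by the A/G mismatch
proportion `f = n_G / (n_A + n_G)` over all counted read bases at the
residue-34 genomic position. C and T calls at the position are reported but
excluded from `f`: at an A reference they are sequencing error, not an
editing readout. The model treats read bases as independent Bernoulli
draws; there is no per-molecule correlation structure and no base-quality
weighting (a minimum base-quality flag exists in the data model but is off
by default, matching raw base-calling practice).

Reads are usable only if they resolve to a single tRNA type. Because a
type's genomic copies are near-identical, a read may align to several
copies of one type — that is fine and the read is counted **once**, at its
primary alignment (copies share the mature sequence, so type-level
composition does not depend on which copy is chosen; a
`count_per_alignment` flag restores per-copy counting for depth-style
analyses). A read whose alignments touch the gene windows of two or more
types is discarded outright; a read touching none is unassigned. This makes
read accounting an exact partition: every input read lands in exactly one
of {counted, ambiguous, unassigned}.

Stage classification: a counted read is **precursor** if at least one
aligned base (soft-clips excluded) falls in the 5′-leader or 3′-trailer
window, **processed** if its aligned span lies entirely within the mature
coordinates. A read overlapping only a flank window is classified
precursor: it contains leader/trailer sequence by construction. Internal
fragments and full-length-like reads are one processed class; the
assignment table carries a span-length column for downstream splitting.

Gene copies with read depth < 10 at the residue-34 position (pooled over
stages) are removed before type-level aggregation; aggregation is an
element-wise sum of per-copy pileup matrices and is associative, so
copy-then-replicate and replicate-then-copy orders agree exactly.

## Statistics

Per-type contrasts (precursor vs processed; control vs knockdown) use the
two-sided Fisher exact test on the 2×2 A/G table, delegated to
`scipy.stats.fisher_exact`; two-sidedness sums hypergeometric probabilities
≤ the observed table's, with the conventional ~1e-7 relative tie
tolerance. Two-sided is the default because both directions are
scientifically meaningful (maturation increases editing, knockdown reduces
it); `alternative=` switches to one-sided.

Benjamini–Hochberg adjustment is implemented directly as the step-up rule
`q_(i) = min_{j≥i} p_(j)·m/j` capped at 1, with missing p-values
propagating as missing and excluded from the family size m. One numerical
note: in IEEE arithmetic `p·m/j` at `j = m` can round one ulp below `p`,
so the implementation clamps each q to at least its p — a no-op in exact
arithmetic that preserves the procedure's q ≥ p guarantee bit-for-bit.
The family is the set of types in one comparison (the eight ANN types),
not all window positions. Condition comparisons pool A/G counts over both
stages by default (stage-restricted comparisons are available); replicate
counts are pooled before testing, with per-replicate tables available
upstream. Wilson intervals on editing fractions are provided as a
convenience only.

Between-type comparisons of editing *levels* are deliberately not emitted
as a ranked table: small-RNA library preparation biases coverage per type
(structure, CCA/amino-acylation, modification-dependent RT behaviour), so
cross-type level differences are not interpretable with this design.

## Synthetic data generator

The generator emulates the features of the real experiment that the
pipeline's correctness depends on, at desk scale:

| parameter | default | meaning |
|---|---|---|
| `n_types` | 8 | ANN tRNA types (Ala-AGC … Val-AAC) |
| `copies_per_type` | 3 | identical-mature-sequence genomic copies; second copy minus-strand |
| `ambiguous_pair` | off | adds two genes of different type with identical mature sequence |
| `pi_precursor` / `pi_processed` | 0.2 / 0.8 | Bernoulli editing probability at residue 34 per stage |
| `knockdown_factor` | 0.5 | multiplies every editing probability in the knockdown condition |
| `error_rate` | 0.005 | per-base probability of substitution to one of the three other bases, uniformly |
| `depth_per_copy` | 500 | Poisson mean reads per gene copy |
| `stage_fraction_precursor` | 0.7 | precursor share of reads (≈70/30 precursor/processed) |
| `p_cover_anticodon` | 0.8 | probability a read span covers residue 34 |
| `frag_len_min/max` | 25/60 | uniform fragment-length band (stretched/trimmed when a cover/miss outcome forces it) |
| `max_flank_ext` | 15 | maximum leader/trailer overhang of precursor reads (nt) |
| `p37_G/T` (pre, post) | 0.3/0.0, 0.3/0.2 | stepwise residue-37 model on Ala-AGC: I37 reads G, m¹I37 reads T |
| `mature_len` | 76 | canonical tRNA length; residue 34 at 0-based offset 33 |

Mature sequences are random with the anticodon fixed at the annotated
offset and residue 37 encoded A; copies of a type share the mature
sequence in copy-specific random flanking context, so mature-body reads
multi-map within a type while precursor reads anchor to one copy. Error
injection applies after the modification emissions and can corrupt an
edited base. The truth SAM holds one alignment per true origin (plus a
secondary record at the partner gene for cross-type-ambiguous processed
reads), so the pipeline is testable without running an aligner; FASTQ is
emitted for optional end-to-end runs through a real one. All outputs are
byte-deterministic under a fixed (config, condition, seed).

What the simulator does **not** model: ligation bias, RT fall-off at
modified bases, adapter and quality-score realism, size selection, a
realistic fragment-length distribution (the uniform band is a stand-in),
per-molecule editing correlation, and intron-containing genes. Passing
tests on this generator therefore demonstrate the correctness of the
counting, classification and testing machinery under the stated stochastic
model — not robustness to real-library artefacts.

With `error_rate = ε` and substitution uniform over the three other bases,
the implied background A→G proportion is `(ε/3) / (1 − ε + ε/3)`; the
never-modified residue 35 (on A35 types) and all other reference-A
positions of the mature body are used as negative controls against this
rate. Type-level background profiles are restricted to the mature span:
copies share the mature sequence but not flanking genomic context, so a
type-level per-position reference outside it is undefined (gene-level
profiles may use the full window).

## Numerical and design conventions

- Coordinates are 0-based half-open genomic throughout; window positions
  are relative to residue 34 in tRNA sense (0 = 34, +1 = 35, +3 = 37), and
  minus-strand genes contribute complemented sense-oriented bases.
- `anticodon_offset` is explicit annotation input, not inferred from
  secondary structure (offsets vary with D-loop length); a substring-search
  helper derives it from a mature sequence and errors on ambiguity. The
  parser verifies the genomic sense triplet against the type key.
- Intron-containing genes are loaded but excluded from editing analysis by
  default; genomic anticodon coordinates are only valid for unspliced
  transcripts.
- Flank windows default to 50 nt each side, matching the ±50 nt
  base-calling window; both are configurable (window ≥ 3 so residues 34–37
  are reachable).
- Primary-record tie-break: if no alignment is flagged secondary, the
  lexicographically first (chrom, position) record is counted.
- The EndoV cut offset (5′ product ends one nucleotide after the inosine)
  is a named constant, configurable; the canonical 6+76+13 construct's
  41/54 split is pinned as a regression test. The construct's sequence
  outside the anticodon is synthetic filler — only length arithmetic is
  meaningful.
- Degenerate inputs: zero-depth positions and zero-margin contingency
  cells yield missing values (never silent zeros); the all-zero table has
  no p-value; an empty SAM produces empty outputs with a warning, not an
  error.

## Problem sizes

The test suite runs the full chain on 8 types × 3 copies at 500 reads per
copy for exact truth-equality checks (error-free setting), and at 3300
reads per copy with 0.5 % error for stage/knockdown recovery — sized so the
expected number of informative reads per type and stage exceeds 2000, which
gives standard errors around 0.01 on recovered fractions and essentially
certain detection of the simulated 0.2→0.8 stage contrast and ×0.5
knockdown. False-discovery control is checked on 200 simulated null
families of 8 binomial contrasts at n = 2000 per group.

## Known limitations

- Spliced (intron-gapped) alignments are not handled; alignment itself is
  out of scope (the pipeline consumes SAM).
- The editing estimator ignores base quality and assumes error
  contamination is symmetric across bases.
- Stage classification is binary; no attempt is made to distinguish
  5′-leader-only from 3′-trailer-only precursors in counts (the span
  coordinates allow it downstream).
- Editing comparisons assume independent reads; UMI/duplicate structure is
  not modelled.
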