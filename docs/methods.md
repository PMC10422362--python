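# Methods

## The problem

Nanopore basecallers emit FASTQ: every called base carries one printable ASCII
quality symbol (line 4 of each record) encoding the estimated probability that
the base was reconstructed correctly. Different basecallers derive that
estimate differently, over different symbol ranges, and with very different
fidelity. `qualstrat` evaluates those symbols: it groups every read base by its
quality symbol and compares the symbol's *implied* error probability against
the *empirically observed* alignment outcome, and it tests whether downstream
tools react to the symbols at all.

## Quality-score models

Symbols use the Sanger convention: character ordinal = Q + 33, error
probability = 10^(−Q/10), so `'!'` is Q=0 (error probability 1) and `'?'` is
Q=30 (error probability 10⁻³). Two published score families are implemented:

* **Likelihood-ratio score** (CTC-style basecallers such as Chiron and
  Causalcall): `qs = 10·log10(P1/P2)`, with P1 and P2 the probabilities of the
  most and second-most likely nucleotide. The score is scale-free (depends
  only on the ratio) and zero when the two candidates tie — which is why it
  measures *discriminability*, not the probability of being correct.
* **Scaled Phred score** (Flappie, Nanonet): `qs = −10·(y·log10(1−p) +
  log10(x))`, with `p` the probability of the most likely nucleotide and
  `(x, y)` tool-internal scaling coefficients. Six built-in coefficient sets
  cover Flappie (x=y=1, i.e. the plain Phred transform) and the five Nanonet
  read categories; template reads switch row at p = 0.1, with the boundary
  value assigned to the "p ≤ 0.1" row, exactly as the row labels read.

Scores are returned unrounded; `round_clamp_phred` separately rounds half-up
and clamps to [0, 93] for symbol emission, because the basecallers do not
document their own rounding.

A known oddity of the source material: the symbol `'5'` (Q=20) is sometimes
described as implying a correct-reconstruction probability of 0.994, while
Phred+33 arithmetic gives 1 − 10⁻² = 0.99. This package follows standard
Phred+33 throughout.

## Repeat masking

Repeat *discovery* is out of scope; the package consumes BED3 intervals (as
emitted by RepeatMasker-class tools) and hard-masks them: every base in the
merged interval union becomes uppercase `'N'`, sequence lengths are preserved,
and the report counts masked bp per sequence and in total. Percentages are
rounded half-up to two decimals, the convention of printed report tables.
Bases that were `'N'` before masking count as masked output but are also
reported separately (`premasked_bp`), since published bp counts rarely state
how pre-masked bases were treated. Intervals extending past a sequence end
are clipped with a warning; intervals naming an unknown sequence are an
error. Masking is idempotent byte-for-byte.

## Stratified evaluation

The central computation walks each primary alignment's CIGAR and assigns every
read base exactly one outcome:

| CIGAR | outcome |
|-------|---------|
| `=`   | matched |
| `X`   | mismatched |
| `M`   | matched/mismatched, resolved via MD tag or reference |
| `I`   | inserted |
| `S`, `H` | clipped |
| `D`, `N` | (no read base; deletions tallied separately) |

Design choices, where the convention was genuinely open:

* **`M` resolution.** If the mapper was not run with `--eqx`, match vs
  mismatch is resolved through the MD tag; failing that, through a supplied
  reference FASTA; with neither, the run aborts rather than guess. A column
  whose reference base is `'N'` counts as mismatched.
* **Primary alignments only.** Secondary (flag 256) and supplementary (flag
  2048) records are skipped so that each read base is counted exactly once —
  this is what makes the conservation identity (below) exact.
* **Deletions** have no read quality symbol, so they are excluded from the
  per-symbol panels and accumulated as a single `deletions_total` used only in
  the read-set summary's deletion percentage.
* **Clips.** Soft-clipped bases are counted as clipped, not as mapped, in the
  per-symbol mapped fraction: `mapped_fraction = (matched + mismatched +
  inserted) / total_in_fastq`. Aligned-base semantics keep the expected
  monotone increase of the mapped fraction with Q meaningful. Hard-clipped
  bases are recovered from the original FASTQ by read id.
* **Reverse strand.** SAM stores SEQ/QUAL reverse-complemented; classification
  walks the stored orientation and maps positions back to read coordinates,
  so per-symbol tallies are strand-invariant.
* **Summary percentages.** `mapped_pct` = aligned query bases over all FASTQ
  bases. The match/substitution/deletion/insertion percentages share the
  alignment-column denominator (matched + mismatched + inserted + deleted),
  so they sum to 100. Other toolchains use slightly different denominators;
  real-data numbers can differ by fractions of a percent. All percentages are
  reported half-up to two decimals.

Conservation invariant, checked on every run: per symbol,
`matched + mismatched + inserted + clipped = bases of that symbol in reads
that have a primary alignment`, exactly.

## Synthetic data

No public dataset is needed for testing: the simulator generates a uniform
random reference (configurable GC) and reads whose statistical structure is
the one the analysis assumes.

* **Symbol profile.** Each emitted base draws its quality symbol from a
  configurable distribution. The default profile is uniform over Q = 5..30
  (26 symbols), chosen to span the quality range real basecallers emit while
  giving every symbol enough bases for per-symbol statistics at moderate read
  counts.
* **Calibration.** A base with symbol of Phred value Q is substituted with
  probability `miscalibration_factor × 10^(−Q/10)`; insertion and deletion
  rates default to 0.5 × the substitution rate each, mimicking the
  indel-heavy nanopore error profile. With `miscalibration_factor = 1` the
  simulated reads are perfectly calibrated; other factors give a known
  ground-truth miscalibration that the pipeline must recover.
* **Deletions** are applied at the profile-averaged deletion rate rather than
  per drawn symbol: a deleted base carries no symbol, and conditioning the
  deletion decision on a drawn-then-discarded symbol would bias the emitted
  symbol distribution away from the profile.
* **Clip flanks.** Uniform random sequence of geometric length (default mean
  30 bp per end) is appended to both read ends and labelled clipped — the
  flanks exercise the clipped category deterministically through truth labels
  rather than through a real mapper's behaviour.
* **Truth.** Every read carries a `TruthAlignment` with per-base outcome
  labels and an `=`/`X`-resolved CIGAR; `emit_truth_sam` writes them as a
  valid SAM (correct flags, 1-based positions, reverse-complemented SEQ and
  reversed QUAL on the minus strand). Stratifying that SAM must reproduce the
  truth counts with zero tolerance — the pipeline's strongest self-check.
* Errors are i.i.d. per base given the symbol: no homopolymer, k-mer context,
  or signal-level effects. Passing tests therefore validate the accounting
  machinery and the calibration statistics, not any claim about how real
  nanopore error processes behave; real reads have context-dependent,
  bursty errors the simulator deliberately omits.
* A single seeded generator (`numpy.random.default_rng`) governs all
  randomness; fixed seeds give byte-identical outputs.

## Invariance harness

From one FASTQ, three inputs with identical ids and sequences are derived:
the original (`real`), a copy with every quality symbol replaced by `'?'`
(`fake`), and a FASTA with quality removed (`none`). An arbitrary downstream
command template (`{input}`, optional `{output}`) runs once per variant and
outputs are compared pairwise — byte-level or record-level (FASTA records,
VCF ignoring `##` meta lines, SAM ignoring `@PG`, TSV ignoring `#`
comments). If all three agree, the tool demonstrably ignores per-base
quality. Verdicts are meaningful only for deterministic commands; pass a
fixed seed through the template where the tool supports one. Two built-in toy
commands (a read counter and a quality-ordinal summer) exercise both verdict
directions without any external tool.

## Pipeline

`run_pipeline` chains masking (optional), mapping (either a pre-computed SAM
or an external mapper command template — tests use truth SAMs so no aligner
binary is required) and the stratified analysis, writing TSVs
(`.stratified.tsv`, `.summary.tsv`, `.distribution.tsv`, plus masking
outputs) with a `#`-prefixed provenance header carrying the tool version and
a hash of the input-determining configuration. Re-running identical inputs
yields byte-identical files.

## Problem sizes and numerical choices

The test suite and the acceptance script use simulations of 200–2,000 reads
of ~0.6–1 kb over 20–80 kb references — large enough that every default
symbol has well over 500 aligned bases (the threshold below which per-symbol
binomial checks are skipped), small enough to run comfortably on one CPU.
Statistical checks use 3 binomial/multinomial standard deviations around the
generator's true rates. Exact checks (oracle equivalence, conservation,
round-trips, masking idempotence) use zero tolerance. The miscalibration
recovery experiment uses symbols Q = 10..30 because a factor of 3 at Q = 5
would push per-base rate sums past 1, which the error model rejects as
invalid.

## Known limitations

* Real-data summary percentages depend on the mapper and its settings; only
  the accounting conventions above are guaranteed.
* The likelihood-ratio and scaled-score formulas are implemented as published;
  closed-source basecallers' scoring is not reproduced.
* The simulator is symbol-marginal (no context effects) and its clip flanks
  are random sequence, unalignable by construction — a real mapper's clipping
  behaviour is not modelled.
* BAM/CRAM are not part of the contract (text SAM is); use `samtools view`
  to convert if needed.
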