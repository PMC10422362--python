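# qualstrat

Per-quality-symbol evaluation of nanopore basecalled reads.

Nanopore basecallers emit FASTQ files in which every called base carries a
quality symbol — a printable ASCII character on the record's fourth line
encoding the estimated probability (Phred convention, Q = ordinal − 33,
error probability 10^(−Q/10)) that the base was reconstructed correctly.
Whether those estimates mean anything is an empirical question. `qualstrat`
answers it for a given read set by:

* implementing the published basecaller scoring formulas — the
  likelihood-ratio score `qs = 10·log10(P1/P2)` (Chiron/Causalcall-style) and
  the scaled Phred score `qs = −10·(y·log10(1−p) + log10(x))`
  (Flappie/Nanonet-style) with the six published `(x, y)` coefficient sets;
* hard-masking repeat intervals of a reference to `'N'` (with bp accounting)
  so repeats do not attract spurious alignments;
* walking each alignment's CIGAR against the read's quality string and
  tallying, **per quality symbol**, how many bases were matched, mismatched,
  inserted or clipped — so the empirical error rate of each symbol can be
  compared with its theoretical `10^(−Q/10)`;
* running an arbitrary downstream tool on three inputs identical except for
  quality (real symbols / constant `'?'` / none) and comparing outputs, to
  detect whether the tool uses quality information at all;
* simulating quality-aware long reads with ground-truth alignments, so the
  whole pipeline is testable offline with zero tolerance.

Intended for people evaluating or developing basecallers, read simulators
and quality-aware downstream tools. See `docs/methods.md` for the model
conventions and their rationale.

## Worked example

Simulate 300 reads (~1 kb) with perfectly calibrated errors over symbols
Q=5..30, then run the pipeline on the emitted truth SAM:

```sh
qualstrat simulate --ref-length 50000 --n-reads 300 --seed 42 --out-prefix demo
qualstrat run --fastq demo.reads.fastq --sam demo.truth.sam \
              --ref demo.ref.fasta --out-prefix demo_run
```

`demo_run.stratified.tsv` (abridged):

```
symbol  phred  total_in_fastq  matched  mismatched  inserted  clipped  mapped_fraction  empirical_error_rate  theoretical_error_rate
&       5      12373           7809     3530        324       710      0.9426           0.3113                0.3162
+       10     12269           10077    1168        323       701      0.9429           0.1039                0.1
7       22     12362           11264    73          359       666      0.9461           0.0064                0.0063
?       30     12336           11295    7           336       698      0.9434           0.0006                0.001
```

Each row is one quality symbol: how many bases carried it, how they fared in
the alignment, and the empirical versus theoretical error rate. On calibrated
input the two columns agree to within sampling noise — exactly what the table
is designed to reveal (or refute) on real basecaller output.

`demo_run.summary.tsv` gives the read-set totals (the four error percentages
share the alignment-column denominator and sum to 100):

```
n_reads  sum_bp  mapped_pct  match_pct  sub_pct  del_pct  ins_pct
300      321411  94.37       88.79      5.57     2.8      2.83
```

Score formulas directly:

```sh
$ qualstrat qscore --model nanonet-template --p 0.5
14.6927
$ qualstrat qscore --model chiron --p 0.999 --p2 0.000333
34.7712
```

Does a downstream tool use quality? Run it on the three variants:

```sh
qualstrat invariance --fastq demo.reads.fastq --workdir inv \
    --cmd 'python -m qualstrat.toycmds count-reads {input}' --comparator tsv
# real vs fake: identical / real vs none: identical / fake vs none: identical
# overall invariant: True
```

Other subcommands: `mask`, `fakeq`, `tofasta`, `dist`, `stratify`,
`summary` — see `qualstrat --help`.

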