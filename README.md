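# npbss

A simulator for PacBio continuous long reads (CLR) with a quality-value
driven empirical error model, plus an evaluation toolkit that measures the
simulator's own fidelity.

Developers of long-read assemblers, aligners and variant callers need
simulated reads with known ground truth.  For PacBio CLR data that means
reproducing two coupled properties of the raw reads: heavy-tailed,
log-normal read lengths, and a ~15% per-base error rate whose magnitude
tracks each base's Phred quality value (QV).  `npbss` samples read lengths
from

```
ln X ~ N(mu, sigma)          (length model)
```

assigns each base a QV drawn from an empirical proportion table, converts
QV to a per-base error probability with the empirical model

```
P_error(q) = 0.3942 * 10^(-q/10) + 0.0041
```

(the Phred-theoretical `P_th(q) = 10^(-q/10)` is also available), rescales
it so the genome-wide average matches the requested substitution/insertion/
deletion targets (defaults 6% / 3% / 6%), and splits it per base in that
ratio.  Output is a Phred+33 FASTQ of simulated reads, a FASTA of the
error-free templates ("truth" reads), and optionally a tab-separated
sidecar with every injected edit event.

See `docs/methods.md` for the model details and design decisions, and
`examples/` for short narrative scripts.

## Worked example

```bash
# make a small test genome (or bring your own FASTA)
python -c "from npbss.synthetic import *; write_genome_fasta(random_genome(1_000_000, seed=42), 'genome.fa')"

npbss genome.fa -n 1,000 -sub 0.06 -ins 0.03 -del 0.06 --seed 1 --events events.tsv
npbss evaluate npbss_simulated.fq reads_correct.fa --events events.tsv
```

The evaluate step prints (numbers from this exact run):

```
 match_rate_pct  insertion_rate_pct  deletion_rate_pct  substitution_rate_pct  total_error_rate_pct  mean_length_bp  n_reads
      85.004111            2.986757           6.004555               6.004577             14.995889          8614.8     1000
```

Reading it: the injected error rates recover the configured 6/3/6% targets
(total ~15%) to within Monte-Carlo noise, over reads averaging ~8.6 kb
(the default length target is 8500 bp).  Rates are percentages of aligned
columns — matches + substitutions + insertions + deletions — so the four
rate columns sum to 100.  Without `--events`, the same command re-measures
the rates independently by global alignment of each read against its truth
record; an optimal aligner compresses a ~15%-error edit script by about one
percentage point, so expect slightly lower totals on that path (see
`docs/methods.md`).

The same pipeline is available as a library:

```python
from npbss import CountSpec, simulate, summarize_rates
from npbss.synthetic import random_genome

refs = random_genome(1_000_000, seed=42)
reads = list(simulate(refs, CountSpec(mode="explicit_n", n=1000, mean_len=8500), seed=1))
print(summarize_rates(reads))
```

Other modes: `-dep 50` simulates to 50x depth; `-lg mu sigma` sets the
log-normal parameters directly (natural-log scale); `-samp reads.fq` fits
the length model to an existing read set; `-qv table.txt` replaces the
bundled QV table; `--ccs --ccs-template ccs.fq` switches to the
resampling-based high-accuracy CCS mode.

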