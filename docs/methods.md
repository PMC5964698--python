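# Methods

## Scope and model overview

`npbss` simulates PacBio continuous long reads (CLR) from a reference
genome.  CLR data have two defining statistical features: heavy-tailed,
roughly log-normal read lengths, and a raw per-base error rate of ~15%
whose magnitude tracks the base's Phred quality value (QV).  The simulator
reproduces both, and records the exact edit script of every read so that
its own fidelity can be measured without alignment.

A read is generated in four stages:

1. **Length.** The final read length X is drawn from a log-normal law,
   ln X ~ N(μ, σ), rounded to an integer and rejection-bounded to
   [min_len, max_len].
2. **Origin.** A reference record is chosen with probability proportional
   to its length (among records long enough to host the read); the start is
   uniform over valid positions and the strand uniform over {+,−}.
3. **Per-base QV.** Each step of the template walk draws an integer QV
   i.i.d. from a discrete proportion table.
4. **Error injection.** The QV is converted to a total per-base error
   probability, split into substitution/insertion/deletion parts, and one
   of four events is drawn per step: match or substitution (emit one base,
   consume one template base), insertion (emit without consuming; the
   inserted base precedes the current template base), deletion (consume
   without emitting).  Emission stops when the read reaches its target
   length.

## QV → error probability

Two models are implemented:

- theoretical (the Phred definition): `P_th(q) = 10^(-q/10)`;
- empirical CLR model: `P_error(q) = a·10^(-q/10) + b`, defaults
  `a = 0.3942`, `b = 0.0041`.

The empirical model reflects that raw CLR base calls are somewhat more
accurate than their nominal QV at low QV, while never becoming error-free:
`P_error` sits below `P_th` throughout the QV range seen in raw CLR data
and levels off at the floor `b` as QV grows.  The coefficients are
configuration, not constants (`--model-a/--model-b`), because they were
fitted on one instrument generation and other chemistries may differ.

### Calibration

Users state target *average* rates per error type (defaults: substitution
0.06, insertion 0.03, deletion 0.06; total 0.15).  The QV table and the
empirical model jointly imply an average error probability
`Σ_q p(q)·P_error(q)` that will generally differ from the requested total,
so a single multiplicative factor `s = total / Σ_q p(q)·P_error(q)` is
applied to the model output.  This preserves the *shape* of the
error-vs-QV relationship (the empirical model's central feature) while
honouring the requested averages exactly in expectation.  Scaled per-base
probabilities are clamped at 0.999 (a probability of 1 would make
generation degenerate); clamping is logged and, with the shipped table and
default targets, never triggers.

### Error-type split

The supplementary equations defining the original tool's per-type split
are not public; this package splits each base's total error probability
proportionally to the configured rates
(`p_sub = p_error·sub/(sub+ins+del)`, etc.).  This is the unique split that
conserves `p_error` per base exactly and yields genome-average rates in the
configured ratio, and it is a deliberate design choice of this package.

## Default QV table

The original instrument-measured QV proportions are not public either.
The bundled default table is therefore a clearly labelled synthetic
stand-in: a discretized Gamma(shape 2, scale 3.2) over QV 0–40, chosen once
so that its table-averaged empirical error probability is ≈ 0.152, i.e.
near the ~15% raw CLR total error rate the default targets imply (the
calibration factor at defaults is ≈ 0.99).  Any two-column `QV proportion`
text file can replace it (`-qv`).  QVs are drawn i.i.d. per base; no
positional autocorrelation is modelled, consistent with the near-uniform
positional error layout of raw CLR data.

## Length model details

- The sampled length is the **final read length** (what a FASTQ consumer
  observes), not the reference span; the consumed template span varies per
  read, ≈ `target_len·(1 + del − ins)` on average, and the template window
  is cut from the reference with 25% slack.  If deletions exhaust a record
  at its end the read is truncated with a warning.
- `-len L` maps to `μ = ln L − σ²/2` so the distribution mean is exactly L;
  the default σ is 0.5, which gives a realistic long right tail, and is
  overridable via `-lg μ σ` (both on the natural-log scale).
- Default bounds: min 50 bp, max 100,000 bp — generous around the ~40 kb
  maximum of real CLR reads; rejection sampling is capped at 1,000 rounds,
  after which stragglers are clamped to the nearer bound with a warning
  (this guarantees termination for degenerate bounds such as
  min = max).
- `-samp FILE` fits (μ, σ) to the observed lengths by maximum likelihood
  (mean and SD of ln length) by default; `--resample-empirical` switches to
  bootstrap resampling of the raw lengths.

## Ground truth and evaluation

Every read records one event per aligned column (match, substitution,
insertion, deletion) together with the QV drawn at that step, forming an
exact edit script: replaying the events reproduces both the read and its
error-free template.  Truth records are written strand-adjusted, so
read-vs-truth comparison needs no reference lookup.

Rates use the aligned-columns denominator (matches + substitutions +
insertions + deletions), so the four percentages sum to 100.  Error-rate
denominators are a classic ambiguity between tools; this convention is
stated everywhere it is used.

`error_rate_by_qv` bins **every aligned column** by the QV drawn at that
step (deletion columns keep the QV that governed their draw).  With this
denominator the observed per-QV error rate is an unbiased estimate of the
calibrated `s·P_error(q)` — the package's reproduction of the error-vs-QV
fidelity curve.  Binning only emitted bases, as one must on real data where
deletions carry no base, gives `(p_sub+p_ins)/(1−p_del)` instead, a
systematically lower value; that variant is provided separately
(`error_rate_by_qv_from_alignment`) for apples-to-apples comparison with
real datasets.

`realign_rates` is the independent oracle: unit-cost global (NW) alignment
of each read against its truth record via edlib, rates from the resulting
edit script.  A known, quantified limitation: an *optimal* aligner
compresses an i.i.d. injected edit script — adjacent insertion+deletion
pairs collapse into one substitution, and chance matches near indels allow
cheaper shifted scripts — so at the default 15% error rate the
alignment-derived total error is ~93% of the injected cost (≈ 14.0% vs
15.0%; at 1.5% injected error the ratio is ≈ 0.99).  The alignment-derived
rate is therefore a guaranteed lower bound that approaches the event-derived
rate as error rates shrink, and heuristic aligners (e.g. BLAST, which does
not produce minimal scripts) land closer to the injected rates than the
optimal aligner does.

## CCS mode

CCS reads are short and highly accurate; their joint (length, quality)
structure is reproduced by resampling donor reads with replacement from a
user-supplied CCS FASTQ.  Each simulated read inherits its donor's length
and per-base QVs, and errors are injected with the *theoretical*
probability `10^(-q/10)` — in the high-accuracy regime nominal QVs are
taken at face value, and the empirical CLR coefficients (fitted on CLR
data only) are deliberately not applied.  Because indels shift the read
relative to its donor, emitted QVs are the donor vector read off step by
step rather than a literal copy; at CCS error rates this perturbs the
per-read mean QV by well under one unit.  The test suite exercises this
module with a synthetic donor set generated by the CLR engine at high QV /
low error, labelled as such.

## Randomness and determinism

All randomness flows from one root seed through
`numpy.random.SeedSequence`: each read gets its own spawned substream, so
output is byte-identical across runs and invariant to emission order, and
the first k reads of an n-read run equal the k-read run at the same seed.
The per-read walk is vectorised in blocks (draw ~15% more steps than bases
still needed, cut at the step where the target emission count or the
template end is reached), which makes a 2,000-read default run a matter of
seconds on one core.

## Problem sizes used in the checks

The bundled verification runs use a 1 Mb synthetic i.i.d. genome with
1,000–2,000 default-parameter reads (≈ 9–18 M aligned columns), which puts
3-sigma Monte-Carlo bands of ±0.02–0.04 percentage points around the
configured rates; length and model-recovery checks use 2,000–10,000 draws.
These sizes make the statistical tolerances sharp while keeping a full run
fast on a laptop.

## Known limitations

- Uniform base composition assumptions: substituted bases are uniform over
  the 3 alternatives, inserted bases uniform over 4; no confusion matrix,
  no homopolymer- or context-dependent error enrichment.
- No chimeric reads, adapters, ZMW loading bias, or polymerase-pass
  modelling; multi-record references are treated as linear (no reads across
  record boundaries, circular genomes not wrapped).
- The synthetic test genomes are i.i.d. uniform A/C/G/T: passing tests
  demonstrate the error *process* is correct, not that downstream tools
  will behave as on real genomes with repeats and skewed composition.
- The shipped QV table is a synthetic stand-in (above); users targeting a
  specific instrument should supply a measured table.
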