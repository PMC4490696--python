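# Methods

## The classification procedure

A positional RNA-seq experiment measures K nested fragment samples whose
region sets grow strictly along the body axis. For transcript *t* and
sample *s* the expression level is

    level(t, s) = log2( count(t, s) / total(s) × scale + pseudo )

with `scale = 100` and `pseudo = 1e-5` by default. The pseudo-count is added
*after* scaling, exactly as in the normalisation this package implements, so
the zero-count floor log2(pseudo) ≈ −16.61 is independent of sequencing
depth. `total(s)` is by default the column sum of the supplied count table;
an explicit per-sample override (e.g. all library-mapped reads rather than
reads mapped to the transcriptome under study) is accepted and must be at
least the column sum. Both denominators are defensible and the choice is
left to the user; results in this package's tests always use column sums,
which are reproducible from the input alone.

Adjacent samples are differenced (later − earlier, so positive means
enriched in the added region) and coded per comparison:
`+` iff diff > θ, `−` iff diff < −θ, else `0`, with θ = 2 log2 units by
default. The inequalities are strict: a difference of exactly 2.00 codes
`0`. θ may be set per comparison, e.g. a laxer threshold at a
contamination-prone cutting level. Raising θ can only move symbols toward
`0` (monotonicity), so the non-differential class grows with θ.

Region calling is a pure function of the code and the design:

* all-zero → non-differential;
* any `−` → other (negative differences are attributed to dilution — see
  below — not to down-regulation or localisation);
* a single `+` at comparison *i* → the region added at *i*;
* `+` at both comparisons of the design's *contamination pair* (and `0`
  elsewhere) → the later comparison's region. In the canonical worm design
  the pair is (B−A, C−B): ovarian tissue abutting the testis→ovary cut can
  leak into fragment B, lifting an ovary transcript's B−A difference over
  threshold, so `[+,+,0]` is pooled with `[0,+,0]` as ovary-region. The
  pattern is honoured *only* for the flagged pair; a generic design without
  one gets only the single-`+` rule;
* everything else → other.

Because the first sample's region (the head) is never an *added* region,
head-specific transcripts are structurally unidentifiable by subtraction:
they show only the dilution staircase, which under the default weights
never exceeds |log2(0.35/0.60)| ≈ 0.78 and hence codes `[0,0,0]`. This is a
property of the experimental design, not of the software.

## The generative simulator

The simulator emulates the experiment, not the sequencer. Each transcript
draws a log-normal baseline abundance (default log-mean 0, log-sd 1).
Uniform transcripts have that baseline in every region. A transcript
specific to region *r* has abundance `baseline × f` in *r* and 0 elsewhere
(leakage 0), or `baseline × λ` outside and `baseline × λ × f` at home when
a leakage level λ > 0 is set; `f` is the enrichment factor (default 2⁶),
the single knob controlling the planted log2 gain.

A fragment's tissue mixture assigns each included region its mass weight
and each contaminating region its ε, then renormalises to sum to one. The
default mass weights (head 0.35, testis 0.25, ovary 0.15, tail 0.25) are a
fixture choice for a worm whose head is the largest region; they affect
only the simulator and diagnostics, never classification, and are freely
overridable. Contamination may only *add* regions absent from the design
set — the modelled scenario is cutting error, e.g. ovary mass in fragment
B.

The expected concentration of transcript *t* in sample *s* is proportional
to Σ_r mixture(s)[r] · a(t, r), normalised over transcripts. Counts are
multinomial at the configured library size (default 5 × 10⁶ reads per
sample), so column sums equal library sizes exactly, mirroring fixed
sequencing depth; optional gamma overdispersion multiplies abundances
before normalisation to mimic biological noise. `noiseless` mode returns
the real-valued expected counts. One seeded generator drives each run;
identical config + seed reproduces the count matrix bit-for-bit, and the
seed is echoed in the provenance sidecar.

Default planting is 5 % of transcripts specific to each of testis, ovary
and tail. Nothing is planted in the head by default because head-specific
transcripts cannot be recovered (above); planting them is still supported
and they are scored as non-recoverable.

### Dilution, exactly

Because per-sample concentrations are renormalised over transcripts, the
difference of a head transcript between samples s and s+1 is
log2(mix(s+1)[head]/mix(s)[head]) − log2(D(s+1)/D(s)), where
D(s) = Σ_r mix(s)[r] · A(r) and A(r) is region r's total abundance. The
textbook closed form — B−A = log2(0.35/0.60), C−B = log2(0.60/0.75),
D−C = log2(0.75/1.00) under the default weights — holds exactly iff the
per-region totals A(r) are equal, which the verification scenario arranges
by planting equal fractions in all four regions with deterministic
baselines (log-sd 0). With random baselines the A(r) fluctuate and every
transcript's differences share a small common offset; at the default
problem sizes this offset stays well under the coding threshold.

### Identifiability cap of the contamination shift

An ovary transcript codes `[+,+,0]` only while the C−B difference still
clears θ. With contamination ε of ovary mass in fragment B,
C−B = log2( (w_o/(w_h+w_t+w_o)) · (w_h+w_t+ε)/ε ), which falls below θ = 2
once ε > w_o (w_h+w_t) / (4(w_h+w_t+w_o) − w_o) ≈ 0.032 under the default
weights. Beyond that cap ovary transcripts are coded `[+,0,0]` and
masquerade as testis-region — the migration of `[0,+,0]` into `[+,+,0]` is
therefore monotone in ε only within the cap. The property test exercises
the monotone range (ε ≤ 0.02); the acceptance suite additionally records
the behaviour across the cap, where the monotonicity breaks by model
arithmetic, not by sampling noise.

## Evaluation

`score_recovery` compares calls with planted labels: sensitivity(r) is the
fraction of truth-r transcripts called "r region" (both `[0,+,0]`- and
`[+,+,0]`-derived ovary calls count — they produce the same call), and
precision(r) the fraction of "r region" calls with truth r; uniform
transcripts are correct when non-differential. The dilution diagnostic
reports mean adjacent differences per truth label; empty labels are absent
rather than NaN.

## Numerical choices

* All arithmetic in double precision; rounding only at serialisation
  (6 significant digits in result tables; full 17-digit precision for
  count/truth tables, which therefore round-trip exactly —
  `float_precision="round_trip"` on re-read).
* The scalar `expression_level` uses the same log2 kernel as the
  vectorised path, so scalar and matrix computations agree bit-for-bit.
* Ties at the threshold code `0` (strict inequalities).
* Candidate ranking orders by descending difference at the call-defining
  comparison, ties broken by lexicographic transcript id.
* Largest-remainder rounding converts planting fractions into exact label
  counts (0.1 × 100 gives exactly 10).
* Degenerate inputs are handled explicitly: header-only count files give a
  valid 0-transcript matrix and an empty call table; a zero-total sample
  is a hard error naming the sample.

## Problem sizes used by the test suite

Unit and property tests run on matrices of ≤ 1 000 transcripts; the
end-to-end recovery study uses 10 000 transcripts at 5 × 10⁶ reads per
sample, and the closed-form dilution check 2 000 transcripts in noiseless
mode. These sizes give the statistics headroom (recovery margins are far
from the asserted bounds) while keeping the whole suite fast.

## Limitations

* No replicates, hence no statistical testing — like the experimental
  design it models, classification is a deterministic threshold rule, with
  false positives expected to be caught downstream (e.g. by in situ
  hybridisation).
* The simulator works at transcript level: no sequence-level reads, mapping
  ambiguity, positional or GC bias. Passing tests show the *analysis
  chain* is correct under the mixture model, not that the thresholds are
  optimal for any particular real library.
* Head-region (first-fragment) transcripts are unidentifiable by design.
* Heavy cutting contamination (ε above the identifiability cap) silently
  reassigns ovary transcripts to the testis class; the per-comparison
  threshold option exists precisely to trade this off.
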