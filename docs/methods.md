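# Methods

## Coordinates and record model

All intervals are 0-based, half-open; `length = end − start` for
deletions, tandem duplications and inversions.  This convention is
chosen because the published per-record tables it mirrors satisfy
`length = end − start` exactly (e.g. a printed 272 bp deletion spanning
20,311,318–20,311,590).  Insertions are zero-width breakpoints
(`start == end`) carrying an explicit inserted length; callers report
them as a point plus inserted sequence, and a reference-interval overlap
rule cannot apply to them.  Chromosome names are normalised (leading
`chr` stripped, case-folded) so mixed sources agree; report ordering is
numeric autosomes ascending, then X, then anything else.  Records below
50 bp, of unknown type (translocations are out of scope for both
emulated callers), or with negative/inconsistent coordinates are dropped
at ingest and tallied per reason — no silent drops.

## Consensus model

Within a sample, raw calls are filtered (support ≥ 3 read pairs;
chromosome Y excluded to remove the gender effect), pooled across the
two callers, and clustered by single linkage under the merge rule:
*same chromosome, same type, reciprocal overlap of at least 25 bp in
absolute terms* (no reciprocal-fraction requirement), with a 25 bp
breakpoint window substituting for insertions.  The threshold is read as
“≥ 25 bp” — the laxer of the two published phrasings — and is a
parameter.  Clustering is implemented as a per-(chromosome, type) sweep
in start order with an active list and union-find; because a qualifying
pair requires `end_j ≥ start_i + 25`, pruning on that bound makes the
sweep exact single linkage (verified against an all-pairs
transitive-closure oracle in the tests).  A cluster becomes a consensus
SV only if every required caller contributed at least one member; its
span is the union of member spans (the source material never states
representative coordinates, so the conservative, deterministic choice is
used).  The support filter is applied per raw call, before merging; the
source does not state the order, and per-call filtering is the stricter
reading.

Across the cohort the same rule merges per-sample consensus SVs; a
cluster is kept when its members come from ≥ 2 distinct samples (a
sample contributing two calls counts once).  Kept clusters receive
zero-padded serial IDs in (chromosome, start) order, so ID assignment is
deterministic.  Group/breed presence is defined as ≥ 1 carrier in the
label, applied after the global two-carrier filter; subset call sets
(e.g. one group's) are obtained by carrier filtering, not re-merging.

## Cohort comparison

The presence/absence matrix (samples × SVs, 1 = carrier) feeds exact
Venn-region counts by set algebra and a PCA computed by SVD of the
column-mean-centred binary matrix — presence data are conventionally
left unscaled.  Variance explained is squared singular values over total
variance; each component's sign is fixed by making its
largest-magnitude loading positive, so coordinates are reproducible
across BLAS builds.  Whether the original analysis used genotypes or
presence/absence is unstated; binary presence is the documented choice
here.

## Annotation

Each SV is classified against every gene it overlaps with precedence
exonic (any CDS base) > UTR > intronic; an SV touching no gene body but
within a 5 kb flank (the common variant-effect default; parameterised)
is upstream or downstream by strand; otherwise intergenic.  Any single
base of overlap counts — no minimum is imposed because none is stated.
Exonic and UTR hits are flagged loss-of-function, matching the published
arithmetic (54 exonic + 39 UTR = 93 LoF).  Per-SV summaries keep the
most severe class, so class fractions partition the call set and sum
to 1; per-gene counts count an SV once per gene.

The conserved-gene depletion test is a Pearson chi-square without
continuity correction on the 2×2 (conserved vs other) × (with vs
without SV) table; it reproduces the published χ² = 4.88, P = 0.027 from
the printed marginals (112/437 conserved, 7,881/25,880 overall).  The
SV-count/transcript-count association is a Spearman rank correlation
with average ranks for ties and the t-approximation p-value; the
published ρ = 0.231 was computed on an unstated gene subset and is
therefore not a validation target, only the operation is.

### Hotspot scan

SV start positions are tallied in 1 Mb windows sliding by 0.5 Mb.  The
background rate is the **median** window count, and a window is called
hot when its Poisson upper-tail probability under that rate falls below
the normal tail mass of `z_threshold` (default 3) divided by the number
of windows (Bonferroni).  Two properties force this design over the
naive “z ≥ 3 against the genome-wide mean/SD”: (i) on a 40 Mb toy genome
a planted 10×/5 Mb hotspot occupies ~12% of all windows and inflates the
genome-wide SD until no window reaches z = 3, so the naive scan cannot
recover its own planted signal — the median is robust to that
contamination; (ii) without multiplicity control, ~76 windows at a
per-window tail of 1.35 × 10⁻³ produce a false hotspot in 8–26% of
uniform null scans, whereas the Bonferroni form holds the family-wise
false-hotspot rate near the nominal tail (measured: ≥ 99.7% of null
seeds produce zero hotspots, and the planted enrichment is recovered
with full coverage).  Contiguous hot windows merge into maximal
intervals per chromosome; each reports its SV count and the count
standardised by √median as a descriptive z.  The published 39–59 Mb
X-chromosome region is qualitative context; no criterion for it was
printed.

## Summaries

Length bins are closed: [50, 1000], [1001, 10⁴], [10⁴+1, 10⁵], with an
overflow bin; “50–1000 bp” is read as inclusive because that reproduces
the published bin naming and row sums.  Covered length is reported two
ways — the per-type length sum and the interval union (insertions
contribute length to the sum, nothing to the union) — because the
published overall figure (27.37 Mb) and its own table sum (≈ 27.78 Mb)
disagree; the package prefers neither.  Type percentages recompute
exactly except the duplication slice, which is 7.01% by division against
a printed 7.02% (a rounding slip in the source).

## Diversity statistics

For a biallelic insertion/deletion site genotyped II/ID/DD, allele
frequencies come from gene counting, `p_I = (2n_II + n_ID)/2N`.  From a
frequency vector *p*: `Ho = Σpᵢ²`, `He = 1 − Ho`, `Ne = 1/Σpᵢ²`,
`PIC = 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ²` (the pair sum is computed as
`(Σp²)² − Σp⁴`).  The original study used a web calculator and printed
no formulas; these are the standard definitions.  Identities `Ho+He=1`,
`PIC ≤ He`, `Ne ∈ [1, k]` are property-tested on random frequency
vectors.  Between-population genotype-frequency differences use a
Pearson chi-square on the 2×3 table (classes absent from both
populations dropped), falling back to Fisher's exact test on the
DD-vs-rest collapse when any expected cell is below 5; the path taken is
reported, since the original significance test is unnamed.

## Synthetic cohorts

The generator emulates the cohort structure the pipeline was designed
for, scaled to desk size:

* **Genome** — three 10 Mb autosomes plus a 10 Mb X (40 Mb total).
* **Truth SVs** — default 2,000; types drawn at 84/8/7/1%
  (DEL/INS/DUP/INV); lengths log-uniform within the three bins with
  per-type bin weights matching the published composition; insertions
  span 50–132 bp as observed.  Placement is uniform, optionally with a
  multiplicative hotspot weight on one interval.
* **Cohort** — default three groups (GZP/NPOG/EUP) × three breeds × two
  samples (18 total, mirroring the 18-per-group design at reduced
  scale).  Each truth SV is shared (70%), group-specific (20%) or
  breed-specific (10%); carriers are drawn from the eligible pool at
  probability 0.3.
* **Callers** — two independent models (detection probability 0.9,
  uniform ±10 bp breakpoint jitter, 1 false positive per Mb per sample,
  support 1 + Poisson(9)).  Jitter is bounded at ±10 bp so that two
  calls from the same ≥ 50 bp truth SV always satisfy the 25 bp rule —
  rule-correctness tests stay separate from sensitivity stress tests.
  False positives are caller-independent, which is exactly the property
  the two-caller design exploits.
* **Genotype tables** — Hardy–Weinberg class counts at configurable
  allele frequencies (default: uniform on (0.05, 0.95), 8 populations,
  35 individuals each, 6 loci, matching the published genotyping scale).

Every component draws from an independent stream derived from the
master seed via hashed seed sequences, so runs are fully deterministic
and regenerating one component never perturbs another.

Because detections carry their truth ID through consensus and merging,
pipeline recall is checkable against a closed form: a truth SV with *c*
carriers survives with probability `P(Binom(c, d_eff²) ≥ 2)` where
`d_eff = d · P(1 + Poisson(mean−1) ≥ 3)` is the per-caller detection
probability after the support filter.  Measured recall on the default
conditions agrees with this expectation within 3σ; the small residual
positive bias comes from rare truth–truth interval collisions on the
toy genome.  False-positive survival is measured at the population
call-set level: independent false positives must both pair across
callers within a sample *and* recur in a second individual, which on
these conditions happens in fewer than 1 in 20 seeds (measured 0/15).

### What the simulation does not emulate

No read-level signal: breakpoint uncertainty is a uniform jitter, not
alignment-driven; caller error is type- and length-independent; false
positives are unclustered; there is no genotyping of non-carriers
(absence = not called, as in the emulated design) and no sequence
content.  Passing tests therefore demonstrate the correctness of the
merge/consensus/statistics machinery under the stated error model, not
caller-specific performance on real reads.

## Problem sizes and numerical choices

Tests and the acceptance script run the cohort pipeline at 2,000 truth
SVs × 18–20 samples, the clustering oracle at 200 calls × 100 seeds, the
hotspot null at 20 seeds × 1,500 SVs, and diversity identities at 1,000
random frequency vectors — sizes chosen so the whole suite completes in
a few minutes while keeping binomial error bars tight enough for 3σ
checks.  Chi-square and Spearman p-values come from `scipy.stats`
(cross-checked in tests against long-hand Σ(O−E)²/E and rank formulas);
PCA uses `numpy.linalg.svd` directly with the documented sign
convention, cross-checked against scikit-learn.  Degenerate inputs are
contracts, not crashes: a constant presence matrix yields zero
variance, zero-variance correlation inputs return NaN with that meaning
documented, a degenerate 2×2 expected cell is fatal, and an empty call
set yields an empty hotspot list.
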