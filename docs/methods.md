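# Methods

## The model

covdesign treats the read pileup at one genomic position as `n`
independent Bernoulli trials: each of the `n` overlapping reads either
supports the variant allele or it does not.  The number of
variant-supporting reads is therefore

    X ~ Binomial(n, p)

with `p` the per-base error rate `e` when the position is wild type
(spurious variant reads only), or the variant allele fraction `f` when
a true variant is present.  The calling rule is inclusive: a position
is called variant iff `X >= k` for a threshold `k`.

Under this model the two quantities that define an assay's operating
point are exact binomial tails:

* **false-positive probability** `P(X >= k | n, e)` — the chance error
  reads alone reach the threshold at a wild-type position;
* **detection probability** `P(X >= k | n, f)` — the chance a true
  variant at the limit of detection (LOD) `f` is called; its
  complement is the false-negative probability.

A *design* is the tuple `(f, e, alpha_fp, min_detection)`.  The solver
answers two questions:

1. **Threshold for a given depth** — the smallest `k` with
   `P(X >= k | n, e) <= alpha_fp` (bisection over the monotone upper
   tail).
2. **Minimum depth for a given LOD** — the smallest `n` whose threshold
   `k*(n)` achieves `P(X >= k*(n) | n, f) >= min_detection` (ascending
   scan from `n = 1`).

Error components compose additively: the overall assay error is the
sequencing error plus any assay-specific per-base components (PCR and
library-preparation errors), with no interaction term.  The composed
sum is normalised to 12 significant digits so that decimal components
reproduce the directly-typed decimal total.

### Assumptions

* Reads are independent and the error rate is homogeneous across reads,
  positions and substitution types.  No overdispersion (beta-binomial),
  no strand or trinucleotide stratification.
* Error and variant regimes are modelled separately: a mutant sample's
  variant reads are `Binomial(n, f)`, without adding `e` on top of `f`.
  The neglected term is of order `e` relative to `f` and conservative.
* Per-position control only: no multiple-testing correction across the
  positions of a panel.  At genome or exome scale `alpha_fp` must be
  tightened accordingly.

## Numerical choices

Tails are computed through the regularized incomplete beta function
(`P(X >= k) = I_p(k, n-k+1)`), the mass through log-gamma; both are
exact to near machine precision for depths up to 1e7 and are verified
in the test suite against a rational-arithmetic (`Fraction`) oracle to
relative error 1e-9 or better up to depth 300.  Degenerate inputs
(`p = 0`, `p = 1`, `k = 0`, `k = n+1`) are handled explicitly.  Gaussian
approximations exist only as a labelled diagnostic, never as decision
machinery: the thresholds sit on tails near 1e-3 where approximation
error flips decisions.

Comparison conventions, fixed here because prose descriptions of such
rules are usually ambiguous: the false-positive constraint is
`<= alpha_fp`, the detection constraint `>= min_detection`, and the
calling rule `X >= k`.  Probabilities are carried at full precision;
rounding to two-decimal percentages happens only in display strings.

### The depth sawtooth and the two search policies

The threshold `k*(n)` jumps by one at irregular depths.  At each jump
the detection probability drops, so design satisfaction is *not*
monotone in depth: a short run of satisfying depths can precede a
violating stretch.  `min_depth` therefore has two policies:

* `first` (default): the smallest satisfying depth, even if it lies in
  such a transient dip.  The returned decision always carries a
  minimality certificate (depth `n-1` violates a constraint).
* `stable`: the smallest depth from which the design holds for a whole
  window (default 50) of consecutive depths, for users who want a
  recommendation robust to small depth fluctuations in real libraries.

## Calibration of the published LOD-curve anchors

The published LOD-versus-depth curve at the 0.001/0.999 setting states
depth 61 for LOD 20% and 175 for LOD 10%, without stating the error
rate used.  With the exact solver and the `first` policy, a per-base
error of **0.71%** reproduces both anchors — and is the unique rate in
a 0.40–1.25% scan (0.01% steps) that does.  At 0.70% the LOD-10% search
instead returns 159: depths 159–160 form a transient satisfying dip
(`P(X >= 6 | 159, 0.007) = 9.65e-4 <= 0.001` with detection 0.99902)
before the threshold jumps to 7 at depth 161 and the design is violated
through depth 174.  All boundary quantities were re-checked in exact
rational arithmetic; margins from the 0.001 bound exceed 3%.

The same curve's LOD 5% -> 562 and LOD 3% -> 1650 anchors are not
reproduced by any single error rate or comparison convention we tested
(0.71% gives 476 and 1170; the `stable` policy gives 505 and 1215).
They are documented here and not asserted anywhere.  Likewise the
published pairing of depth 2000 with a 40-read threshold at an overall
error of 1.16% does reproduce exactly (`min_variant_reads(2000, 0.0116,
0.001) = 40`) but sits near a tail boundary, so the test suite logs it
rather than asserting the specific count.

## Monte-Carlo simulator

`simulate` draws read counts from the same binomial model
(`numpy.random.default_rng`, PCG64) and applies the calling rule,
giving empirical false-negative rates (mutant truth) or false-positive
rates (wild-type truth) next to their analytic values and the binomial
Monte-Carlo standard error `sqrt(p(1-p)/replicates)`.  Every output
records the seed actually used; absent a seed, one is drawn from OS
entropy and still recorded.  The dilution-series helper runs one
mutant-truth scenario per VAF level with independent spawned child
streams, so levels are reproducible individually.

Because the generator *is* the analytic model, simulator-analytic
agreement validates the implementation of both, not the model's fit to
real sequencing data: real pileups show overdispersion, strand bias,
mapping artifacts and position-dependent error, none of which are
emulated.  Depth is fixed per run; per-sample depth variation is left
to the caller via multiple runs.  Agreement tests use a 3-sigma band
with seeds fixed once; problem sizes (1e5 replicates, 1e6 for the rare
false-positive tail) keep the full suite under a minute while leaving
the 3-sigma band an order of magnitude tighter than the effects tested.

## Coverage QC

Internal coordinates are 1-based inclusive (the samtools-depth
convention); BED converts at the boundary (0-based half-open, expanded
per base on input, contracted on output).  Sub-threshold positions
merge into maximal failing intervals only when coordinate-adjacent on
the same chromosome.

Per-variant thresholds are re-solved at each observation's own depth,
because observed depths vary per position; the design depth serves only
as the insufficient-depth gate.  This deliberately differs from
applying one assay-wide `(depth, threshold)` pair: at higher observed
depth the re-solved threshold is stricter in reads but equally
calibrated in false-positive probability.  Call statuses are
`positive`, `negative`, `below-LOD` (called, but observed VAF under the
design LOD), `needs-confirmation` (observed VAF inside the confirmation
band, default 1–3%, where replication or an orthogonal method is
advisable), and `insufficient-depth`.  The 5,000x-style minimum target
depth gate is interpreted per base, not per amplicon.

DNA input amount, source and quality are carried through the report as
free-text metadata: they belong in the disclosure set but no
computation is defined on them.

## Known limitations

* Plain binomial error model; UMI/duplex error correction, FFPE
  artifacts and strand-aware models are out of scope.
* The additive error composition ignores PCR-cycle-dependent error
  amplification.
* LODs below ~2x the error rate are accepted with a warning but are
  intrinsically false-positive-prone regardless of depth.
* The depth solver's linear scan is exact but O(search_max); for the
  default cap of 100,000 this is still sub-second.
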