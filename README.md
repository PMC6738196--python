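# covdesign

Binomial design of sequencing coverage depth for deep targeted NGS.

Clinical variant calling at low variant allele fractions (VAF) — think
*TP53* subclones in chronic lymphocytic leukemia — hinges on one
technical question: **how deep must I sequence, and how many
variant-supporting reads must I require, to call a variant at my
intended limit of detection (LOD) without drowning in sequencing
error?**  covdesign answers it with the exact binomial model and no
approximations, for assay designers, diagnostic laboratories setting
validation thresholds, and bioinformaticians doing coverage QC.

## The model

The variant-supporting read count at a position of depth `n` is
`X ~ Binomial(n, p)`, with `p = e` (per-base error rate) at a wild-type
position and `p = f` (the VAF) at a mutant one.  A position is called
variant iff `X >= k`.  Given a design `(f, e, α, P_det)`:

* the calling threshold at depth `n` is the smallest `k` with
  `P(X ≥ k | n, e) ≤ α` — the false-positive probability of the rule;
* the minimum depth for the LOD is the smallest `n` whose threshold
  achieves `P(X ≥ k | n, f) ≥ P_det` — the detection probability, whose
  complement is the false-negative probability.

All tails are computed exactly via the regularized incomplete beta
function; assay-specific error components add onto the sequencing error
to form an overall error rate.  See `docs/methods.md` for assumptions,
the depth sawtooth, and the search policies.

## Worked example

A platform with 1% per-base error, sequenced to 250x, targeting a 10%
VAF with a per-position false-positive tolerance of 0.001:

```
$ covdesign threshold --depth 250 --error 1% --alpha 0.001 --vaf 10%
depth   250
error   0.01
alpha_fp        0.001
min_variant_reads       10
fp_prob 0.00025019006874050777
detection_prob  0.9998749408239253      99.99%
fn_prob 0.000125059176074734    0.01%
fp_satisfied    True
tp_satisfied    True
```

Ten or more variant reads are required: error alone reaches that count
with probability 0.025%, while a true 10% variant reaches it with
probability 99.99% — only 0.01% of such variants are missed.  The same
question inverted (how deep for a 3% LOD with an overall assay error of
1.16%?):

```
$ covdesign depth --vaf 3% --error 0.0116 --alpha 0.001 --min-detection 0.999
min_depth       2193
min_variant_reads       43
fp_prob 0.0008624360041294312
detection_prob  0.9990061881946485      99.90%
```

A whole LOD-versus-depth curve, here at the calibrated 0.71% error
(see `docs/methods.md`):

```
$ covdesign curve --vafs 0.03,0.05,0.10,0.20 --error 0.0071
vaf     alpha_fp  min_detection  error   min_depth  threshold  ...
0.2     0.001     0.999          0.0071  61         4
0.1     0.001     0.999          0.0071  175        7
0.05    0.001     0.999          0.0071  476        11
0.03    0.001     0.999          0.0071  1170       19
```

`covdesign simulate` validates any (depth, threshold) pair by seeded
Monte-Carlo — e.g. at 100x with a 10-read threshold a 10% VAF variant
is missed ~45% of the time, which the simulator reproduces within
Monte-Carlo error.  `covdesign qc` applies a solved design to a
samtools-depth table and a VCF (or TSV) of observations, reporting the
fraction of targeted bases at the required depth, the failing intervals
(BED), and a per-variant call status with read support — the
disclosure set a diagnostic assay should report.  Everything is also
available as a library (`import covdesign`).

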