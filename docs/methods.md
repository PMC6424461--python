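# Methods

## Model and assumptions

The package models carcinogenesis as the completion of any one of `k`
alternative combinations of `h` specific somatic mutations (hits) among
`G` possible mutable loci.  Two assumptions make the closed form
tractable: (1) mutations are equally likely at every one of the `G`
loci — not a constant mutation *rate*, only an approximately uniform
distribution of mutations across loci; and (2) carcinogenesis is driven
by somatic mutations (germline hits and epigenetic events are ignored,
which biases `h` slightly downward).  Under these assumptions the
probability that a given h-hit combination is complete after `m`
mutations is the inclusion–exclusion sum

    P_h(m) = sum_{i=0}^{h} (-1)^i C(h,i) ((G-i)/G)^m,   m >= h, else 0,

the probability that at least one of the `k` combinations is complete is
`P_k(m) = 1 - (1 - P_h(m))^k` (an approximation: combinations sharing
loci are not independent, but the overlap is negligible for G >> m and
the cumulative probability correctly approaches 1), and the
per-mutation probability is the increment `P(m) = P_k(m) - P_k(m-1)`,
with `P_k(0) = 0` by convention (no mutations, no hits).

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `G` | mutable loci that can fix without killing the cell | 3.25e9 × 2 × 1.1 × 1.5/100 ≈ 1.0725e8 | diploid genome, ~1.5% exome (burdens are counted from whole-exome calls), ~1.1 fixable mutations per locus |
| `h` | hits required | fitted over 1..9 | spans all reported estimates (2–8) with margin |
| `k` | alternative h-hit combinations | fitted; decade ranges 1e3–1e6 (h=1) … 1e37–1e48 (h=9) | each h implies a characteristic k scale; the ranges bracket the per-h RMSD minima |
| bin width / range | burden histogram resolution | 100 over 0–5000 | resolves the mode of every observed cohort while keeping ~50 informative bins |

`k` is treated as a positive real, not an integer: `P_k` is smooth in
`k` and the search spans 45 decades.  Counts above 5000
(hypermutators) are excluded from the binned comparison with a warning
and tallied separately; model mass beyond 5000 is likewise absent, not
renormalized, so both sides of the RMSD lose the same tail.

## Numerical evaluation of P_h

At exome scale `P_h` can be ~1e-40 while every term of the alternating
sum is ~1, so direct double-precision evaluation returns pure rounding
noise.  Two regimes are distinguished, switched on the cheap surrogate
`(1-(1-1/G)^m)^h >= 1e-5`:

* **Appreciable P_h** — the direct alternating sum, whose absolute
  rounding error (~1e-12) is then at least ~7 digits below the result.
  In the small-G regime used by the enumeration oracle this evaluation
  is exact to machine precision.
* **Tiny P_h** — the sum rearranged as a power series in 1/G:
  expanding `((G-i)/G)^m` binomially and exchanging summation order, the
  layers `j < h` vanish identically (finite differences annihilate
  low-degree polynomials — exactly the mass that rounding destroys in
  the direct sum), leaving

      P_h(m) = sum_{j=h}^{m} (-1)^(j-h) [m]_j / G^j * h! S(j,h) / j!

  with `[m]_j` the falling factorial and `S(j,h)` Stirling numbers of
  the second kind.  Successive terms shrink by ~m·h/G (< 0.05 at all
  supported scales), so there is no cancellation; the series is exact
  if run to j = m and is truncated when terms fall below 1e-16 of the
  partial sum (at most 40 extra terms).

The naive surrogate `(1-(1-1/G)^m)^h` itself is *not* adequate: it
treats the h hit times as independent and overcounts by a relative
~h(h-1)/(2m) (a factor of 3 at h=5, m=10), which the leading series
term `[m]_h/G^h` corrects exactly.

`P_k` is evaluated as `-expm1(k * log1p(-P_h))`: `k·P_h` is the only
well-scaled quantity when `P_h ~ 1e-40` and `k ~ 1e40`.

The validation reference evaluates the alternating sum with mpmath.
Because the sum cancels roughly `-log10(P_h)` digits (up to ~70), the
reference raises its working precision by the estimated cancellation
depth so that the requested 60 significant digits survive in the
result.  Production values agree with this reference to relative error
≤ 2.3e-8 over G ∈ {1e6, 1.0725e8, 8.58e8}, h = 1..9, m up to 5000.

## Fitting procedure

Observed counts are binned (bin 1 spans 0–100 inclusive, bin b spans
100(b−1)+1..100b) into percentages of included samples; model mass is
accumulated into the same bins as `P_k(edge_b) − P_k(edge_{b−1})`.  For
each h, k is scanned over mantissas {1..9} of every decade in that h's
range — the reported combination counts are single-digit mantissas,
which this grid reproduces — followed by a refinement pass of 20
log-spaced points within ±0.5 decade of the coarse minimum.  Ties
within 1e-9 RMSD break toward smaller h, then smaller k (parsimony).
Fits are deterministic and invariant to sample order.

The mixture fit optimizes both components' k jointly on the coarse
grids for every pair hi < hj and every share a ∈ {10,...,90}%, using the
quadratic expansion of the RMSD so each (pair, a) costs one small matrix
product, then refines (ki, kj) around the joint optimum.  Pairs with
hi = 1 are allowed: some observed cohorts are best described with a
1-hit component.

Uncertainty in h uses a percentile bootstrap: samples are resampled
with replacement, h is refit on the coarse grid only (the refinement
pass moves k within a decade and essentially never changes h), and the
empirical 2.5/97.5 percentiles are reported.  Robustness checks refit
on 80% subsamples (h should not change for cohorts above ~200 samples)
and with G scaled 8-fold (h should not change; k compensates).

## Synthetic cohorts

The generator draws per-sample counts from the model's own normalized
increment distribution `P(m)/P_k(5000)` on 1..5000 by inverse-CDF
lookup, with optional two-component mixtures (component drawn per
sample) and an optional hypermutator tail (counts uniform on
(5000, 50000]).  One seeded stream is consumed in a fixed order, so a
seed pins the cohort bitwise.  Default cohort size in the recovery
experiments is 500 samples — between the ~200-sample robustness
threshold and the largest real cohorts (~900 samples).

What the generator emulates: integer burdens concentrated in 0–5000
with model-determined mode and variance, mixture structure, and an
overflow tail.  What it does not: inter-locus mutability differences,
mutational signatures, subclonal structure, or measurement error in
variant calling.  Passing recovery tests therefore show the estimator
is consistent and well-calibrated *under the model's own assumptions*;
they cannot show the model is correct for real tumors.

## Identifiability limits

At 500 samples the multinomial noise floor of the binned distribution
is ~0.6 RMSD percentage points, which is comparable to the separation
between an 8-hit curve and the best k-adjusted 7- or 9-hit curves.
Recovery of h from 500-sample cohorts is therefore essentially certain
for h ≤ 5 (measured ≥ 96% over 200 replicates) but ~80% for h = 8, with
misses going to the adjacent 7 or 9; at 200,000 samples the 8-hit fit
is exact.  The same limit makes the second component of a 3+8 mixture
wander over {7, 8, 9} from seed to seed, while the first component and
the mixing share are recovered reliably.  This mirrors the wide
bootstrap CIs the method itself reports for 8-hit cancer types and
should be kept in mind when interpreting high-h fits on real cohorts.

## Degenerate inputs and edge conventions

A count of exactly 100·b belongs to bin b (lower-edge inclusive only
for bin 1, which also holds count 0).  Cohorts below 200 samples fit
with a warning, not an error.  An empty cohort, empty search grid, or
zero bootstrap replicates raise.  The generator refuses specs whose
model places most mass beyond the sampling grid (P_k(m_max) ≤ 0.5) and
suggests a larger m_max.  Correlation utilities reject constant inputs
(undefined r) and n < 3 (p-value undefined); the Fisher-z interval
requires n ≥ 4 and |r| < 1.

## MAF ingestion conventions

All variant rows count toward the burden by default — the 1.1 factor in
G already accounts for synonymous calls; excluding `Silent` rows is an
option (estimates of h are typically unchanged).  Rows identical in
(sample, chromosome, position, alternate allele) are collapsed by
default, a defensive measure for concatenated MAFs that leaves
single-caller files untouched.  Positions stay 1-based and are never
used downstream.  Clinical metadata joins on the first 12 characters of
the sample barcode (the TCGA patient ID), configurable.
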