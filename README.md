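# multihit

Estimating the number of carcinogenic mutations ("hits") a cancer type
requires, from the distribution of somatic mutation burdens across tumors.

## The problem

Individual cancers are thought to arise when some small combination of
*h* specific somatic mutations — the hits — has occurred in one cell.
There is no single carcinogenic combination: many alternative
combinations (*k* of them) can each suffice.  Classical estimates of *h*
work from cancer incidence by age and therefore require an assumed
mutation rate, which varies by orders of magnitude between individuals.
This package implements a model that sidesteps mutation rate entirely by
working directly from the number of somatic mutations per tumor sample
(the mutation burden), as counted from MAF variant tables such as those
TCGA provides.

## The model

With *G* equally likely mutable loci (default exome scale,
G = 3.25·10⁹ × 2 × 1.1 × 1.5/100 ≈ 1.07·10⁸), the probability that one
given combination of *h* loci has been completed after *m* somatic
mutations follows from inclusion–exclusion:

    P_h(m) = 1 − Σ_{i=1}^{h} (−1)^{i+1} C(h,i) [(G−i)/G]^m        (m ≥ h)

the probability that at least one of *k* alternative combinations is
complete is

    P_k(m) ≈ 1 − [1 − P_h(m)]^k

and the probability that the *m*-th mutation is the completing hit is
P(m) ≈ P_k(m) − P_k(m−1).  Fitting proceeds by binning observed
per-sample burdens (width 100, range 0–5000), binning the model's P(m)
the same way, and choosing (h, k) to minimize the RMSD between the two
binned distributions, with h = 1..9 and k on per-h mantissa–decade grids
spanning 10³–10⁴⁸.  A two-component variant fits a mixture
P = (a·P_hi + (100−a)·P_hj)/100 for cohorts that blend two hit numbers,
and percentile-bootstrap resampling gives a confidence interval on h.

P_h is numerically delicate (it can be ~10⁻⁴⁰ while every term of the
alternating sum is ~1); see `docs/methods.md` for the cancellation-free
evaluation scheme and its arbitrary-precision validation.

## Worked example

Simulate a 500-sample cohort from a 3-hit model with 9·10¹⁴ combinations
(the scale fitted for breast carcinoma), then fit it back:

```sh
$ multihit simulate --h 3 --k 9e14 -n 500 --seed 11 -o sim
500 samples -> sim/cohort.csv
$ multihit fit sim/cohort.csv --mixture --bootstrap 200 --seed 0 -o fit
h=3 k=9.41e+14 RMSD=0.52% (n=500) -> fit/fit.json
$ multihit stability sim/cohort.csv --seed 1 -o stab
full fit h=3; h unchanged in 10/10 subsamples
```

The fit recovers h = 3 with k = 9.4·10¹⁴, within one mantissa step of
the generating value; the RMSD of 0.52 percentage points is at the
sampling-noise floor for 500 samples spread over 50 bins.  The bootstrap
95% CI in `fit/fit.json` is [3, 3], and the 80%-subsample refits all
keep h = 3 — the cohort is comfortably above the ~200-sample size below
which these estimates stop being robust.  `fit/binned.csv` holds the
observed and model bin percentages side by side for plotting.

Real MAF input goes through `multihit count`:

```sh
multihit count cohort.maf --metadata clinical.csv -o counted
multihit fit counted/cohort.csv -o fit
```

and `multihit correlate` computes the Pearson r / Fisher-z interval used
for burden-vs-age and hits-vs-stem-cell-division analyses.

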