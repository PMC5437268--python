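# Methods

## Read model and tumour LOD score

A sequenced base at a candidate locus is modelled as a two-component
mixture: a fraction `f` of fragments carry the variant, and a uniform
per-base substitution error `e` corrupts any base (a *specific* wrong
base appears with probability `e/3`). The per-read likelihoods are

    P(alt | f) = f(1−e) + (1−f)·e/3
    P(ref | f) = (1−f)(1−e) + f·e/3

and the tumour LOD score of a locus with `k` alt reads in depth `n` is
the log10 likelihood ratio of `f = f̂` against `f = 0`, with the
unconstrained plug-in MLE `f̂ = k/n`:

    LOD = k·log10[P(alt|f̂)/(e/3)] + (n−k)·log10[P(ref|f̂)/(1−e)]

This reproduces the structure of the f* statistic of somatic callers for
deep tumour-only data, with one deliberate simplification: a single
uniform `e` replaces per-read base qualities. No quality information
exists in a call table, and the downstream filter consumes the
*within-sample distribution* of LODs, which is insensitive to absolute
calibration. Exact numerical parity with any specific caller is
therefore not claimed — only structural parity. Default `e = 1e-3`
(typical Illumina raw substitution rate); the deep-sequencing study
conditions use `e = 5e-4`.

Two boundary properties matter. `LOD = 0` exactly at `k = 0` (numerator
and denominator coincide). And the score is *not* globally monotone in
`k`: for `0 < k/n < ≈e` the plug-in MLE explains the data slightly worse
than pure error and the LOD dips below zero, turning increasing once
`k/n` clears the error rate. All thresholds of interest sit far above
this dip, and `detection_floor` (smallest `k` reaching a given LOD)
bisects on the increasing branch, which is valid for any positive LOD
target.

## Per-sample modified Z-score filtering

Absolute LOD distributions shift between samples and between sequencing
batches (reported batch medians differ by roughly 15 LOD units), so the
filter normalises per sample: over the pool of candidates the upstream
caller *kept*, compute the median and the raw MAD (median absolute
deviation — no 1.4826 consistency constant and no 0.6745 modified-Z
constant, because the calibrated threshold of 20 is defined on the raw
statistic; textbook constants would silently rescale it). Each call's
modified Z-score is `(LOD − median)/MAD`. The z-scores are invariant
under adding a constant to, or positively rescaling, a sample's LODs —
precisely the batch-effect resistance the normalisation exists for.

Stepwise dispositions, first removal wins (the categories are mutually
exclusive and exhaustive):

1. `REMOVED_JUDGEMENT` — upstream caller rejected the candidate;
2. `REMOVED_Z` — `z < z_threshold` (pass is inclusive, `z ≥ 20`:
   "20 MADs above the median" is read as the boundary of acceptance);
3. `REMOVED_GERMLINE` — population allele frequency annotated and
   strictly `> 0.1%` (a call *at* 0.1% is kept; unannotated calls are
   kept);
4. `SOMATIC_KEPT` otherwise.

A germline SNP that also fails the Z step is counted `REMOVED_Z`
(first-step attribution). Degenerate samples with MAD = 0 substitute a
floor of 1e-6 and are flagged rather than failed, keeping cohort runs
robust; samples with no kept candidates yield a report with NaN
statistics and every call `REMOVED_JUDGEMENT`. The pool for median/MAD
is KEEP calls only; REJECT calls still receive z-scores for reporting.

## Threshold training and cohort evaluation

The Z threshold is trained by an ROC sweep over a grid (default integers
1–100): at each threshold the full filter runs over a training cohort,
sensitivity is the fraction of bone-marrow truth mutations kept in any
cfDNA sample of their patient, and specificity the fraction of non-truth
KEEP candidates removed. The selected threshold maximises Youden's
J = sensitivity + specificity − 1, ties broken toward the smaller
threshold (favouring sensitivity). Truth matching is by exact locus
(contig, position, ref, alt); no positional window.

Concordance reporting rounds to integer percent (26/27 → 96%). The
specificity denominator is candidate-level — pooled non-truth KEEP
candidates — because that is the only denominator computable from call
tables; a per-base or per-position definition would need the full target
footprint and is out of scope. Patients without truth records are
excluded from sensitivity but still contribute false positives, with a
warning.

Per-patient allele-fraction regression (cfDNA AF vs bone-marrow AF) is
ordinary least squares with intercept, restricted to patients with at
least three shared mutations; fewer pairs, or zero variance in the cfDNA
fractions, is an error rather than a silent NaN. Subclonal rank
concordance compares the two AF orderings (verdict: identical or not)
alongside Kendall's tau. Fragment-overlap phasing of two nearby variants
classifies them from per-fragment presence/absence: *mutually exclusive*
iff no fragment carries both and each has support (distinct subclones),
*co-occurring* iff every supporting fragment carries both, otherwise
*mixed* with counts.

## Plasma input-mass and complexity models

With haploid genome mass 3.5 pg, a mass of `m` ng contains
`n = floor(1000·m/3.5)` genome equivalents (floored: fragments are
molecules). The probability that an aliquot contains at least `k_min`
tumour fragments at fractional abundance `f` is the exact binomial tail
`1 − BinomCDF(k_min−1; n, f)`. The inverse (required mass) uses the
closed form `n = ceil(ln(1−p)/ln(1−f))` for `k_min = 1` and bisection on
`n` otherwise. Both `k_min` readings are exposed because the two are not
equivalent: at `f = 0.05%` and target 99.99%, `k_min = 1` needs ~64.5 ng
while `k_min = 2` needs ~82.3 ng, bracketing the 83 ng design input from
below; the package treats `k_min` as an explicit model choice rather
than resolving the ambiguity silently.

The complexity chain: genome equivalents × (genome size / fragment
length) total fragments; × retention fraction (default 0.43) surviving
library preparation; × (target size / genome size) on-target unique
molecules; × (fragment length / target size) the unique-fragment
coverage ceiling. Defaults: 17,500 bp target (146 probes × 120 nt at 1×
tiling ≈ 17.5 kb), 2.86e9 bp effective genome (the value consistent with
the retained-fragment → on-target arithmetic), 170 bp fragments. The
percent-unique utility `min(100, 100·ceiling/depth)` reproduces the
~55% unique reads at 20,000× and ~11% at 100,000× implied by a ~11,000×
ceiling. Capture-hybridisation efficiency and fragment-size
distributions are deliberately not modelled.

## Synthetic cohort generator

The generator produces per-sample call tables with the statistical
structure the filter assumes, plus matched bone-marrow truth. Per
sample: depth ~ negative binomial (mean 20,000, dispersion 50 — mild
overdispersion typical of capture panels); 200 artefact sites with alt ~
Binomial(depth, e_site/3), where 10% of sites have `e` inflated by
`1 + Pareto(shape 3)` (a heavy-tailed minority of error hotspots —
polymerase/damage artefacts; published assays report no artefact-rate
figures, so these are conventional Illumina-scale choices); 30 germline
SNPs at AF 0.5 (three-quarters) or ~1.0, carrying population frequencies
log-uniform in (0.0011, 0.5) so the 0.1% cutoff removes them by
construction (a configurable rare-germline fraction below the cutoff
exercises the known failure mode of database filtering); somatic spikes
at allele fractions log-uniform in 0.25–46%. LODs are computed with the
package's own scorer at the *nominal* error rate — the analyst does not
know which sites are inflated, which is exactly what lets hotspot
artefacts leak through and keeps specificity below 100%. Batches add
constant LOD offsets (default {0, +15}, emulating the reported batch
medians ~8.5 vs ~23.2); offsets are additive only, as no batch scale
differences are reported.

The default cohort is 48 samples carrying 51 somatic truth variants in
total (the evaluated-cohort scale), one sample per synthetic patient,
with bone-marrow AF = cfDNA sampling AF × per-patient scaling
(log-normal around 2 — marrow plasma cells are enriched relative to
plasma) × (1 + Normal(0, 0.05)) clipped to [0, 1]. All randomness flows
from one seed; per-sample substreams use `default_rng([seed, index])`,
so output is bit-reproducible and order-independent.

`simulate_training_set` post-adjusts emitted LODs so that per-sample
artefact z-scores lie strictly below a ceiling and somatic/germline
z-scores strictly above a floor, iterating to a fixed point (adjusted
LODs re-enter the median/MAD pool) and verifying the guarantee
afterwards. The top artefacts are pinned just below the ceiling at 0.5-z
spacing so every threshold under the boundary loses specificity — making
the ROC sweep's selection of the boundary informative rather than a tie
artifact.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: read-level errors and alignment (no
FASTQ/BAM; judgement labels are assigned, not derived), context-specific
artefact spectra (e.g. oxidative G>T damage), correlated errors across
samples in a batch beyond the location shift, tri-allelic sites, indels,
contamination, and rare germline variants absent from population
databases (present only if configured). Performance numbers on synthetic
cohorts are *bounds under the model's assumptions*, not measurements of
a wet-lab assay.

## Numerical choices and problem sizes

Floats are serialized with shortest-roundtrip `repr`, so
write-then-read of call tables is exactly identity on every numeric
field. Threshold comparisons are exact (`z ≥ t`, `pop_af > cutoff`);
ties in ROC selection go to the smaller threshold. The binomial tail
uses `scipy.stats.binom.sf` (checked against outcome enumeration for
n ≤ 12); OLS uses `scipy.stats.linregress`.

Default analysis scales — one ~230-candidate sample for the detection
floor, a 48-sample cohort for sensitivity/specificity, 25 samples for
threshold recovery, an integer 1–100 ROC grid — run in seconds and are
the package's chosen experiment sizes; larger cohorts only narrow the
Monte-Carlo spread of the same statistics.
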