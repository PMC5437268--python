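# lbseq

Detection of tumour-derived mutations in blood plasma from deep targeted
sequencing of cell-free DNA (cfDNA). In advanced myeloma and other
cancers, a fraction of the DNA fragments circulating in plasma comes from
tumour cells; sequencing a small gene panel to ~20,000× depth exposes
those fragments as candidate substitutions at allele fractions down to
fractions of a percent — buried in a background of sequencing artefacts
with similar apparent allele fractions, plus germline polymorphisms.
`lbseq` implements the analytics that separate them, for people who work
with candidate-variant call tables from hybrid-capture liquid-biopsy
assays (or want to stress-test such a filter on synthetic data before
trusting it on patients).

## The method

Each candidate substitution carries a **tumour LOD score**

```
LOD = Σ_reads log10 [ P(read | f = f̂) / P(read | f = 0) ]
```

with per-read likelihoods `P(alt|f) = f(1−e) + (1−f)e/3`,
`P(ref|f) = (1−f)(1−e) + f·e/3`, `f̂ = alt/depth` the ML allele fraction
and `e` the per-base substitution error rate — the log-likelihood ratio
of "a variant is present" against "every alt read is an error".

Absolute LOD values shift strongly between samples and sequencing
batches, so LODs are never thresholded directly. Per sample, the LODs of
all caller-kept candidates are transformed into **modified Z-scores**

```
z_i = (LOD_i − median) / MAD        (raw MAD, no consistency constant)
```

and filtered stepwise: (1) drop candidates the upstream caller rejected,
(2) drop candidates with `z < 20` — the threshold an ROC sweep against
bone-marrow truth sets selects by maximising Youden's J — and (3) drop
likely germline polymorphisms annotated at > 0.1% population allele
frequency. Survivors are putative somatic mutations. Companion modules
evaluate cohort concordance and subclonal structure against bone-marrow
profiling, and size the assay itself: under a binomial sampling model
with 3.5 pg haploid genomes, the input mass needed to catch a tumour
fragment at 0.05% abundance, and the library-complexity ceiling on
informative coverage.

A synthetic-cohort generator emulates the whole setting — artefact
backgrounds with heavy-tailed error hotspots, batch-shifted LOD
distributions, annotated germline SNPs, somatic spikes at 0.25–46% AF
with matched bone-marrow fractions — so every stage is testable without
any sequencing data.

## Worked example

Score a candidate with 50 alt reads at 20,000× and error rate 5×10⁻⁴
(a 0.25% allele-fraction variant):

```
$ lbseq lod --depth 20000 --alt 50 --error 5e-4
38.508486
```

Simulate a 4-sample cohort with 8 somatic truth variants, filter one
sample, and evaluate the cohort against its bone-marrow truth:

```
$ lbseq simulate --config cohort.json --seed 7 --out demo   # {"n_samples": 4, "n_somatic_total": 8}
wrote 4 samples, 8 truth records to demo

$ lbseq filter --callstats demo/SYN-000.tsv --out report.tsv
SOMATIC_KEPT         5
REMOVED_JUDGEMENT    0
REMOVED_Z            198
REMOVED_GERMLINE     30

$ lbseq concordance --cohort demo --truth demo/truth.tsv
n_truth	8
n_detected	8
concordance_pct	100
false_positives	5
specificity_pct	99.46
```

Sample SYN-000 holds 233 candidates: 200 artefact sites, 30 germline
SNPs and 3 somatic spikes. The filter computes the sample's LOD median
(−0.327) and MAD (0.136), sets the sample-specific LOD threshold at
`median + 20·MAD = 2.39`, removes 198 candidates below it and all 30
germline SNPs, and keeps 5 — the 3 spikes plus 2 error-hotspot
artefacts, which is what the cohort-level 99.5% specificity and 8/8
(100%) concordance are counting.

Size the assay: the input mass question and its inverse:

```
$ lbseq plasma-model --mass 83
genome_equivalents	23714
capture_probability	0.999993

$ lbseq plasma-model --target-prob 0.9999 --kmin 2
required_mass_ng	82.278
```

An 83 ng aliquot (23,714 haploid genome equivalents at 3.5 pg each) has
a 99.9993% chance of containing at least one tumour fragment at 0.05%
abundance; conversely ~82 ng suffices for 99.99% confidence of capturing
two such fragments.

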