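# tukinetics

RNA processing kinetics from very short metabolic-labeling time courses.

Pulse-labeling nascent RNA with a nucleotide analog (4-thiouracil, "4tU")
for 1.5, 2.5 and 5 minutes, purifying the labeled fraction and sequencing
it captures RNA populations that are invisible at steady state: unspliced
pre-mRNAs, cryptic unstable transcripts (CUTs), stable unannotated
transcripts (SUTs) and other short-lived species in budding yeast.
`tukinetics` is a library for analyzing such time courses — and for
simulating them with known ground truth, so every estimator in the
pipeline can be validated end to end without external sequencing data.

It is aimed at computational biologists working on splicing or RNA
turnover who want a self-contained, testable implementation of:

* **Splicing-ratio inference.** For a single-intron gene, the splicing
  ratio at labeling time *t* is R = mRNA / (mRNA + pre-mRNA). Junction
  fragments are unambiguously mature, intron-touching fragments
  unambiguously precursor, and exon-only fragments are ambiguous. A
  latent-variable model in the MISO family assigns each fragment an
  identity *z* and Gibbs-samples the ratio, with emission weights
  normalized by isoform effective length and a Beta prior placed on the
  reported (abundance-scale) ratio; the posterior yields a mean and a 95%
  credible interval per gene per time point. Two direct estimators
  (junction/boundary counts; intron/exon read densities) are provided for
  comparison, and genes are filtered by credible-interval width (< 0.3).
* **Splicing speed.** Per-gene trapezoidal area under the ratio
  trajectory, normalized by the steady-state ratio:

  AUC = [(R₂.₅ + R₁.₅)/2 + 2.5·(R₅.₀ + R₂.₅)/2] / (3.5·R_SS)

  AUC = 1 means splicing is effectively instantaneous on the labeling
  timescale; smaller values mean slower splicing.
* **Decay-rate proxy for ncRNAs.** log₂ of the weighted mean nascent FPKM
  over the steady-state FPKM — higher means faster degradation. Includes a
  first-order goodness-of-fit check, because short-time trajectories of
  CUTs/SUTs are incompatible with single-step decay kinetics.
* **Background bounding.** A worst-case upper bound on unlabeled RNA
  carried through the purification, from the intronic FPKM fractions of
  the unlabeled control (α₀) and the labeled sample (α₁):
  m/n = (β − α₁)/(α₁ − α₀) with β ≤ 0.5, background ≤ (m/n)/(1 + m/n).
* **Sequence/structure features and statistics.** Folding energy per
  nucleotide (whole intron, 5′ss-to-branch-point region, ±15 nt windows)
  via a pluggable backend (built-in Nussinov-style proxy, optional
  ViennaRNA), PWM splice-site scores in bits, k-mer composition,
  fastest-vs-slowest-thirds rank-sum tests, feature–speed Pearson
  correlations with BH adjustment, Gaussian naive Bayes 10-fold-CV
  ROC/AUC, and random-forest regression with permutation-importance
  feature selection (out-of-bag predictions only).
* **A synthetic 4tU-seq simulator.** Labeled precursor/mature abundances
  from an explicit kinetic chain (synthesis → maturation, optionally an
  Erlang multi-step chain producing the delayed, non-first-order behavior
  of CUT-like species → decay), aligned fragments with configurable
  background contamination, intron sequences with consensus splicing
  signals and controllable A/U composition, and labeled feature tables.

## Worked example

`examples/` contains one short script per capability. From
`examples/simulate_and_quantify.py` (five simulated single-intron genes,
8,000 fragments at 1.5 min, true R = 0.468):

```
gene      true_R   posterior_mean   95% CI            n_reads
g0001   0.468    0.441            [0.391, 0.492]    1870
g0002   0.468    0.446            [0.391, 0.503]    1496
g0003   0.468    0.466            [0.420, 0.514]    1666
g0004   0.468    0.515            [0.465, 0.560]    1599
g0005   0.468    0.454            [0.401, 0.510]    1369
```

Each posterior mean estimates the gene's labeled mRNA fraction; the
credible intervals cover the simulated truth at roughly their nominal
rate. From `examples/decay_and_background.py`:

```
         1.5    2.5    5.0  proxy
cut1   1.686  1.710  1.694  0.766
sut1   1.635  1.652  1.630  0.715
mrna1  0.833  0.827  0.832 -0.269

background bound: m/n = 0.1010, fraction <= 9.18%
```

The CUT-like species (delayed maturation, fast decay) sits in a flat
plateau ~1.7× its steady-state level throughout the nascent window — the
signature of multi-step, non-first-order processing — while the stable
mRNA does not; the proxy orders them by turnover. The background bound
says that with 7.5% intronic signal in the unlabeled control and 46.1% at
1.5 min, unlabeled carry-over can be at most ~9.2% of the labeled sample.

A full orchestrated run (`examples/full_pipeline.py`, or
`tukinetics run --out <dir>` from the shell) writes every stage's TSV
plus a manifest with per-file hashes; reruns with the same config are
byte-identical.

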