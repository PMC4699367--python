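# Methods

This note documents the models, estimators, numerical choices and known
limitations of `tukinetics`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Kinetic model of labeled abundances

Label is added at t = 0; incorporation begins after `label_offset` minutes
(default 0.5 min, reflecting the ~30 s lag before analog incorporation
becomes detectable in vivo). Labeled material then follows a linear chain

    synthesis (k_syn) → precursor → mature → decay (k_decay)

with maturation rate `k_splice` (1/min). For `n_maturation_steps = 1` the
labeled precursor and mature pools have the classic two-compartment
closed form

    P(t′) = (k_syn/k_splice)(1 − e^(−k_splice t′)),  t′ = max(0, t − offset)
    M(t′) = k_syn/k_decay − k_syn/(k_decay − k_splice) e^(−k_splice t′)
            + k_syn k_splice / (k_decay (k_decay − k_splice)) e^(−k_decay t′)

with a separate closed form for the degenerate case k_splice = k_decay
(detected at relative tolerance 1e-10). For `n_maturation_steps = n > 1`
the precursor passes through an Erlang chain of n stages, each at rate
n·k_splice (preserving the mean maturation time 1/k_splice); the affine
linear system is solved exactly with the matrix exponential of the
augmented system, and tests verify agreement with an independent
`solve_ivp` integration to relative error < 1e-6. Steady state is taken
analytically: total chain occupancy k_syn/k_splice, mature pool
k_syn/k_decay, so R_SS = k_splice/(k_splice + k_decay).

**The plateau of unstable ncRNAs.** CUT-like species in the simulator
default to a 4-step chain with mean delay 1/k_splice ≈ 5 min followed by
fast decay. On the per-sample-normalized scale (each sample divided by
its total, nascent values expressed relative to steady state — the scale
on which FPKM heat maps are drawn) such species hold an approximately
flat plateau well above their steady-state level across 1.5–5 min,
because their labeled pool grows nearly linearly, in step with the
sample total; a first-order species with the same rates saturates
immediately and its normalized ratio erodes monotonically. The
`labeled_fpkm_trajectory` helper computes this normalization, and the
property test freezes the contrast. Note the per-gene *unnormalized*
ratio labeled(t)/labeled(∞) is never flat in this regime; the plateau is
a property of within-sample normalization against a background
transcriptome.

## Read simulator

Fragments are drawn from (gene, isoform) pairs with probability
proportional to abundance × effective length (valid start positions),
start positions uniform, fragment lengths truncated-normal
(lower-truncated at `read_len`). The whole fragment is reported as the
covered interval — a deliberate simplification; there is no model of
gapped paired-end coverage, sequencing error, PCR duplication or
positional bias, so passing tests demonstrate estimator correctness
under the stated generative model, not robustness to real library
artifacts. A configurable fraction of fragments is drawn from the
steady-state composition instead of the labeled one, emulating unlabeled
RNA that survives the purification (such RNA is overwhelmingly spliced,
which is what makes the intronic-fraction background bound work).
Isoforms shorter than the mean fragment are skipped with a logged
warning. Single-exon genes carry their total labeled pool as one
species. Reads are exchanged as a documented TSV
(read_id, gene_id, block_starts, block_ends, category); SAM/BAM is
ingested via pysam with uniquely-assignable, primary alignments only.

Annotation defaults (lognormal medians): RP-intronic genes
150/400/600 nt (exon1/intron/exon2), non-RP intronic 120/150/450 nt,
CUT 300 nt, SUT 550 nt (SUTs longer than CUTs by construction), XUT
600 nt, snoRNA 120 nt. Per-class kinetic regimes put fast splicing and
slow decay on RP transcripts and delayed maturation with fast decay on
CUTs. All randomness flows from one integer seed through
`numpy.random.default_rng`; nothing touches global state.

## Splicing-ratio estimators

`classify_read` labels a fragment mature iff its two blocks exactly skip
the intron (any anchor length — unambiguous evidence is unambiguous
regardless of anchor), precursor iff any block overlaps the intron, and
ambiguous otherwise. Region *counting* (`count_regions`) is stricter: a
junction or boundary is only counted with ≥ `min_anchor` = 5 nt on each
side, standard short-read practice. Consequently the probabilistic
estimator uses weakly-anchored junction fragments that the direct
junction estimator ignores.

**Posterior estimator.** Let φ be the probability that a fragment
originates from the mature isoform; physically φ = R·ℓ_m / (R·ℓ_m +
(1−R)·ℓ_p) with effective lengths ℓ. The Gibbs sampler alternates
(i) drawing each ambiguous fragment's identity with probability
∝ φ/ℓ_m vs (1−φ)/ℓ_p (ambiguous fragments sharing a span are collapsed
to one binomial draw — an exact reformulation), and (ii) updating φ.
The Beta(prior_a, prior_b) prior (default uniform) is placed on the
*reported, abundance-scale ratio R*, not on φ; on the φ scale this
contributes the Jacobian ∝ 1/(φℓ_p + (1−φ)ℓ_m)², handled by a
Metropolis step whose proposal is the conjugate Beta given the identity
counts. When ℓ_m = ℓ_p the Jacobian is constant, every proposal is
accepted, and the sampler reduces to exact conjugate draws (the analytic
Beta oracle in the tests). Posterior φ samples are mapped through the
effective-length transform to R; the estimate is the posterior mean with
the central 95% interval. Defaults: 2,000 iterations, 500 burn-in,
per-gene effective lengths from the median fragment span.

Known finite-sample behavior, quantified by MCMC-free quadrature in the
validation work: at 200 fragments per gene with roughly half of them
exon-only (hence nearly uninformative), the posterior mean retains a
shrinkage-toward-0.5 bias of about +0.02 at true R = 0.1, falling below
0.008 for R ≥ 0.2; 95%-interval coverage stays between 0.90 and 0.98
across the grid. Users who need minimal edge bias at very low coverage
should prefer the posterior median or report the interval.

**Direct estimators.** Junction: R = J/(J + B), with B the mean of the
two boundary counts (a 5′ss-only mode mirrors RT-qPCR assays probing the
5′ exon–intron border); flagged inestimable when J + B = 0. Density:
R = 1 − d_intron/d_exon, clamped to [0, 1]; consistent when densities
are formed from region-internal fragments over effective (valid-start)
lengths, which is how the estimator benchmark feeds it.

**Filtering and combination.** Genes with steady-state FPKM ≤ 10 are
excluded before estimation. The credible-interval filter retains a gene
iff its 95% interval width is strictly below 0.3 at every nascent time
point. Replicates are combined by averaging posterior means (and
interval bounds); steady-state reads are pooled across replicates before
estimation (averaging per-replicate ratios is available by calling the
estimator per replicate).

## Kinetic statistics

* **AUC splicing speed**: trapezoid over [1.5, 2.5] (width 1) and
  [2.5, 5.0] (width 2.5), normalized by 3.5·R_SS; exactly 1 when all
  nascent ratios equal the steady-state ratio, monotone in each input.
* **Decay proxy**: log₂(weighted mean nascent FPKM / FPKM_SS). Default
  weights are the AUC trapezoid interval weights (0.5, 1.75, 1.25)/3.5
  at 1.5/2.5/5.0 min, chosen for internal consistency with the speed
  statistic; uniform weights are one flag away. Transcripts with any
  nonpositive FPKM are flagged and excluded rather than silently
  log-transformed.
* **Background bound**: m/n = (β − α₁)/(α₁ − α₀), fraction
  (m/n)/(1 + m/n). β defaults to 0.5 — the worst case in which spliced
  intronic RNA decays as fast as mRNA, making the signal's intronic
  fraction maximal. Inputs are validated (α₁ > α₀, β ≥ α₁).
* **Class comparisons**: median log₂ decreases per class and time gap
  with a Welch (unequal-variance) t-test between classes — Welch chosen
  because class variances have no reason to be equal; enrichment
  summaries count adjusted p strictly below 0.05, and empty classes are
  reported missing, not zero.
* **First-order check**: least-squares fit of A(t) = A_SS(1 − e^(−kt))
  (scipy `curve_fit`, positivity bounds, data-driven initialization);
  the relative RMS residual flags trajectories (e.g. flat plateaus above
  steady state) that single-step kinetics cannot produce. At least three
  time points are required.

## Sequence features

The folding backend is pluggable because thermodynamic folding is not
this package's contribution: the built-in default is a Nussinov-style
dynamic program minimizing a proxy energy (GC −3, AU −2, GU −1 per pair,
−1 stacking bonus for directly nested pairs, hairpin loops ≥ 3 nt),
verified against exhaustive enumeration on short sequences; ViennaRNA is
available as `backend="vienna"` when its bindings are importable, and
any callable can be supplied. Proxy energies are comparable with each
other, not with published ΔG values. Features: ΔG per nucleotide for the
whole intron and for the 5′ss-to-branch-point region (intron positions
1..BP inclusive, BP = 1-based position of the branch adenosine), ΔG of
±15 nt windows at the transcript start, stop and 3′ss (truncated windows
are flagged), lengths, PWM log-odds scores in bits (pseudocount 0.5 per
base, uniform 0.25 background, PWMs built from the supplied annotation
set), and overlapping k-mer fractions for k = 1..3. Minus-strand genes
are reverse-complemented before any windowing, and feature extraction is
strand-symmetric by construction (tested).

The intron generator plants GUAUGU / UACUAAC / UAG at annotated
positions (BP-to-3′ss spacer 23 nt, shrinking on short introns; minimum
length 30 nt) and draws the remaining positions i.i.d. with the A+U
probability adjusted so the whole-sequence A+U fraction matches the
requested bias in expectation; the `a_fraction` knob splits the A+U mass
between A and U, which at fixed total A+U reproduces the compositional
regime where A and U frequencies anticorrelate strongly across introns.

## Statistics and learned models

Thirds are floor(n/3) fastest and slowest by score, ties broken by a
stable sort on identifier. "Wilcoxon" is the two-sided Mann–Whitney
rank-sum test with scipy's exact small-sample null. Feature–speed
correlations report raw Pearson p-values and BH-adjusted values side by
side (BH re-application is not idempotent, so only one adjustment pass
is ever applied). The classifier is Gaussian naive Bayes under
stratified 10-fold CV with *pooled* out-of-fold probabilities forming a
single ROC/AUC — pooling chosen over fold-averaging for stability at
small n. The regressor is a 500-tree random forest (default depth,
seeded); feature selection keeps features whose permutation importance
(mean R² drop over 5 shuffles) exceeds 0.01, then refits, and all
reported predictions are out-of-bag — never in-sample. When no feature
passes the threshold all features are kept (the null-data path).

The feature-table generator shifts two informative features by a
separation parameter in SD units; the default 0.52 places the
naive-Bayes AUC near 0.7, the intermediate regime relevant for
stability classification of ncRNA classes, and AUC is monotone in the
separation (tested at 0, 0.52, 2).

## Pipeline

`RunConfig` (YAML-loadable) is the single source of truth: time points
1.5/2.5/5 min plus steady state, two replicates, FPKM > 10 selection,
CI width < 0.3, p < 0.05. Stage outputs are TSVs headed by a comment
line naming the producing stage and the config hash; the manifest
records SHA-256 digests, row counts and the gene funnel
(simulated → FPKM-selected → quantified → CI-retained). All per-stage
seeds are spawned from the single config seed via `SeedSequence`, so a
rerun with the same config is byte-identical (tested). A degenerate
configuration (e.g. CI threshold 0) completes with empty downstream
tables and a recorded warning rather than failing. Problem sizes in the
shipped tests and examples (tens of genes, thousands of fragments,
hundreds of Gibbs iterations) are chosen so a full run stays in the
seconds-to-minutes range; all of them scale up linearly via the config.

## Known limitations

Two isoforms per gene only (no multi-intron genes, no alternative splice
sites); no lariat-derived reads; no sequencing-error or bias model; the
folding proxy is not a thermodynamic model; the decay proxy is a
relative ranking statistic, not an absolute rate in 1/min; synthesis
rates are not deconvolved. The simulator's defaults describe budding
yeast scales and are not calibrated to any particular dataset.
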