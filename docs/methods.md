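# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Synthetic hybrid genomes

**Parental divergence.** Per-SNP allele frequencies for the wild (WC) and
domestic (DC) pools are independent Beta draws with mean p (ancestral
frequency, uniform on 0.05–0.95) and variance F·p·(1−p) — the
Balding–Nichols model. The divergence parameter F is recovered exactly by
the Hudson-style ratio-of-means estimator
Fst = 1 − Σ hw / Σ hb (hw = within-pool, hb = between-pool
heterozygosity); the per-SNP mean-of-ratios Wright estimator is biased
down by construction ((F/2)/(1−F/2) ≈ 0.82 at F = 0.9), so calibration
checks use the ratio-of-means form. The default F = 0.9 reproduces a
deeply diverged species pair whose top markers are fixed differences.

**Map.** 18 autosomes (the cat autosome count) totalling 30 Morgans by
default, equal spans, SNP positions uniform on the cM scale, 1 Mb/cM.
Chromosome span below 1 Morgan is rejected.

**Recombination.** Poisson crossovers at 1/Morgan, positions uniform in
cM, no interference, chromosomes independent. Two mating designs:

- *Pedigree*: F1 (g = 1), F2, or BCg = F1 followed by g − 1 backcrosses to
  the recurrent parent, tracking every transmitted segment exactly.
  E[m] = 0.5^g; the first backcross carries ≈ L junctions on its admixed
  haplotype (L = map length in Morgans).
- *Hybrid isolation*: one pulse then g generations of random mating in a
  large population. The founding pool is mixed at the haplotype level
  (haplotype ancestry iid Bernoulli(m)), so a generation-g gamete lineage
  passes through g junction-forming meioses: ancestry along a haplotype is
  a Poisson(g/Morgan) redraw process with Bernoulli(m) redraws, giving
  E[diploid junctions] = 4·L·m·(1−m)·g exactly — the identity the
  closed-form dater inverts — and pairwise ancestry correlation e^(−g·d),
  the identity the LD dater fits.

Note that junction counts grow monotonically with g only at fixed m
(hybrid isolation); under backcrossing the donor fraction dilutes and
junction counts decay again after the first backcross.

**What the simulator does not emulate.** Mutation and drift within the
parental pools after divergence, crossover interference, sex chromosomes,
genotyping error, phasing error (query haplotypes are truth-phased), and
ascertainment structure of a real array. Consequences worth knowing: at
F = 0.9 the Balding–Nichols tails contain *fully* fixed differences with
zero within-pool variation, so top-Fst AIM panels here reach panel
Fst ≈ 1 and PID ≈ 1 within the wild pool, whereas real arrays retain
residual heterozygosity (real panels show Fst 0.90–0.95 and very small
but non-unit PID). Passing tests therefore demonstrate correctness of the
machinery under a clean neutral model, not robustness to genotyping or
phasing artifacts.

## QC and LD pruning

Filter order is SNP missingness (GENO > 0.2) → sample missingness
(MIND > 0.2) → invariant SNPs, the PLINK convention; each stage's
in/removed/out counts are recorded and must satisfy the arithmetic
identity. Pruning computes squared Pearson correlation of dosages
(composite LD, phase-free) on pairwise-complete samples in 50-SNP windows
stepped by 5, removing the later SNP of an offending pair, repeated until
stable — deterministic and idempotent; windows never span chromosome
boundaries. Coordinates are 1-based inclusive internally; BED output is
0-based half-open.

## Global ancestry

PCA standardizes each SNP by its estimated frequency (center 2p̂, scale
√(2p̂(1−p̂)), mean imputation of missing calls, monomorphic SNPs dropped).

The admixture model is fit by plain EM: monotone in log-likelihood,
convergence at < 1e-4 log-likelihood gain, at most 500 iterations, 3
random starts (best kept), cluster frequencies clipped to [1e-6, 1−1e-6].
Supervised mode pins reference rows of Q to indicator vectors.
Cross-validation masks random non-missing genotype *entries* (5 folds)
and scores squared deviation between the held-out dosage and its
reconstruction 2·Σₖ qᵢₖ fₖⱼ — robust at frequencies near 0/1.

The q-threshold classifier uses q_w < 0.090 (domestic reference) and
q_w ≥ 1.000 with a 5e-4 tolerance (wild reference; printed assignment
values are 3-decimal rounded), everything between is admixed.

f3 subtracts the unbiased target-noise correction p̂(1−p̂)/(aₜ−1)
(aₜ = called allele count) per SNP; the SE is a delete-one-block jackknife
over consecutive 20-SNP blocks.

## Local ancestry

Windows are 20 consecutive SNPs per chromosome; a trailing remainder of at
least half a window is kept, shorter remainders are dropped.

Per-window evidence for each query haplotype is the composite Bernoulli
log-likelihood of its alleles under each reference class's
Laplace-smoothed allele frequencies. This emission is the default because
it is *calibrated*: in weakly divergent windows it yields the moderate
odds that the HMM can overrule. The alternative PC-score emission
(per-window PCA on pooled references, homoscedastic Gaussian on leading
scores with model-based binomial variance; `emission="pca"`) is retained,
but in its natural per-class-variance form it inflates ambiguous windows
into decisive calls — in a 40-reference hold-out re-assignment it
confidently miscalled one window for ~10% of individuals, which the
calibrated emission resolves to a clean self-check.

Smoothing is a two-state forward–backward pass per chromosome with switch
probability 1 − e^(−r·ΔcM) between adjacent windows, r = 0.01/cM by
default — a weak prior that suppresses isolated flips without erasing
true short tracts. Hard calls are the posterior argmax with a no-call
margin of 0.1 on the posterior difference. The diploid switch count S
sums haplotype-level transitions over both haplotypes and all chromosomes,
bridging no-calls (the nearest called neighbors are compared); with phased
input this is the only self-consistent definition of a per-individual S.

## Dating

**Switch-count dating.** For every candidate g (grid 1–30 by default) the
generative model simulates switch-count distributions for individuals
whose realized ancestry fraction lies within ±0.05 of the observed m̂
(rejection sampling, cap 50× oversampling, tolerance doubled with a
warning if exceeded). For speed these simulations run at reduced
resolution: the ancestry process restricted to an ordered set of points is
exactly Markov under both mating models, so states at 3 points per window
are propagated vectorized and majority-voted into window calls; a test
confirms the resulting distributions match the exact tract-level engine.
The estimate is the grid argmax of the ±1-count kernel likelihood
(kernel widened if the observed S falls between supports), with a central
95% interval from the normalized likelihood; S above every simulated
support returns the top of the grid with a saturation flag.

The closed form ĝ = S/(4·L·m·(1−m)) is exact for *true junction counts*
under hybrid isolation (tested against forward simulation within 10%).
Fed window-resolution switch counts it is conservative (biased young),
because tracts shorter than a window are invisible; the empirical method
is immune since its reference distributions are built at the same
resolution. This is why the empirical method is primary.

**Weighted LD.** For every same-chromosome SNP pair at distance
d ∈ [0.005, 0.3] Morgans (1 mM bins), the sample covariance of dosages
across the admixed cohort is weighted by (p_WC − p_DC) at both SNPs and
bin-averaged. The lower cutoff guards against background LD. The curve is
fit by bounded nonlinear least squares to A·e^(−n·d) + c (A, n ≥ 0),
weighting bins by √pair-count; uncertainty is a delete-one-chromosome
jackknife. Significance requires *both* n̂ and A to be jackknife-positive
(one-sided normal, p = max of the two, α = 0.01): with amplitude ≈ 0 the
decay rate is unidentifiable and its jackknife SE collapses, so a
rate-only test misfires on pure noise.

Years = g × generation time (default 2 years); calendar year =
sampling year − years; rounding only at presentation.

## Scans

Window tails: the top ⌊tail·W⌋ windows per direction (boundary ties
included; degenerate distributions yield an empty set with a warning),
adjacent selected windows merged into regions. The Fst outlier scan
compares per-SNP Weir–Cockerham θ between admixed and parental samples to
a parametric null: Balding–Nichols frequency pairs at the genome-wide
(ratio-of-sums) mean θ around ancestral frequencies resampled from the
observed pooled frequencies, Hardy–Weinberg genotype counts at the
observed sample sizes. Upper-tail p-values carry an add-one correction;
Benjamini–Hochberg q ≤ FDR (0.05) flags outliers. A mean θ ≤ 0 aborts the
scan (groups indistinguishable). Flagged SNPs become ±100 kb regions
(about the scale of background LD in domestic cats), clipped at
chromosome bounds and merged; gene overlap honors BED 0-based half-open
and GFF3 1-based inclusive conventions at ≥ 1 bp.

## AIM panels

Per-SNP scores: Weir–Cockerham θ (two populations, sample-size aware,
negative estimates clipped to 0), Rosenberg I_N (natural log, 0·ln 0 = 0,
maximum ln 2 for a fixed biallelic difference), and pooled expected
heterozygosity. Selection takes the top n by the chosen criterion among
LD-pruned SNPs, breaking ties by the other criterion's rank and then map
order, so panels are bit-reproducible. Panel evaluation refits K = 2
*unsupervised* (pinning the references would force every reference
wildcat to q_w = 1.000 and void the minimum-reference misclassification
rule, whose whole point is that reduced panels let reference minima slip
below 1.000); the wild cluster is oriented by the labelled references
afterwards. Misclassified hybrids are those whose panel q_w reaches the
minimum reference-wildcat q_w; the percent detected is
100·(1 − misclassified/total), and both counts are reported so either
reading of the detection rate can be recovered. PID and PIDsib use the
standard biallelic genotype-match products on wild-pool frequencies;
PIDsib ≥ PID always.

## Problem sizes and determinism

Default study-scale runs use 20k SNPs, 57 + 44 reference individuals and
45 admixed cats — the shape of a realistic array study and comfortable on
one CPU core (the full validation suite runs in about a minute). The
switch-model grid (1–24 in recovery checks) and its 300 conditioned
replicates per g are accuracy/speed compromises that callers can raise.
All randomness flows from explicit seeds (the pipeline fans one seed into
fixed per-stage offsets); identical seeds give byte-identical outputs.

## Known limitations

Two ancestries only; input haplotypes must be phased upstream (the
simulator provides truth phase); the LD dater assumes a single pulse
(continuous admixture yields a midpoint-like n̂); the outlier scan's
parametric null ignores locus-to-locus heterogeneity in divergence, so it
is calibrated for the neutral no-outlier case rather than powered for
subtle selection; gene-set enrichment is out of scope (the module stops
at gene lists).
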