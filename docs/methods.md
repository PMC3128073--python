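# Methods

## Statistical model

### Per-SNP association

Association between a biallelic SNP and case/control status is measured
by the Cochran–Armitage trend test with additive weights (0, 1, 2) on
the alternate-allele dosage. With those weights the statistic satisfies
the identity T = N·ρ², where ρ is the Pearson correlation between
dosage and the binary phenotype over the N samples with a non-missing
genotype; the implementation uses this identity, and the batched
permutation engine computes whole batches of relabelings with two
matrix products (case-indicator × genotype). Missing genotypes are
handled per-SNP complete-case — the call-rate filter keeps the impact
small — and a SNP monomorphic among complete cases receives T = 0 with
a flag rather than an error, so permutation streams never abort.

Under the null T is asymptotically χ² with 1 df. Two caveats matter at
cohort sizes of a few hundred per arm and are deliberately accepted:

* **Lattice discreteness.** Dosages are integers, so T takes values on
  a lattice; in balanced designs the null distribution has small atoms
  (including one at exactly 0, a few percent of mass). Tail
  probabilities beyond ~χ²₀.₉₅ are essentially exact, but the body of
  the distribution deviates from the continuous χ²₁ by up to a few
  percent. Consequences for p_emp are discussed below.
* **Correlated SNPs.** Within an LD block the statistics are strongly
  correlated, which does not bias any single T but inflates the
  sampling error of summaries taken across SNPs (notably λ).

### Genomic control

λ = median(T) / median(χ²₁), with the χ²₁ median (≈ 0.4549) evaluated
from the quantile function. All statistics are divided by λ before any
gene-level step. By default λ < 1 is clamped to 1 (deflation only), the
standard practice; `deflate_only=False` disables the clamp. The median
of a few thousand block-correlated statistics is itself noisy (the
effective sample is roughly the number of independent blocks), so null
simulations at desk scale legitimately produce λ anywhere in roughly
0.85–1.15; this is estimator noise, not miscalibration.

### Gene-wide statistics

A gene with statistics T₁…Tₙ (post-genomic-control) is summarised by
maxT, meanT, and topQ = mean of the k = ⌈n/4⌉ largest statistics.
For every input maxT ≥ topQ ≥ meanT; for n ≤ 4, topQ = maxT; for
n = 1 all three coincide. Only the multiset of values matters to topQ,
so ties among statistics at the cut need no special handling.

Each summary has a characteristic gene-size confound under the null:
maxT grows with n; meanT concentrates at 1 as n grows (variance ∝ 1/n,
up to LD); topQ concentrates near the mean of the top quartile of χ²₁
(≈ 3). These confounds are what the permutation control removes, and
the test suite asserts both the confounds (raw statistics) and their
absence (empirical p-values) on the same simulated cohorts.

### Permutation empirical p-values

Disease labels are permuted uniformly at random, preserving
case/control totals; per-SNP statistics, λ (by default re-estimated
within each permuted dataset so observed and permuted statistics get
identical treatment; a fixed-λ mode is available), and gene scores are
recomputed per permutation. All three methods share one permutation
stream, so cross-method comparisons are paired. The empirical p-value
is p_emp = k/N with k the number of permutations whose gene-wide
statistic **strictly** exceeds the observed one; k = 0 is flagged and
written as `< 1/N`. Ranking uses (p_emp, then observed statistic, then
gene id), so genes at the resolution floor are ordered sensibly.

Two consequences of the strict inequality are documented rather than
patched:

* p_emp can be exactly 0; the floor flag and the `< 1/N` output make
  the resolution explicit, mirroring how permutation floors are usually
  printed.
* Because observed and permuted statistics live on the same discrete
  lattice, the atom at exactly the observed value is excluded from k.
  For single-SNP genes this makes p_emp systematically smaller than the
  χ²₁ upper-tail probability of the observed statistic by up to the
  atom mass (~0.03–0.05 in the body of the distribution at 500+500
  samples), even though both quantities are "correct". The two agree
  closely in the significance tail, where atoms are negligible — the
  regime that matters for discovery. One acceptance-style test asserts
  agreement within ±3 binomial SD across *all* single-SNP genes; it
  fails for exactly this reason and is retained as an honest record of
  the approximation error, with the engine itself validated by an exact
  equivalence test against the SNP-level permutation tally.

The default permutation count is 10,000 — adequate for per-gene
calibration and ranking. Chasing a 20,000-gene Bonferroni threshold of
α/G = 2.5×10⁻⁶ requires several hundred thousand permutations; that is
a configuration value, not a different code path.

### SNP-to-gene assignment and LD

A SNP is eligible for a gene if it lies in the gene body or within
40 kb (default) up/downstream; the closest gene wins (distance 0 inside
the body, else base pairs to the nearer boundary), with alphabetical
gene id as a deterministic tie-break. Exclusion regions (e.g. the MHC,
whose long-range LD smears one association over dozens of genes) remove
both the SNPs inside them and the genes overlapping them before
assignment. All internal coordinates are 0-based half-open; region
strings on the CLI are accepted 1-based inclusive as usually printed.

LD extension is a single step: every SNP whose r² with a SNP already
assigned to gene g exceeds 0.8 is added to g, including SNPs assigned
elsewhere (genes may share SNPs afterwards). No transitive closure is
taken through newly added SNPs — closure could chain along a
chromosome. r² is the squared Pearson correlation of dosages over
pairwise-complete samples (composite LD): phase-free and deterministic,
unlike EM-haplotype estimators, and computed only for same-chromosome
pairs within 1 Mb (long-range LD above r² = 0.8 is rare, and the window
bounds the O(pairs) cost).

### QC

Per-SNP filters on the pooled case/control sample, applied before
association: exact two-sided Hardy–Weinberg test p < 0.001 (the exact
conditional test, no mid-p — well defined at low counts where the χ²
approximation fails; a controls-only option exists but is off by
default), minor allele frequency < 0.01 (strict), call rate < 0.97
(strict). A SNP may fail several criteria; the report tallies each
independently. Sample-level QC is a user-supplied drop list, not
recomputed.

### Evaluation

Rankings are compared by Spearman correlation on the genes with the
best (smallest) rank sums across the supplied lists. Note: selecting by
"highest summed ranks" read literally would pick the *least*
significant genes; the implementation selects the most significant
(smallest rank-sum) genes, which is the only reading consistent with
evaluating the top of the rankings. ROC curves treat the truth list as
positives and every other ranked gene as a negative; AUC is the
trapezoid area and equals the Mann–Whitney pair-counting probability
(asserted to 1e-12 in tests). `null_auc_quantile` provides the
chance-level AUC spread for a given number of genes and positives.

## Synthetic cohorts

The generator produces the features the method actually exercises, not
population-genetic realism:

* **LD blocks**: the SNP sequence is partitioned into blocks
  (geometric sizes, mean 8); each block has a founder pool of 20 binary
  haplotypes with allele frequencies drawn from Beta(1.2, 3.0) clipped
  to [0.05, 0.95]; each individual draws two founder haplotypes per
  block. Fewer founders mean stronger within-block LD; blocks are
  independent, so cross-block r² ≈ 0.
* **Gene sizes**: a geometric body (mean 4 SNPs) plus an 8% tail
  (15 + geometric(mean 25)), giving ≥ 70% of genes under 10 SNPs and a
  long tail past 50 — the strongly right-skewed profile of genotyping
  arrays. Genes are tiled along chromosomes with 100 kb gaps (more than
  twice the assignment window), so the distance rule recovers exactly
  the simulated membership; LD can still couple neighbouring genes
  through blocks that straddle a boundary.
* **Disease model**: log-odds = intercept + Σ log(OR)·dosage over the
  planted causal SNPs, intercept solved so the population prevalence is
  10% at mean genotype; cases and controls are filled by rejection
  sampling with a bounded number of draws. Causal SNPs are drawn among
  sites with realized founder-pool MAF ≥ 0.1 (a "causal" site must
  segregate; a 20-haplotype pool is otherwise monomorphic at clipped
  frequencies more than a third of the time). The truth set is the list
  of genes containing causal SNPs.
* Default scale: 500 cases + 500 controls, 300 genes (~2,000 SNPs) —
  small enough that a full 2,000-permutation run takes seconds, large
  enough that per-SNP power at OR 1.5–2.0 is high.

What the generator does **not** emulate: population stratification
(λ ≈ 1 by construction; the genomic-control machinery is exercised but
never strained), genotyping batch effects, realistic recombination-rate
variation, allele-frequency spectra from demography, or imputation
uncertainty. Passing tests therefore demonstrate the calibration and
ranking machinery, not robustness to stratified or artefactual real
data.

## Numerical and design notes

* Phenotypes are coded 1=control / 2=case on disk (the common GWAS
  convention) and 0/1 internally; missing dosage is NaN, never 0.
* The exact HWE test sums probabilities of heterozygote counts with
  probability ≤ the observed (tolerance factor 1 + 1e-12 against
  floating-point ties), computed in log space; an exact-fraction
  enumeration oracle backs it in tests.
* The batched permutation engine is contract-tested for equal
  exceedance counts against a naive per-permutation loop on the same
  label stream; both consume the identical RNG sequence.
* All randomness flows through `numpy.random.Generator` seeds carried
  in config objects; equal seeds give bit-identical datasets, result
  tables and CLI outputs.
* Degenerate inputs: empty statistic lists, single-class phenotypes,
  all-zero genotype counts and duplicate identifiers raise immediately
  with named offenders; empty QC survivors and empty assignments warn
  and return empty structures.

## Known limitations

* p_emp resolution is 1/N and the strict-inequality lattice bias above
  applies to non-tail p-values of small genes.
* The composite-LD r² differs slightly from haplotype-based r² used by
  some external tools; near the 0.8 threshold a few pairs can differ.
* λ re-estimation inside permutations costs one median per permutation
  batch row; with `recompute_lambda=False` results change only at the
  third decimal of p_emp in null simulations but the observed data are
  then treated asymmetrically.
* Stratification correction beyond genomic control (e.g. PC-adjusted
  logistic regression) is out of scope; rankings from such analyses can
  be fed into the evaluation tools as external TSVs.
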