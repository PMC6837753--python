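# Methods

`ithbench` packages the statistical machinery needed to ask two questions
about intra-tumor heterogeneity (ITH) inferred from a single tumor/normal
whole-exome sample: *do different subclonal reconstructions agree with
each other?* and *does any ITH summary carry prognostic information beyond
chance?* Because real cohorts of this kind (consortium WES with restricted
raw calls) cannot ship with a software package, every stage is exercised
against a synthetic cohort generator with known ground truth.

## Generative model of the synthetic cohort

Each simulated tumor carries a clone tree collapsed to its cancer cell
fractions (CCFs): one truncal clone at CCF 1 and `K − 1` subclones with
CCFs drawn uniformly and rejection-sampled until all pairwise gaps of the
sorted CCF vector reach `min_ccf_separation` (default 0.1, at most 0.5).
Mutation counts per clone follow a symmetric Dirichlet(5)–multinomial with
every clone receiving at least one mutation.

Read counts follow the standard allele-counting model. A mutation at
CCF `c`, multiplicity `m` on `CN_t` total tumor copies, in a sample of
purity `ρ` with diploid normal contamination has expected VAF

    E[VAF] = ρ·m·c / (ρ·CN_t + (1 − ρ)·2)

Tumor and normal depths are Poisson(mean coverage) truncated at one read
(zero-depth loci have no defined VAF and do not occur in practice in
callable regions); alt counts are Binomial(depth, VAF), with a fixed
per-read error rate of 0.001 in the normal. A random fraction of
mutations (drawn from `cna_fraction_range`) sits on copy-number-altered
segments with `CN_t ∈ {1, 3, 4}`; multiplicity is uniform on
`{1, …, ⌈CN_t/2⌉}`. Defaults — 100× coverage, purity 0.3–0.95, 1–5
clones, 50–300 SNVs per sample — describe a moderate-coverage WES cohort.

Two nested mutation views emulate the two release levels of consortium
variant calls: the *protected* view is everything the simulator emitted;
the *public* view keeps variants with strong evidence (≥8 alt reads or
VAF ≥ 0.1) and then retains each independently with probability 0.9.

Survival is exponential proportional hazards on the z-scored latent ITH
features of the ground truth: `T ~ Exp(h₀·exp(βᵀx))` with uniform
censoring on `(0, horizon)`; `h₀ = 0.02` per month and a 120-month
horizon give event fractions (~55–75% depending on β) typical of
oncology cohorts. β = 0 by default, so survival carries no ITH signal
unless a study explicitly injects one; the generator is deliberately
extensible to Weibull hazards but the exponential case is the simplest
generator consistent with the proportional-hazards assumption of the
evaluation models.

What the generator does *not* emulate: sequencing error beyond the flat
normal-sample rate, strand bias and mapping artifacts, subclonal copy
number, phylogenetic structure beyond the CCF constraints, and the
correlated failure modes of real reconstruction tools. Passing tests
therefore demonstrate correctness of the *evaluation machinery* under a
clean generative model, not robustness of ITH inference on real tumors —
the latter being precisely the open question this kind of benchmark
exists to probe.

## Variant filtering

The protected set applies, per caller: FILTER-status rules ("PASS" for
VarScan2 and SomaticSniper; "PASS" or "panel_of_normals" for Mutect2;
"Tier1"–"Tier5" for MuSe); removal of variants with 1000 Genomes or ExAC
frequency above 0.01 unless reported in COSMIC (missing frequencies count
as zero); and a coverage rule — normal: ≥6 reads with ≤1 alt read or
normal VAF < 0.01; tumor: ≥8 reads with ≥3 alt reads or tumor VAF > 0.2.
Both per-sample clauses must hold; the inequalities on the VAF escapes
are strict, so a normal VAF of exactly 0.01 and a tumor VAF of exactly
0.2 both fail. Zero depth fails rather than raising. The public set
applies only indel removal before taking the union of the four callers'
SNVs. Duplicate calls of one mutation collapse to the record with the
highest tumor depth.

## Reconstruction representation and baseline

A reconstruction is a partition of mutations into clones with cellular
prevalences. The standard post-filter keeps clones with ≥5 SNVs, unless
no clone reaches 5, in which case all are kept (small samples would
otherwise be discarded entirely).

The *baseline reconstructor* is a deliberately simple reference method —
a stand-in, not a reimplementation of any published tool: CCF estimates
are assigned to the nearest center of a fixed 0.1-wide grid, and occupied
bins with fewer than 5 members are merged into the nearest heavier bin
(ties toward the heavier bin); each surviving bin becomes a clone whose
prevalence is the mean of its members. It is isolated behind one function
so any external tool's output can replace it through the
`assignment.tsv`/`clones.tsv` import surface.

## ITH features

Five features summarize a post-filtered reconstruction: number of clones
`J`; fraction of SNVs in the major clone (the clone with the most SNVs;
ties broken by higher prevalence, then clone id); minimal cellular
prevalence over clones (a flag restricts the minimum to non-truncal
clones, default off, since either reading of "minimal prevalence of a
subclone" is defensible); Shannon index `−Σ pₖ ln pₖ` of the clone-size
distribution in natural log; and the prevalence of the major clone. The
MATH score is `100 · 1.4826 · MAD(VAF) / median(VAF)` with the plain
median absolute deviation and the usual normal-consistency constant; it
is invariant under positive scaling of the VAFs. Squared-feature
augmentation doubles a design matrix with elementwise squares to admit
quadratic risk relations. Immune-signature scores are inverted against
the cohort maximum (`inv_s_i = max_j s_j − s_i`) so they co-vary with
purity and stay nonnegative; the expression normalization that produces
the raw scores is out of scope and assumed done upstream.

## Agreement metrics

* **score1B** `(J₁ + 1 − min(J₁ + 1, |J₂ − J₁|)) / (J₁ + 1)` compares
  clone counts; 1 iff equal, 0 once the counts differ by J₁ + 1.
* **score1C** is the exact 1-Wasserstein distance between the two
  weighted CCF distributions (point mass per clone, weight = share of
  mutations), computed from the CDFs, not sampled. Consensus-style
  reconstructions without prevalences are rejected.
* **score2A** restricts both reconstructions to their common mutations
  (at least 2, otherwise the pair is non-comparable), builds binary
  co-clustering matrices, and averages three rescaled agreement scores:
  Pearson and Matthews correlation over all N² vectorized entries
  (diagonal included — required so the identity-matrix bad scenario
  differs from the all-ones one) and the V-measure of the predicted
  partition against the reference partition (natural-log entropies; a
  component with zero reference entropy counts as 1). Each raw score is
  rescaled against the better of two degenerate predictions — all
  mutations in one clone, every mutation its own clone — via
  `(raw − worst) / (1 − worst)` clipped to [0, 1]; when the worst
  scenario itself scores ~1 the rescaling is degenerate and collapses to
  an indicator.

Degenerate-statistic conventions: a prediction whose co-clustering
matrix is identical to the reference scores 1 on every component even
where the statistic is formally undefined (identical constant matrices),
so self-agreement is always 1; any other zero-variance or
zero-denominator case scores 0, because a degenerate prediction that
differs from the reference carries no agreement information.

score1B and score2A are asymmetric in the reference/prediction roles, so
tabulation computes every ordered method pair; per-pair medians across
samples summarize a cohort, with failing samples excluded and logged.

The correlation screen reports pairwise Pearson r between per-sample ITH
measures and confounders (purity, mutation load, fraction of altered
copies) on pairwise-complete observations, with two-sided p-values from
the exact t transform and a Benjamini–Hochberg mask at FDR 0.05 across
all off-diagonal pairs jointly. Constant columns and pairs with fewer
than three complete observations are excluded rather than reported.

## Survival evaluation

The ranking SVM minimizes `wᵀw + α Σ_(i,j)∈P max(0, 1 − (wᵀxᵢ − wᵀxⱼ))²`
over comparable pairs `P = {(i, j): yᵢ ≥ yⱼ, δⱼ = 1}`. Features are
z-scored internally; the objective is strictly convex, so the minimizer
is unique, and L-BFGS with the analytic gradient is run to projected
gradient 10⁻⁶. α defaults to 1, matching the default of the widely used
off-the-shelf solver for this model; pair enumeration is explicit, which
is exact and entirely adequate at cohort sizes of a few hundred to a few
thousand. Predicted risk is `−wᵀx̃` — the SVM scores longer survivors
higher, and negation aligns the score with the risk convention of the
concordance index.

The concordance index counts, over comparable pairs, the fraction where
the shorter survivor received the higher risk, ties counting ½. Its
standard error uses the asymptotic Noether/U-statistic estimator built
from per-patient concordant/discordant pair counts (ties split evenly),
and the one-sided upper-tail z-test compares CI to the chance value 0.5.
The estimator is cross-checked against a permutation null in the test
suite. Evaluation is 5-fold cross-validation with a seeded shuffle and no
stratification; per-fold p-values are combined with Fisher's method
(−2Σln p on 2k df) and corrected across settings with
Benjamini–Hochberg; significance stars in the benchmark tables mark
BH-adjusted p below 0.05/0.01/0.001. Paired per-fold CI comparisons
between two feature sets use a two-sided paired t-test; identical fold
vectors return p = 1.

**Known limitation.** Fisher's method assumes independent p-values, but
cross-validation folds share training data: under a β = 0 null the
fold-level one-sided test is well calibrated (~5% rejections at nominal
0.05) while the Fisher-aggregated test over the five dependent folds is
anti-conservative. This is a property of the aggregation procedure
itself; the package reports both the per-fold and the aggregated
p-values so users can judge significance accordingly, and the
calibration suite asserts the fold-level rate.

Clinical covariates are screened in three steps: one-hot levels kept only
when at least 50 patients carry the level *and* at least 50 carry another
level (both groups must be estimable); numeric variables kept only when
observed for every patient; survivors kept only when the Wald p-value of
a univariate Cox proportional-hazards fit (Breslow ties, as in the
underlying library) passes Benjamini–Hochberg at FDR 0.05.

## Numerical and design choices

* Tolerances: rank-SVM gradient 10⁻⁶; degenerate-rescaling guard 10⁻¹²;
  oracle-equivalence assertions 10⁻¹⁰.
* Tie-breaks are deterministic everywhere (major clone by size, then
  prevalence, then id; baseline bin merges by distance, then size, then
  index), so all outputs are byte-identical under fixed seeds.
* Folds with no comparable pair, or with zero-variance concordance (no
  defined test), are excluded from aggregation with a warning rather
  than poisoning downstream statistics.
* The combined survival design concatenates each clone-resolving
  method's 5 features plus the single MATH column; with five methods
  this is the 26-column model evaluated alongside per-method models.
* Problem sizes in the shipped tests and the reproduction script —
  cohorts of 10–200 samples, survival calibration at n = 500 with 50–100
  replicates — were chosen as the smallest sizes at which the asserted
  properties are stable, keeping the whole suite runnable on a laptop in
  minutes.

## Limitations

Beyond the generator simplifications and the Fisher caveat above: the
baseline reconstructor assumes multiplicity 1 when inverting VAFs to
CCFs, biasing CCF estimates upward on amplified loci; the clinical
screen fits one covariate at a time and therefore inherits the usual
hazards of univariate screening; and nothing here runs the external ITH
tools themselves — their outputs enter through the two-table import
surface.
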