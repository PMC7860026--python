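# Methods

`aimpanel` designs ancestry-informative SNP (AIM) panels from pooled
allele frequencies and assigns individual genotypes to honey bee
subspecies and evolutionary lineages. This note records the models,
estimators, defaults and numerical conventions the package uses, and
what its synthetic data does and does not emulate.

## Population model and synthetic data

European *Apis mellifera* diversity is hierarchical: four deeply
diverged evolutionary lineages (A, C, M, O), each containing one or
more recently diverged subspecies, each sampled as one or more
population pools. The simulator (`aimpanel.simulate`) drifts ancestral
allele frequencies down this tree under the Balding–Nichols Beta model:
given a parent frequency *p* and a divergence parameter *F* ∈ (0, 1),

    child ~ Beta(p(1−F)/F, (1−p)(1−F)/F),

so E[child] = *p* and Var[child] = *F·p(1−p)*. This is the minimal
hierarchical drift model in which the per-level divergence parameter is
recoverable from the emitted frequencies. Defaults: `f_lineage = 0.15`,
`f_subspecies = 0.05`, `f_pool = 0.02` — deep lineage divergence with
shallow structure below it. Ancestral frequencies are drawn uniformly
on (0.05, 0.95) so that sites segregate.

Pool sequencing is emulated as Poisson read depth (default mean 50×
per pool per SNP — desk scale; real pool-seq studies reach far deeper
coverage, which only narrows the binomial noise) with reference-read
counts binomial in the pool's true frequency. Individuals are
Hardy–Weinberg draws: alt-allele dosage ~ Binomial(2, 1 − p_ref).
Null alleles — markers that systematically produce no genotype call in
some subspecies, e.g. through probe-site deletions — are modelled as an
all-or-none subspecies × SNP mask, with a default per-subspecies null
rate of 0.13 chosen to reproduce a mean individual call rate of 0.87.

The default tree (`reference_config()`) mirrors the reference study
design: 22 pools, 14 subspecies, 4 lineages, with lineage A represented
by a single pool.

What the simulator does **not** emulate: linkage disequilibrium (sites
are independent), sequencing or mapping error, admixed or introgressed
individuals, within-pool relatedness, and partially penetrant null
alleles. Passing tests therefore demonstrate that the estimators and
the selection/assignment logic behave correctly under idealised
hierarchical drift — not that any particular accuracy will be attained
on real genotype data, where class overlap, mislabelled references and
admixture dominate the error budget.

### Divergence-parameter recovery

Between two sibling demes that each drifted with parameter *F* from a
common parent, the heterozygosity-form pairwise F_ST has expectation
≈ *F*/2, because the two-deme mean frequency absorbs half of the
between-deme variance (E[H_T] = 2p(1−p)(1−F/2), E[H_T−H_S] = F·p(1−p)).
Recovery checks therefore use the doubled ratio-of-means estimator

    F̂ = 2 · Σ(H_T − H_S) / Σ H_T

(`simulate.estimate_f_between`), which is accurate to about 1% at 5000
independent SNPs and is asserted within ±20% in the test suite.

## F_ST branch of marker selection

Per SNP and pool pair, F_ST uses the heterozygosity (Nei) form on pool
frequencies:

    p̄ = (p₁+p₂)/2,  H_T = 2p̄(1−p̄),
    H_S = (2p₁(1−p₁) + 2p₂(1−p₂))/2,  F_ST = (H_T − H_S)/H_T,

with the convention F_ST = 0 when H_T = 0. A fixed difference gives 1,
identical frequencies give 0, and a SNP fixed in one pool and absent in
the other 21 pools of a 22-pool design sums to exactly 21 over the
focal pool's pairs — the bound the selection exploits.

Two site-filter settings control which pairs contribute: a pair is
eligible at a SNP iff both pools reach `min_depth` and the pair's
combined minor-allele read count reaches `min_minor_count`; ineligible
pairs contribute 0 to the sum. Defaults: loose = (depth ≥ 10, minor ≥
2), stringent = (depth ≥ 30, minor ≥ 4). The loose pass surfaces rare
population-specific variants at the cost of call quality; the stringent
pass favours reliable sites. Both are configurable and recorded in the
panel manifest.

Selection walks each pool's descending summed-F_ST ranking (ties broken
by (chrom, pos)), stringent quota first (default 80), then loose
(default 20), skipping SNPs already taken by any pool or the other
setting and continuing down the ranking, so every pool contributes
exactly 100 unique SNPs and 22 pools yield exactly 2200. Pools are
processed in table order; panel content can depend on that order only
at exact score ties. A pool whose eligible SNPs run out raises an
explicit shortfall error naming the pool. On a degenerate single-pool
table there are no pairs; eligibility then reduces to the depth filter
and all sums are 0.

## PCA branch of marker selection

Pools are observations, minor-allele frequencies are variables. The
minor allele of a SNP is resolved per pool subset (the allele with mean
frequency ≤ 0.5; ties go to the alternate allele); undefined cells
(zero depth) are mean-imputed per SNP, and SNPs undefined in every
subset pool are dropped at that level only.

The PCA is scaled: columns centred and scaled to unit variance
(zero-variance columns dropped), eigenvalues taken from the correlation
structure so that Σλ equals the retained column count and at most
(pools − 1) eigenvalues are nonzero. Significant components follow a
Kaiser-style rule — λ strictly above the mean eigenvalue, with a
fallback to PC1 when all eigenvalues tie. The contribution of SNP *j*
to PC *k* is `100 · coord(j,k)²/λ_k` (coord = correlation of the
variable with the component), which sums to 100 over SNPs per PC;
contributions across the significant PCs are aggregated with
eigenvalue-share weights so dominant axes dominate selection.

Hierarchical selection runs the global level (all pools) first, then
each lineage on its own pool subset, taking the top-quota SNPs per
level and skipping SNPs selected earlier. Default quotas follow the
reference design: global = 300, M = 200, O = 600, C = 1100 (lineage A
has a single pool, hence no within-lineage level). Combining both
branches with cross-branch deduplication (PCA first, configurable)
yields exactly 4400 SNPs on a 20 000-SNP input.

### Planted-marker recovery experiment

Recovery of known lineage-diagnostic markers is validated on a designed
experiment: a balanced 16-pool tree (4 lineages × 2 subspecies × 2
pools) with modest neutral divergence (f_lineage = 0.05) and 50 planted
SNPs whose lineage frequencies are separated by a gap of 0.8. In that
regime the planted SNPs are unambiguously the strongest AIMs and ≥ 90%
of them appear in a global selection of quota 50. Under strong neutral
divergence (f_lineage = 0.15) many *neutral* SNPs drift to near-fixed
lineage differences and legitimately outrank planted ones — recovery is
then not a meaningful measure of selection quality — and a lineage
represented by a single pool contributes no significant axis, so its
planted markers are invisible to a pool-level PCA by construction.

## Classification

Panel genotypes are one-hot encoded with four explicit states per SNP
(hom-ref, het, hom-alt, missing); missingness is deliberately a
first-class state rather than being imputed, because subspecies-specific
null alleles make systematic missingness informative. The reference set
is shuffled and split 70/30 with floor rounding (1988 samples → 1391
train / 597 test). Candidate models (random forest, logistic
regression, RBF-kernel SVM, linear SVC, all with scikit-learn defaults
and a fixed seed) are compared by stratified k-fold cross-validation
(default k = 10, degrading with a warning when the rarest class is
smaller); the best mean accuracy wins, ties broken by lower SD.

Margin-based winners are wrapped in cross-validated calibration fitted
on training data only. The default method is **isotonic**: with a
multi-way one-vs-rest problem, sigmoid (Platt) calibration leaves every
negative class a non-negligible probability, and after row
normalisation the top-class probability is capped well below 1 even
for unambiguous samples — which silently turns a 0.9 rejection
threshold into "reject everything". Isotonic calibration preserves
near-0/near-1 probabilities and reproduces the expected distribution
(median top-class probability ≈ 1 on separable data). The method is a
`fit()` argument and is recorded in the model metadata.

Assignment takes the argmax class when its probability reaches the
rejection threshold τ (default 0.90) and otherwise reports
`unassigned`; exact argmax ties go to the first class in column order.
Raising τ never decreases the unassigned count and never increases the
number of misclassified-among-assigned samples; both are asserted in
the test suite. Lineage-level accuracy figures use argmax assignment
(τ = 0), since rejection moves borderline samples to `unassigned`
rather than misclassifying them.

## Evaluation conventions

Confusion matrices keep raw counts; unassigned predictions are tallied
per true class and excluded from row percentages. When a threshold is
active, accuracy and misclassification denominators are
*assigned-only*; without one they are over all test samples — reports
state which denominator applies to avoid the 3.8%-of-total versus
3.9%-of-assigned ambiguity. Percentages are rounded to one decimal in
reports. Call rate is the per-sample fraction of non-missing genotypes
with per-subspecies means. The 2-D embedding delegates to
scikit-learn's t-SNE (seeded, hence deterministic); label-outlier
flagging is an automated k-NN rule (default k = 10) on Hamming distance
over genotype states in which a missing call matches nothing, flagging
a sample when the majority label of its nearest neighbours differs from
its own — a reproducible replacement for visual outlier removal.

## Problem sizes and runtimes

The quota-arithmetic checks use the full reference design at 20 000
SNPs (a few seconds). The lineage-accuracy check uses 4 lineages × 2
subspecies × 100 individuals at 2000 SNPs with a 300-SNP global panel.
The end-to-end subspecies check uses the 22-pool reference design at
4000 SNPs, 25 individuals per pool and a 900-SNP combined panel, where
held-out subspecies accuracy exceeds 95%. These sizes were chosen as
comfortable desk-scale designs; all pipeline stages are vectorised and
the complete test suite runs in well under a minute.

## Known limitations

- The exact site filters behind the upstream pooled F_ST tool's "loose"
  and "stringent" options are not published; the defaults here encode
  the qualitative trade-off only.
- Pool-level PCA cannot select markers for a lineage represented by a
  single pool (no within-lineage axis exists).
- Isotonic calibration can be overconfident with very small training
  classes; sigmoid remains available via `fit(..., calibration="sigmoid")`.
- Classification is closed-set plus rejection: admixture proportions
  and truly novel populations are out of scope, though consistently low
  probabilities against all classes are a practical novelty signal.
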