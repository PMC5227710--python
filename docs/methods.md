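# Methods

## The full genetic model

The trait of individual *k* in ethnic group *h* (records stacked over the
two examinations, treated as replications) is modelled as

y_hk = mu + s_k + Σ_i (x_a a_i + x_d d_i) + Σ_ij (x_aa aa_ij + x_ad ad_ij +
x_da da_ij + x_dd dd_ij) + e_h + Σ_i (x_a ae_ih + x_d de_ih) + (epistasis ×
ethnicity terms) + ε_hk,

where the sex block s_k and all locus main/epistasis effects are fixed,
and ethnicity plus every locus-by-ethnicity class is random with a
class-wise variance (zero-mean normal levels).  Codings: x_a = +1/0/−1 for
the major homozygote / heterozygote / minor homozygote, x_d = 1 for the
heterozygote, and the four digenic epistasis codings are the products of
the two loci's a/d codings (equivalent to the genotype-by-genotype
enumeration; verified exhaustively in the tests).  The incidence column of
an interaction level is the genetic coding times the group indicator, so a
block's four columns sum to the main-term column.  Residuals are i.i.d.
normal, independent across replicate records.

Assumptions worth stating: biallelic SNPs; sex and ethnicity constant
within individual; replicate records share the genetic value and differ
only in residual (no individual-level repeatability term — the replicates
are treated as true replications; an intraclass correlation between exams
would make the permutation unit, which is the individual, conservative
rather than invalid).

## Testing: Henderson method III with permutation calibration

Each term's F statistic is built from reductions in sums of squares with
every effect treated as fixed: ΔSS is the type-III-style reduction from
adding the term's column group to the model containing the conditioning
set, and the denominator is the residual mean square of the all-terms
least-squares fit.  Because indicator-coded interaction blocks span their
main-effect column, the conditioning set respects marginality:

- a fixed main or epistasis term is tested conditioning on everything
  except its own ethnicity-interaction block;
- a single ethnic level, when its main term is in the model, is a
  deviation from the main effect and is tested keeping the main column but
  dropping the block's sibling levels (with all five columns the level is
  saturated and untestable); without a main term the level is the whole
  group-specific effect and is tested against the full model;
- a whole interaction block is tested against the full model (its df is 3
  rather than 4 when the main column is present, by rank).

Rank decisions are made once, on the observed design, by an
order-respecting greedy Cholesky basis (relative tolerance 1e−8, earlier
columns win so mains stay in the basis); least-squares reductions use an
explicit singular-value cutoff of 1e−10 to keep near-null directions out
of the projections.

The experiment-wise null is the permutation distribution of the maximum F
over all tested terms.  The permutation unit is the individual: both
replicate records keep their phenotype, sex and ethnicity, and are paired
with the genotype of a uniformly drawn other individual.  The critical F
is the empirical (1−α) quantile (default α = 0.05, 2,000 permutations; the
simulation benchmarks use 500).  P values beyond the permutation
resolution (< 1/(n_perm+1)) are extrapolated from a generalised Pareto
distribution fitted to the upper 10 % of max-F samples and flagged as
extrapolations; a bounded-support (negative-shape) fit is replaced by an
exponential tail so extrapolated P values never collapse to zero.  Under a
permutation an exact within-group collinearity can arise between tight-LD
loci (e.g. two loci sharing a dominant coding inside the smallest group);
the evaluator then falls back to a pseudo-inverse, which zeroes the
degenerate direction and is conservative.

Variance components are estimated two ways: Henderson method III (equate
each class's reduction R(all) − R(all∖v) and the residual quadratic form
to their expectations — trace terms in the class variances plus rank
differences times σ²_ε — and solve the linear system; negative solutions
truncate to zero with a flag, and a non-positive residual solution falls
back to the all-terms MSE), and as posterior means from the Gibbs chain.

## Estimation: Gibbs sampling

Effects are estimated by a blocked Gibbs sampler for the Bayesian linear
mixed model: flat priors on fixed effects, i.i.d. normal priors with
class variance on random levels, inverse-gamma(0.001, 0.001) on all
variances.  Defaults: 20,000 iterations, 2,000 burn-in, no thinning
(tests and simulation benchmarks use shorter chains).  Posterior means
and SDs are the reported estimates and SEs.  Two identifiability
consequences are worth knowing: a fixed main effect absorbs the
(shrunken) mean of its interaction levels, and interaction-level
posterior means are shrunken toward zero at small n — the parameter
recovery test therefore checks truth coverage by empirical intervals
across replicates rather than unbiasedness of single fits.

## Heritability partition

Each fixed genetic term contributes the sample variance across records of
(coefficient column × estimate); an interaction unit contributes the
variance of its four levels' combined fitted effect; class heritabilities
are class sums divided by the phenotypic variance, in percent, and the
total is exactly the sum of the six class components (additive model:
h2_a + h2_ae).  This realised-variance definition — per-locus
contributions summed within class — was chosen over variance-component
ratios because it yields a per-term h² for the results table and reduces
to the textbook single-locus formula (effect² × coefficient variance /
V_P).  Covariances between terms (e.g. LD between loci, or the
a–d coding covariance at MAF ≠ 0.5) are deliberately not attributed, so
class sums can differ from the variance of the summed genetic value.

## Two-stage association pipeline

GMDR-style pre-screening is replaced by an exhaustive F-test screen: per
SNP the joint a+d F-test given sex and ethnic-group means (records
stacked, missing codings mean-filled for screening only; default P ≤
1e−3), then pairwise 4-df epistasis tests among the top-20 1D SNPs
(default P ≤ 1e−5), capped at 50 candidates by score.  The optimum model
is built by forward selection with backward elimination: each round tests
every remaining candidate unit (locus = joint a+d, pair = joint 4-df
epistasis) conditional on the current model, enters the largest F if it
exceeds the round's experiment-wise critical F (permutation max over all
remaining candidates), and removes included units that have fallen below
it; ties break by genome order, and interaction random classes are added
to the selected specification after the fixed-architecture search.  A
three-way interaction scan is not implemented (no three-way terms are
part of the model).  Outlier handling drops records with |standardised
residual| > 3 from the all-terms fit and refits once; repeated passes
converge to a fixed point.

## The single-locus baseline

Per-SNP least-squares regression of one examination's trait on
minor-allele dosage (0/1/2; note the sign flip against the full model's
major-oriented coding) with sex and the top principal components of the
standardised genotype matrix as covariates; Wald P values; genomic
control λ_GC = median χ² / 0.4549; greedy sliding-window LD pruning
(window 50, step 5, r² > 0.75, dropping the lower-MAF member, ties to the
later position) to count independent tests for the Bonferroni threshold
−log10(α/m).  A mixed-model (GRM-based) single-locus arm is not
re-implemented; external scan results can be scored by the evaluation
harness instead.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: four ethnic
groups at recruitment shares 38 % / 12 % / 28 % / 22 % (E-A, C-A, A-A,
H-A, largest-remainder rounding), Balding–Nichols group allele
frequencies (Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral MAF p, default
p = 0.30 and FST = 0.05 — enough differentiation to exercise
stratification control without overwhelming the interaction effects),
Hardy–Weinberg genotypes within group, and optional LD blocks in which
each member haplotype copies a hub SNP's allele with probability ρ
(allelic correlation ρ to the hub; genotype r² ≈ ρ²).  Phenotypes add a
population mean (default 193, a typical total-cholesterol level in mg/dL),
a sex block (−7 for males), fixed group effects (+3.0/−4.0/+1.5/−0.5 —
modest, arbitrary values that give the ethnicity random class something
to absorb), the genetic value from a truth set, and i.i.d. normal
residuals per replicate record (two records per individual).

Two scenarios are bundled.  Scenario I carries the full-model truth set
(17 main-effect loci, 3 pairs; additive, dominance, epistasis and
ethnic-interaction effects); scenario II the additive-model truth set
(13 additive effects), with additive-by-ethnicity effects defaulting to
zero unless supplied (their published values are not available — a
documented limitation).  The residual SD is calibrated so a variance
target holds exactly in-sample: by default the anchor locus rs629301's
additive term explains 1.46 % of phenotypic variance; calibrating instead
to a total genetic share (e.g. 33.64 %) is supported.

What the generator does **not** emulate: real haplotype LD beyond the hub
blocks, allele-frequency spectra matched to a genotyping array,
relatedness/cryptic kinship, genotyping error, and exam-to-exam
non-genetic correlation.  Passing benchmarks therefore demonstrate the
estimators' statistical behaviour under the assumed structure, not
performance on any particular real cohort.

## Evaluation

`run_replicates` keeps one genotype panel (as a study re-analysing one
cohort would) and redraws phenotype noise per simulation with seeds
base+10000+i.  A locus counts as detected when any of its tested terms is
experiment-wise significant; per-effect detection for an interaction
requires the specific ethnic level's deviation term.  FDR is the per-sim
ratio of falsely identified loci to detected loci, averaged over sims
with detections; a detected non-truth locus with genotype r² > 0.85 to a
truth locus counts as true in the LD-adjusted FDR.  Bias flags come from
the empirical 2.5–97.5 % interval of estimates across simulations (over =
truth below the interval, under = truth above).

### Problem sizes used by the test-suite benchmarks

The headline benchmark runs at cohort scale: 5,277 individuals × 2
records, the scenario-I truth set, 50 simulations, 500 permutations.  The
property benchmarks run reduced so the whole suite stays quick: parameter
recovery at n = 1,000 with a 5-effect truth subset over 50 replicates
(Gibbs 1,200/300); the full-vs-additive comparisons at n = 600 over 20–30
pipeline simulations with a 4–6 effect truth set, one tight-LD partner
(ρ = 0.95) for each main-effect locus and four null SNPs.  At that scale
the absolute FDRs are dominated by proxy swaps between a locus and its
near-duplicate partner and are much larger than at cohort scale; the
checks are therefore directional (additive raw FDR exceeds the full
model's under non-additive truth; the two agree under additive truth;
LD-adjusted FDRs collapse toward zero), matching what a scaled-up run
shows in sign rather than magnitude.

## Numerical and design choices

- F denominator: all-terms residual MS (the permutation calibration makes
  the test valid regardless of this choice).
- Permutation critical value: empirical quantile, no smoothing; same-seed
  runs are bit-identical.
- Aliasing: exact duplicates of a tested term raise an error in direct
  calls and are skipped (logged on the tester) inside the automated
  pipeline, where tight-LD panels can produce them legitimately.
- QC boundaries are strict exclusions (MAF < 0.05, call rate < 0.90), so
  boundary values are retained; no Hardy–Weinberg filter is applied, since
  the pooled multi-ethnic sample is not expected to be in HWE.
- Missing genotypes at model loci drop the individual's records listwise
  (counted); screening and the single-locus scan mean-impute instead.
- PLINK text round trips infer major/minor orientation by frequency (ties
  lexicographic); the binary format stores orientation explicitly.

## Known limitations

- The per-level deviation test is a fixed-effects surrogate for testing a
  shrunken random level; its df and null distribution are calibrated by
  the same permutation scheme, but it is not the (unpublished) original
  quadratic-form construction.
- Henderson III with many interaction classes on small unbalanced designs
  can be ill-conditioned; the implementation truncates and falls back as
  described rather than failing.
- The stepwise search explores fixed architectures only; interaction
  classes attach to whatever loci are selected, so a locus carried only by
  an interaction effect can be missed.
- Scenario II's ethnic-interaction truth defaults to zero; power for those
  effects is then trivially undefined.
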