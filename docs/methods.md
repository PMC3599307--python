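# Methods

## The problem

Whole-gonad expression profiles mix two cell compartments: germ cells
(spermatocytes in the postnatal testis, oocytes in the embryonic ovary),
which progress through meiotic prophase, and the surrounding somatic cells.
A gene's measured time course is therefore a composite, and genes expressed
specifically by germ cells cannot be read off the matrix directly.
`germdeconv` treats the problem as supervised classification: genes with
known germ-cell or non-germ-cell expression (from single-gene assays and a
tissue-specificity rule) are training examples, the gonadal time-point
values are features, and a kernel classifier emits, for every gene on the
array, a probability of germ-cell expression during meiotic initiation and
prophase.

## Classifier

The model is a soft-margin SVM minimising `1/2 ||β||² + C Σ ζᵢ` subject to
`yᵢ(βᵀφ(xᵢ) + β₀) ≥ 1 − ζᵢ`, with linear, polynomial, sigmoid and radial
kernels; the radial kernel `K(xᵢ,xⱼ) = exp(−γ‖xᵢ−xⱼ‖²)` is the default and
the one that wins model selection in practice. The quadratic program is
solved by `sklearn.svm.SVC`; this package owns everything around it:

- **Features.** One column per (tissue, time point) after replicate
  averaging — four features for the default design. Replicate-level
  features can be used by skipping `average_replicates`.
- **Scaling.** Each feature column is z-scored with training-set statistics
  stored in the fitted model, so prediction uses the same transform.
- **Probabilities.** Platt sigmoid calibration fitted within training
  (`SVC(probability=True)`), with a fixed seed for its internal folds; all
  outputs lie in [0, 1] and are deterministic given the model.
- **Model selection.** Grid search over `C ∈ 2⁻⁵…2¹⁵`, `γ ∈ 2⁻¹⁵…2⁵`
  (powers of two), scored by the mean ROC AUC of repeated stratified
  5-fold cross-validation. The grid spans the two gonad-model optima
  (γ=8, C=2 male; γ=1, C=2048 female) as interior points.
- **Repeated CV.** Each training gene gets exactly one out-of-fold
  probability per repeat; the ranking score is the mean over repeats.
  Folds are stratified by label (avoiding single-class folds on small,
  imbalanced sets) and drawn from the CV seed; when the fold count exceeds
  the smaller class (e.g. leave-one-out) plain shuffled folds are used,
  with a bounded redraw if a training side ends up single-class.
- **Genome-wide predictions** come from one final model fitted on the full
  training set with the selected configuration — deterministic, rather
  than an average over CV models.
- **Persistence.** A saved model stores configuration + training rows +
  seed as JSON; loading refits the (small) SVM, which reproduces the same
  decision function without serialising solver internals.

## Training-label curation

Evidence records carry one of five strength grades. Very strong / Strong /
Present mark a gene positive; a gene is negative only if all its records
are Absent / Trace; conflicting genes are kept positive. Additional
negatives come from a multi-tissue panel: with a single global median taken
over the concatenated gene × tissue matrix (linear scale), a gene is a
tissue-specific negative when it exceeds 10× that median in exactly one
non-gonadal tissue and sits below the median in every other tissue
(including testis and ovary — the "other tissues" clause is read as using
the same global median; a per-gene-median variant is available behind
`per_gene_median=True` for sensitivity analysis). The final set is the
union of curated positives and negatives intersected with the array's gene
universe; a gene reaching both lists stays positive with the conflict
logged.

## Evaluation

Curves use a fixed-decrement threshold sweep from the maximum score down
past the minimum (0.002 for probabilities and correlation coefficients, 2
for log2 expression), predicting positive at score ≥ threshold. Both
endpoints are included so recall reaches 1, at which point precision equals
class prevalence exactly; a threshold with zero predictions has undefined
precision and is omitted. Average precision is the recall-weighted step
integral `Σ (Rⱼ − Rⱼ₋₁)·Pⱼ`, which depends only on the ranking once the
decrement resolves all distinct scores and is then invariant to monotone
score transforms. ROC AUC is the exact Mann–Whitney concordance (ties ½),
independent of the sweep grid.

Two reference rankers quantify what the classifier adds:

- **Expression level**: mean log2 gonadal expression across the time
  course. On mixtures this confounds ubiquitous and strongly somatic genes
  with germ-specific ones, which is exactly why it loses to the SVM.
- **Pairwise correlation**: Pearson r of time profiles for every unordered
  pair of training genes, same-type pairs positive. Its random-precision
  floor is the pair prevalence `(C(P,2)+C(Q,2))/C(P+Q,2)`. Zero-variance
  profiles make r undefined; their pairs are dropped with a log entry.

## Enrichment

The hypergeometric upper tail `P(X ≥ k) = Σ_{X=k}^{min(m,n)}
C(m,X)·C(N−m,n−X)/C(N,n)` (scipy's stable implementation; tested against
exact big-integer rationals to < 1e-10 relative error over the full
N ≤ 60 grid) drives chromosome and GO-term tests. Chromosome tests use a
fixed Bonferroni divisor of 21 (autosomes 1–19, X, Y) regardless of how
many labels a particular map contains; GO tests multiply raw p by the
number of terms with at least one universe gene, capped at 1.

The essential-gene curve reports the cumulative essential fraction at rank
cutoffs `bin, 2·bin, …` down the ranking, against the mean ± sd of (default
100) random orderings; at the final cutoff both equal the global essential
fraction exactly, by construction. Significance defaults to a one-tailed
t-test using the randomization rounds as replicates (each round's curve
mean versus the observed curve mean). A paired-over-bins alternative is
kept behind `test="bins"`, but is documented as underpowered when only the
top bins are enriched, because late cumulative bins are pinned to the
global fraction for observed and random curves alike.

The microRNA screen scores each target set by the ROC AUC of `1 − p`
(probability of *not* being a germ-cell gene) with targets as positives.
The AUC cutoff (default 0.6) and the consensus requirement across target
sources are explicit configuration, since neither is a settled convention.

## Synthetic data

The generator emulates the study design the package targets: a 4-time-point
gonadal time course with duplicate arrays, plus a 61-tissue panel and
annotation files, all with known ground truth.

Observed value for gene g, time t, replicate r:

    log2( f(t)·2^E_germ(g,t) + (1−f(t))·2^E_soma(g,t) ) + ε,
    ε ~ Normal(0, noise_sd_log2)

Mixing happens on the linear scale and is re-logged, because transcript
abundances add — their logs do not. Four gene classes are planted in equal
proportions by default: germ-specific (germ compartment elevated by
`germ_effect_log2`, default 3.0, with a ramp from half to full effect
across time so profile *shape* is informative), soma-specific (somatic
compartment elevated, constant), ubiquitous (both elevated) and silent
(background in both). Per-gene baselines are `baseline_log2 = 4.0` plus
N(0, 0.5) jitter; replicates share compartment means and differ only by
N(0, `noise_sd_log2` = 0.5) noise on the log2 scale — the standard
microarray noise assumption. The germ-cell fraction trajectory defaults to
(0.20, 0.35, 0.50, 0.65): the germ pool expands through prophase, but the
exact per-time-point fractions are a modelling choice, not a measured
quantity; they are fully configurable. Setting `germ_time_ramp=False`
together with a flat trajectory produces level-only signal, the regime in
which the correlation-pair ranker is provably uninformative (its average
precision collapses to pair prevalence).

The tissue panel draws lognormal background around a median of ~100 and
plants tissue-specific genes at 40× / 0.3× the realised global median
(re-planted against the post-plant median until stable), so the curation
rule recovers exactly the planted set; a few genes are planted
testis/ovary-specific to exercise the exclusion clause. Annotations plant:
chromosome labels with the X-probability of germ-specific genes inflated
3× (echoing the X-enrichment of early-meiotic gene expression), essential
flags at 7% base rate raised to 12% among germ-specific genes (the
genome-wide rate and top-list rate the enrichment machinery should
resolve), GO-like sets half-drawn from the germ class, and repressor
microRNA target sets drawn entirely from non-germ classes (a rate near the
75% non-germ genome fraction would encode no detectable direction).
Realised overlap counts are recorded in the ground truth.

What the simulation does *not* model: probe-level structure and
normalisation artefacts, non-Gaussian heavy-tailed noise, correlated genes
(co-regulation), partial-specificity classes, or time-varying somatic
composition. Passing tests therefore demonstrate that the machinery
recovers planted structure under idealised mixture conditions, not that
real-data performance reaches any particular level.

## Numerical choices and degenerate inputs

- Linear values ≤ 0 are floored at 2⁻¹⁰ before log2.
- Probe collapsing keeps the minimal annotation tier per gene, averaging
  ties element-wise; unannotated probe-sets are dropped with a warning
  count, unmapped genes are absent (not imputed).
- Ties in predicted probability at a top-list or bin boundary break by the
  stable order of the sorted series (gene-id order among equals).
- Constant feature columns get unit scale (pass through centred).
- Class counts in the simulator use largest-remainder rounding, so stated
  proportions are hit exactly.
- All randomness flows from explicit integer seeds (`numpy` Generator or
  fixed `random_state`); identical seeds give bit-identical outputs.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script simulations use 2,000-gene genomes
(120 genes for the all-pairs correlation check, 5,000 for null-calibration
draws, 22,409 for the essential base-rate arithmetic), 5-fold CV with 10
repeats, 100–200 randomizations/null draws. These sizes give sampling
error comfortably inside the asserted tolerances while keeping any single
check in the seconds-to-a-minute range.

## Known limitations

- The tissue-specificity rule's double use of the single global median is
  an interpretation; the per-gene variant can disagree on skewed panels.
- Platt calibration on small training sets (tens of genes) is noisy;
  probabilities near 0.5 should not be over-read even when the ranking is
  good.
- Repeated CV averages probabilities across repeats before ranking; other
  aggregation choices (rank-averaging, per-repeat curves) are not exposed.
- The GO machinery uses flat gene sets; no ontology-graph propagation.
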