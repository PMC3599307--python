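# germdeconv

Supervised detection of germ-cell-specific gene expression hidden inside
whole-gonad time-course microarray data.

## The problem

Only germ cells undergo meiosis, but expression profiling of the gonad
during meiotic initiation and prophase — the postnatal testis (first wave
of spermatogenesis) or the embryonic ovary — measures germ cells and
somatic cells together. Physically isolating germ cells is hard in the
male and currently infeasible for embryonic oocytes, so germ-cell-specific
signals must be recovered computationally from the mixed signal.

`germdeconv` frames this as classification. Genes known from single-gene
assays to be expressed (or not) by germ cells in prophase are training
examples; their whole-gonad log2 expression values at each time point are
the features; a soft-margin SVM with a radial-basis kernel,
`K(xᵢ,xⱼ) = exp(−γ‖xᵢ−xⱼ‖²)`, trained by minimising
`1/2 ||β||² + C Σ ζᵢ`, assigns every gene on the array a calibrated
probability `p ∈ [0,1]` of germ-cell expression. The package covers the
full workflow:

- **`germdeconv.synthetic`** — a mixed-compartment simulator (germ +
  somatic compartments, time-varying germ fraction, planted gene classes,
  tissue panel, chromosome/essential/GO/microRNA annotations) with known
  ground truth, so every downstream stage is testable without any external
  download.
- **`germdeconv.io` / `germdeconv.matrix`** — TSV/GMT formats, probe→gene
  collapsing by annotation tier, replicate averaging.
- **`germdeconv.curation`** — training labels from graded evidence records
  (Very strong/Strong/Present ⇒ positive; all Absent/Trace ⇒ negative;
  conflicts ⇒ positive) plus tissue-specific negatives (>10× the global
  panel median in exactly one non-gonadal tissue, below the median
  elsewhere), restricted to the array's gene universe.
- **`germdeconv.classifier`** — fitting, Platt-calibrated probabilities,
  grid search over (kernel, γ, C) by cross-validated ROC AUC, repeated
  stratified 5-fold CV with out-of-fold probabilities.
- **`germdeconv.evaluation`** — fixed-decrement precision–recall and ROC
  sweeps (0.002 for probabilities/correlations, 2 for log2 levels),
  precision at target recall, recall-weighted average precision, exact
  Mann–Whitney AUC, and two reference rankers: mean expression level and
  pairwise profile correlation.
- **`germdeconv.enrichment`** — hypergeometric upper-tail
  `P(X ≥ k) = Σ C(m,X)C(N−m,n−X)/C(N,n)` for chromosome (Bonferroni at
  M=21) and GO-term enrichment, cumulative essential-gene curves against
  randomized orderings, Jaccard overlap of top lists.
- **`germdeconv.mirna`** — microRNA target sets scored by the AUC of
  `1 − p` for predicting non-germ-cell genes, with a consensus filter
  across target-prediction sources.

## Worked example

`examples/03_train_and_predict.py` simulates an 800-gene gonadal time
course (4 time points × 2 replicates, germ effect 3.0 log2 units, noise
0.5), trains on germ-specific-vs-rest labels and prints:

```
grid search winner: gamma=0.125, C=32.0 (mean CV AUC 1.000)
SVM out-of-fold: AUC 1.000, precision@10%recall 1.000, average precision 0.999
expression-level ranker: AUC 0.367 (confuses ubiquitous with germ-specific genes)
genome-wide probabilities: 0.1% of genes in [0.4, 0.6] (bimodal separation)
```

The SVM separates planted germ-specific genes essentially perfectly
because the *shape* of the mixed time course (rising germ fraction × germ
ramp) is informative, while the mean-level ranker is actively misled —
ubiquitous and soma-specific genes carry more total signal than
germ-specific ones inside a mixture. The probability histogram is bimodal:
nearly every gene is confidently called one way or the other.

The other examples cover simulation (`01`), label curation (`02`),
enrichment characterisation (`04`: the planted X-chromosome excess is the
only flagged chromosome, planted GO sets are recovered, the essential-gene
fraction is 12.8% in the top bin versus 8.0% at random with the final
cumulative fraction equal to the global rate exactly) and the microRNA
screen (`05`: the three planted repressors rank first with AUC > 0.6 in
both target sources).

A thin CLI mirrors the workflow:
`germdeconv simulate | curate | train | predict | evaluate | enrich | mirna`
(see `germdeconv COMMAND --help`).

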