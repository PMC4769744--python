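# Methods

## Model and procedure

The pipeline treats a 16S rRNA sample as a bag of reads and represents it by
normalized canonical k-mer counts, k = 2..6. For a read of length L, each
window count is weighted 1/L; a k-mer and its reverse complement are pooled
onto the lexicographically smaller string (so profiles are strand-invariant
and palindromic k-mers are counted once); the per-read weighted counts are
summed and divided by the number of reads. Windows containing non-ACGT
characters are skipped rather than discarding the read. Zero-variance
features are removed before any learning.

Motif agglomeration operates per length, independently. Each feature is a
string over the 15-letter generalized alphabet in which a letter denotes a
nonempty subset of {A,C,G,T}; the letter for the D set is the standard IUPAC
{A,G,T}, which keeps the complement table an involution (H ↔ D). The
site difference between two letters is the Jaccard *distance*
1 − |∩|/|∪| — 0 for identical, 1 for disjoint sets — and a motif distance
sums site differences, taking the smaller of the direct and
reverse-complement orientation (ties go to the direct orientation, making
the result deterministic). One merge iteration:

1. score all same-length pairs by distance;
2. retain the ⌊n_k/2⌋ smallest, ordering equal distances by the merge gain
   (1 − p_new) − mean_i(1 − p_i), then lexicographically by motif strings;
3. greedily keep at most ⌊√n_k⌋ mutually disjoint pairs;
4. merge each kept pair site-wise; the merged profile is
   X_covered · α where α is the leading Fisher discriminant direction
   computed on the profiles of **all original k-mers** the motif covers
   (the original matrix is retained read-only), α normalized to unit norm
   with positive first nonzero component.

n_k here is the *current* per-length feature count, so both limits shrink
as merging proceeds. The per-candidate p_new is computed on the prospective
merged profile before committing; these scores are cached by feature
identity across iterations (unchanged features keep identical profiles), a
performance measure with no semantic effect. Termination is structural:
each length ends at one motif, after exactly Σ_k (n_k − 1) merges in total.

After every merge a model snapshot records the current dimension (counting
all lengths) and the stratified 5-fold cross-validated macro error of the
chosen classifier on the current feature set. The `snapshot_every` knob
evaluates the error only every B-th merge for large runs; the final state
of the run is always evaluated.

## Model selection

Among the recorded snapshots, the ⌊√N_records⌋ with the smallest training
error form the shortlist; the selected record minimizes
`training_error + log(dim)·log(N·k)/(N·k)` with `N = min(n_train, b)`,
`b` the number of shortlist records of lower dimension than the
minimum-error record, and `k` the shortlist's min/max dimension ratio.
Natural logarithms are used. Three boundary conventions are the package's
own choices:

- **Equal-error ties.** Records tying on training error are ordered by
  dimension (smaller first). Without this, a flat stretch of the error
  curve would make shortlist membership an accident of snapshot order; the
  parsimony preference is the only tie rule consistent with the penalty's
  purpose. When the whole curve is flat (perfectly separable training
  data) selection therefore returns the most parsimonious model.
- **b = 0.** Then N·k = 0 and the penalty term is undefined; it is taken
  as 0, so selection degrades to the argmin of training error.
- **Macro CV error** is computed over pooled out-of-fold predictions (mean
  of per-class error rates). Pooling, rather than averaging fold-level
  macro errors, keeps the quantity defined when a small fold misses a
  class; for stratified folds with adequate class counts the two agree up
  to fold-size weighting.

Note the discriminant weights entering merged profiles are estimated on the
full training set, and cross-validation happens on top of those profiles;
snapshot errors are therefore optimistic. This mirrors the procedure the
pipeline implements (the merge history is part of the model, not refit per
fold) and is the reason held-out test samples are projected through the
stored weights for honest evaluation.

## Motif ranking

Motifs of the selected model are ranked by (1 − p) + specificity, with p
the Kruskal-Wallis p-value of the motif's profile in the selected model and
specificity the mean over sites of 1 − x_i/4 (x_i = member-set size):
0 for all-N, 0.75 for a fully specified motif. Ties break by smaller p,
then lexicographic motif string. Specificity is monotone non-increasing
under merging, so the ranking trades class association against degeneracy.

## Classifiers, baselines, evaluation

1-NN uses Euclidean distance with distance ties resolved to the smallest
class code. The SVM backend is a linear-kernel SVC with default
regularization (no kernel is prescribed by the method; the backend is a
fit/predict contract so other kernels can be swapped in). Three-class
problems use a hierarchy — controls vs pooled disease, then within
disease — because the margin classifier is intrinsically pairwise; a
stage-1 misrouting is never corrected downstream. Baseline selectors rank
features by Kruskal-Wallis p, Information Gain or Chi-square, the latter
two on features discretized at mean ± std into three levels, with KW p
breaking ties. All error reporting is macro-averaged (mean of per-class
error rates) because the cohorts this method targets are imbalanced.

The Fisher direction solves the generalized eigenproblem for
α'S_Bα / α'S_Wα; a rank-deficient S_W (detected by an eps-scaled
eigenvalue tolerance) gets ridge 10⁻⁶ × mean diagonal added. With more
covered columns than samples the problem is solved exactly in the data
row-space — once the ridge is added the optimum provably lies there — which
keeps every eigenproblem at sample-count size.

## Synthetic data: what it emulates, what it does not

`generate_reads` plants concrete instances of a degenerate motif (uniform
over its matches, random strand, non-overlapping positions, Poisson counts
per read) into i.i.d. background reads; uniform base frequencies by
default, with a GC-skew option since real 16S data are not uniform.
`generate_profile_matrix` bypasses reads entirely (log-normal background,
additive class shifts) for fast statistical unit tests. Neither models
amplicon error profiles, chimeras, phylogenetic correlation between taxa,
or compositional effects; passing tests show the machinery recovers planted
signal under clean class structure, not that it will rank biologically
meaningful motifs on real cohorts.

The recovery study (`pmf.study.planted_motif_study`, also the acceptance
script's experiment) uses 20 + 20 training samples of 200 reads × 150 bp
with the 6-mer TCWCGY at 3 instances per read in the case class, profiled
at k = 2..6 (~2 770 canonical features, ~2 765 merges), with snapshots
every 10 merges and 8 + 8 held-out test samples; these sizes keep a full
run at a few minutes on one CPU. At this signal strength the training
classes are perfectly separable at every snapshot, so selection exercises
the tie-break path and returns the fully merged model; the study therefore
verifies recovery through covered sets (all planted instances inside one
selected feature, top-ranked motif covering planted-signal k-mers) and
through held-out error rather than through the shape of the error curve.

## Known limitations

- The merge gain rewards merges that *improve* on their parents' average
  association, so pairs of already strongly associated k-mers carry no
  bonus; planted k-mers join motifs through the distance ordering rather
  than jumping the queue.
- Snapshot errors inherit the full-training-set discriminant weights (see
  above); model selection compares models on equal footing, but the
  absolute CV errors are optimistic.
- Gapped or variable-length motifs, position-weight matrices and
  cross-length merging are out of scope; the "tree" of merges is implicit
  in the history rather than exported as Newick.
- Feature counts grow as 4^k/2; lengths beyond 6 would need a faster
  candidate-scoring path than the current per-pair Kruskal-Wallis.
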