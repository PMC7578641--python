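# Methods

## Problem setting

Predicting which miRNAs are associated with which diseases is a binary
classification task with a structural twist: databases record confirmed
*positive* associations only. Every other miRNA × disease combination is
unlabeled, not negative. `seqsymrf` therefore works in the
positive-unlabeled (PU) setting: positives come from a curated
association table, and negatives are *mined* from the unlabeled universe
by a distance rule before a random forest is trained on the balanced
set.

## Feature definitions

### miRNA (126 dimensions)

A pre-miRNA is a sequence over {A, C, G, U} plus a dot-bracket secondary
structure of equal length with balanced brackets and a minimum free
energy (MFE, kcal/mol). The vector is three concatenated blocks, order
frozen in `mirna_features.FEATURE_NAMES`:

**Global (10).** With L the sequence length and the *central loop* the
longest maximal `.`-run flanked by `(` on the left and `)` on the right:

| descriptor | definition |
|---|---|
| symmetric_difference | abs(U5 − U3): unpaired counts 5′/3′ of the central loop, tails excluded |
| n_base_pairs | count of `(` |
| gc_content | (#G + #C) / L |
| length_bp_ratio | L / n_base_pairs (L when unpaired, with a warning) |
| seq_length | L |
| central_loop_length | length of the central loop (0 if none) |
| free_energy_per_nt | MFE / L |
| bulge_number | maximal `.`-runs flanked by brackets on both sides, central loop excluded |
| tail_length | leading + trailing `.`-run lengths |
| n_tails | number of nonempty terminal runs (0–2) |

Several of these terms are used informally in the hairpin literature
without an operational definition; the readings above (arm asymmetry
relative to the central loop; longest-loop rule for multi-hairpin
structures) were fixed once, are isolated behind named helpers, and are
pinned by hand-evaluated unit tests so alternates can be swapped
deliberately.

**Triplet (32).** `)` is mapped to `(` (paired/unpaired binarisation —
the only reading under which exactly 8 three-position patterns over
{`(`, `.`} exist); for every interior position the 3-character pattern
and the middle base index one of 8 × 4 counters. Counts sum to L − 2.

**k-mer (84).** Overlapping 1-/2-/3-mer counts in lexicographic order
(A < C < G < U); blocks sum to L, L − 1, L − 2. Both count blocks are
raw counts by default — forests are scale-insensitive — with a
`normalize` flag for frequencies.

### Disease (symptom vocabulary dimensions)

Scores come either precomputed (disease/symptom/score TSV) or from a
co-occurrence matrix via TF-IDF with term frequency replaced by the
absolute co-occurrence: `score(d, s) = C(d, s) · ln(N / n_s)` with N the
disease count and `n_s` the number of diseases mentioning s. Natural log
is used; the base only rescales and affects neither the forest nor the
support-based Jaccard similarity. The vocabulary (322 symptoms on the
published resource) is frozen at read time.

### Pairs (126 + vocabulary)

Concatenation, miRNA block first. No cross-block scaling is applied —
the distance rule below therefore operates on raw feature scales, which
is the plainest reading of the selection procedure; a standardized
variant can be obtained by scaling the feature tables before calling it.

## Reliable-negative selection

1. centroid = per-dimension mean of all positive pair vectors;
2. Euclidean distance of every unlabeled pair to the centroid
   (computed as √(‖m − c_m‖² + ‖d − c_d‖²), so the universe is never
   materialised as a dense matrix);
3. AED = mean of those distances;
4. candidates = pairs with distance **strictly greater** than
   `multiplier × AED` (default multiplier 1.5; 1.0 when larger pools
   are needed, e.g. for ratio experiments);
5. the required number (positives × ratio) is drawn uniformly without
   replacement, seeded.

Requesting more negatives than candidates raises an explicit error
suggesting a lower multiplier rather than silently relaxing the
threshold.

## Training and evaluation

The classifier is a scikit-learn `RandomForestClassifier`; association
scores are the fraction of trees voting positive. Defaults follow the
published optimum: 100 trees, 22 split features (≈ √448); a grid search
(trees 100–1000, split features 2, 4, 8, 16, 32 plus the sqrt default)
picks the smallest configuration within one standard deviation of the
best mean accuracy — the economy rule that favours compact forests once
performance plateaus.

Metrics are computed from the confusion matrix at score ≥ 0.5 (Acc, Spe,
Sen, Pre as percentages; Mcc unscaled) plus trapezoidal AUROC and
step-wise non-interpolated AUPRC (average precision). A metric whose
denominator vanishes is reported as NaN, never as 0. Summaries report
the mean and the relative standard deviation (RSD%) across folds.

Two cross-validation protocols are provided:

* `cross_validate(X, y, …)` — repeated stratified k-fold on a fixed
  design matrix (negatives selected once on the full data).
* `cross_validate_pu(…)` — the strict protocol and the default
  recommendation: positives are folded, and the centroid, threshold, and
  both the training and test negatives are recomputed inside each fold
  from that fold's training positives only, so negative selection never
  leaks information from held-out positives. `selection="random"`
  swaps the centroid rule for uniform draws from the unlabeled set — the
  baseline strategy the distance rule is compared against.

### The PU selection artifact

Distance-thresholded negatives are, by construction, the tail of the
distance distribution, and a flexible classifier can learn "far from the
centroid" as a concept of its own. Consequently even a corpus with *no*
planted association signal yields cross-validated AUROC ≈ 0.93 under the
reliable-negative protocol — performance that measures the selection
rule, not biology. This mirrors the behaviour on real data, where the
uniform-random baseline already reaches a high AUROC. Three readouts
disentangle this in the tests and acceptance script: the full pipeline
AUROC (planted signal + selection structure), the label-permuted AUROC
(≈ 0.5; pure null), and the `selection="random"` sweep over signal
strengths (monotone in the planted signal, chance at zero signal —
the artifact-free measure of signal recovery).

### Case-study ranking

`rank_candidates` removes every pair touching the query, retrains from
scratch, and scores all candidates for the query (descending, stable id
tie-break). Ranking an *unseen* disease requires the forest to have
learned the feature interaction rather than the selection shortcut, so
the case-study protocol mines its negatives at 1.0 × AED: the broader
pool contains typical-but-mismatched pairs that force the interaction to
be learned. With 1.5 × AED tail-only negatives, leave-query-out transfer
degrades markedly — a practical caveat for applying the method to new
diseases.

## Similarity and redundancy

miRNA similarity is global-alignment identity (Needleman–Wunsch, match
+1 / mismatch 0 / linear gap −1, identity = identical columns /
alignment length, via Biopython's `PairwiseAligner`) — an internal
replacement for an external clustering tool, whose identity convention
(normalising by the shorter sequence) can differ slightly near gaps.
Disease similarity is support-set Jaccard. Pair similarity is
`mDPS = (Sm + Sd)/2`. Histograms use ten bins on [0, 1], the last
closed. Greedy non-redundancy removes an entity whose similarity to
anything already retained strictly exceeds the threshold; the pair-level
variant prunes positives first, then deletes redundant negatives one at
a time, stopping the moment the pool reaches 1:1 balance (an oversized
non-redundant pool is trimmed at random; an undersized one raises,
naming the achievable count).

## Synthetic data generator

`synthetic.FixtureConfig` defaults define the study conditions: 300
miRNAs × 50 diseases, 322 symptoms, 1000 positives, 4 latent clusters,
full signal, seed 0. Hairpins are tail + arm (+ optional 1–3 nt bulge) +
loop + mutated reverse-complement arm + tail, with stems of 18–55 bp,
loops 4–15 nt, tails ≤ 8 nt and 5% point mutations on the 3′ arm; each
cluster draws nucleotides from a skewed composition (one base at 55%),
planting an identifiable k-mer signature. The annotated mfe is a
stem-length proxy (−1.2 per pair). Diseases draw 5–15 symptoms, 70%
from a small cluster-shared core (emulating the recurring cardinal
symptoms of a disease family, and making an unseen disease's cluster
recognisable), with heavy-tailed lognormal co-occurrence counts — the
skew that gives the 448-dim distance distribution the long right tail
real resources have; with narrow uniform counts almost no pair exceeds
1.5 × AED and the published threshold/ratio combination is
unsatisfiable. Positives connect matching clusters with probability
`signal_strength` (uniform pairs otherwise), drawn without replacement.

What passing tests show — and do not show. The generator plants a clean,
low-rank cluster signal; real association data have correlated,
literature-biased, incomplete labels and far weaker structure. Passing
the planted-signal criteria demonstrates that the pipeline's machinery
(features → selection → forest → evaluation) recovers a learnable signal
end to end and degrades to chance on null data; it does not certify the
published real-data performance, which depends on the external
resources.

## Numerical and design choices

* Folding fallback: Nussinov maximum base-pairing (Watson–Crick + GU,
  hairpin loops ≥ 3), deterministic traceback preferring the smallest 5′
  index; unfoldable sequences return all dots with mfe 0. It is a test
  stand-in, not a thermodynamic model; pseudoknots are out of scope.
* T→U conversion and uppercasing are silent on read (mixed conventions
  in public FASTA files); all other alphabet violations are parse errors
  naming the line.
* Strict inequalities everywhere a threshold is compared ("higher
  than"), including AED and redundancy thresholds.
* Stratified folds in the fixed-matrix protocol prevent degenerate
  single-class folds at small n.
* All stochastic stages (selection, shuffles, folds, forests, the
  generator) take explicit seeds; pipeline reruns with the same seed are
  byte-identical.
* Problem sizes in the test-suite and acceptance script (default corpus,
  1–2 CV repeats, 5 seeds for medians) were chosen so a full run
  completes in a few minutes on one CPU; results at 10 repeats match to
  well within the reported RSD.

## Known limitations

* The 126-feature definitions for "symmetric difference", "bulge",
  "tail" and "central loop" are one consistent operationalisation of
  informal terms; alternates would shift individual global features.
* Euclidean distances on unscaled concatenated features let
  large-magnitude blocks dominate selection; standardize the tables
  first for a sensitivity analysis.
* The reliable-negative protocol's headline metrics partially reflect
  the selection rule itself (see the artifact section); use the random
  baseline and permutation null alongside it.
* SHAP-based importance is not included; permutation importance is the
  in-core substitute.
* Comparison methods from the literature and real-database case-study
  validation are out of scope.
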