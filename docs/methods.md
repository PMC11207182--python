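# Methods

## Problem and model

The unit of analysis is a fixed-length RNA window (default L = 41,
alphabet {A, C, G, U}, T accepted and mapped to U) centred on a candidate
2′-O-methylation site at position ⌈L/2⌉ (21 for L = 41). Prediction is a
two-layer stacked-generalization model:

* **Layer 1 (baselines).** Every combination of a classifier family
  {RF, SVM, XGB, LGBM, CBC, NB, KNN, LR} with one of 18 sequence encodings
  is trained under a single stratified k-fold plan (default k = 5). Each
  baseline contributes the out-of-fold (OOF) probability column: the
  probability for sample *i* always comes from the fold model whose
  training folds exclude *i*. The baseline's cross-validated AUC is
  computed on this column.
* **Layer 2 (meta).** Baselines are ranked by OOF AUC (ties broken by MCC
  at threshold 0.5, then key). The top-n OOF columns form the meta-feature
  matrix for a plain logistic regression
  log(P/(1−P)) = β₀ + Σᵢ βᵢXᵢ; alternative meta-learners
  {LGBM, XGB, RF, SVM, KNN, NB} are selectable for comparison. Meta-level
  CV metrics are computed with the *same* fold plan (fit on the other
  folds' OOF rows, score the held-out fold), so no sample's meta
  prediction sees its own label at any layer. A window is called a site
  when P ≥ threshold (default 0.5; a probability exactly at the threshold
  calls a site).

Fitting the meta-learner on strictly out-of-fold probabilities is a
deliberate design choice: stacking on in-fold probabilities rewards
overfitted baselines, and the leakage-control test asserts the OOF
construction mechanically.

## Encoders

Stateless encoders (Binary, ENAC, NCP, ANF, EIIP, DNC, TNC, CKSNAP,
RCKmer, PseEIIP, CTD, Kmer, NCP-ND, NPS, PseKNC) are pure functions of the
sequence; data-dependent encoders (BPB, NPPS, W2V) are fitted on training
data and are refitted inside each CV training fold. Conventions:

* k-mer-indexed features are ordered lexicographically over A < C < G < U;
  positional blocks run 5′→3′. Dimensions derive from L (never hard-coded
  to 41).
* Frequency denominators are the number of windows: L−k+1 for k-mers,
  L−k−1 for k-spaced pairs (gap k between the two members).
* **ANF / NCP-ND density** is cumulative: dᵢ = (occurrences of the
  nucleotide at position i among positions 1..i)/i, which keeps dᵢ ≤ 1.
* **EIIP vs PseEIIP**: EIIP multiplies the summed trinucleotide
  pseudopotential (A 0.1260, C 0.1340, G 0.0806, U 0.1335) by the
  trinucleotide frequency; PseEIIP uses the mean (sum/3). The two are kept
  as separate encoders, proportional by construction, to preserve the
  18-encoder census.
* **CTD**: 4 composition fractions + 6 unordered distinct-pair adjacent
  transition frequencies + 20 distribution values (first/25%/50%/75%/last
  occurrence position of each nucleotide as a fraction of L, 0 when
  absent) — the only decomposition consistent with 30 output dimensions.
  The q-quantile occurrence is the ⌈q·count⌉-th occurrence.
* **BPB** stores 4×L per-position likelihood matrices for each class,
  smoothed additively: (count + c)/(N + 4c) with pseudocount c = 0.25 by
  default (zero-count columns otherwise break downstream ratios). Class
  priors cancel for balanced training sets, so the encoding is the pair of
  positional likelihood lookups (p₁⁺…p_L⁺, p₁⁻…p_L⁻).
* **NPPS** additionally stores 16×(L−k−1) positional pair matrices
  (pseudocount denominator N + 16c) and emits
  pᵢ = f_d[pair at i]/f_s[second member, position i+k+1] for each class,
  returning p⁺ − p⁻. The single-nucleotide index follows the second member
  of the pair. Zero denominators under pseudocount 0 raise an error that
  instructs the caller to use a positive pseudocount.
* **PseKNC** (k = 2, λ = 2, w = 0.1 by default) appends λ correlation
  tiers θⱼ, each the average over positions of the mean squared
  property difference between dinucleotides j apart, to the normalized
  k-mer block; both blocks share the denominator Σf + wΣθ. The packaged
  dinucleotide property table (`data/rna_dinucleotide_props_synthetic.json`)
  is **synthetic**: six standardized placeholder property rows named after
  the usual helical parameters, not measured values. Any standardized
  (mean 0, sd 1 across the 16 dinucleotides) table can be supplied via
  `PseKncSpec(props=...)`; the encoder validates standardization.
* **W2V** trains a skip-gram with negative sampling (implemented in numpy,
  single-threaded and deterministic per seed) over overlapping 3-mer
  tokens (stride 1), embedding dim 64, context window 5, 3 epochs,
  5 negatives, unigram^0.75 noise. The per-sequence vector is the mean of
  its token vectors (concatenation is available); out-of-vocabulary tokens
  map to the zero vector. The default corpus is the training-fold
  sequences themselves; an external corpus can be substituted. Mean
  pooling was chosen because it keeps the feature dimension independent of
  L and is the common default for short-sequence embedding averaging.

## Classifier families and hyperparameters

Grids are small and scored by OOF AUC under the shared fold plan (the
winning candidate's OOF column is retained):
RF n_estimators {100, 300} × max_depth {None, 6}; SVM RBF with C {1, 10},
gamma scale, built-in probability calibration; XGB and LGBM
learning_rate 0.1, n_estimators {100, 300}; CBC — the gradient-boosted-tree
slot — scikit-learn histogram gradient boosting with learning_rate 0.1,
max_iter {100, 300}; Gaussian NB; KNN k {5, 15}; LR L2 with C = 1. SVM,
KNN and LR inputs are standardized (their objectives are scale-sensitive;
tree ensembles and NB are not). The meta LR uses C = 10⁶, i.e. effectively
unregularized plain logistic regression over probability columns.

Each baseline derives its own seed from the master seed and its
`FAMILY_ENCODER` key (CRC-32 mix, < 2³¹), so results are independent of
training order and reproducible end-to-end.

## Synthetic benchmark generator

The generator emulates the structure of the real Nm benchmarks: balanced
positive/negative 41-nt windows, with the positive class enriched for the
bases A, G, A, U at positions 22–25 (1-based; immediately 3′ of the site).
Negatives are i.i.d. draws from a background distribution (uniform by
default); positives are background draws in which each motif base is
planted at its position independently with probability `enrich_prob`
(default 0.7). An option fixes the central nucleotide to emulate the
nucleotide-specific (Am/Cm/Gm/Um) dataset variants.

Published logo analyses quantify enrichment significance, not emission
probabilities, so enrichment strength has no literature value; 0.7 was
fixed a priori as a moderate-signal regime that puts baseline OOF AUCs in
the 0.8–0.95 band typical of this task at n ≈ 10³, and is not adjusted
thereafter. With `enrich_prob = 0` (equal to background) the two classes
are exchangeable, giving the null pipeline check (meta CV AUC ≈ 0.5).

What the generator does **not** model: real RNA-type composition
(tRNA/rRNA/…), sequence redundancy and its removal, genomic context,
secondary structure, or correlated multi-position motifs. Passing tests
therefore demonstrate correctness and leakage-free behaviour of the
machinery, not real-data accuracy; headline performance on the published
benchmark requires the external data and is out of scope here.

## Numerical and degenerate-input conventions

* Metrics: SEN, SPE, PRE, ACC, MCC from confusion counts with
  score ≥ threshold counted positive; zero denominators yield 0 with a
  logged warning (MCC denominator 0 → 0). AUC uses the rank/Mann–Whitney
  statistic with average ranks, exact under ties; AUPRC is the step-wise
  precision–recall sum over distinct-score operating points. Both are
  cross-checked in tests against all-pairs enumeration and scikit-learn.
* Ranking ties: OOF AUC, then OOF MCC at 0.5, then lexicographic key —
  fully deterministic.
* FASTA windows of the wrong length are rejected (strict) or skipped with
  a log line (lenient); ambiguity codes are always rejected, naming the
  record and position. Imputing ambiguity codes would distort frequency
  encoders.
* Test-time prediction uses baselines refitted on the full training set,
  with encoder profiles fitted on the full training set.

## Problem sizes used in the shipped checks

The test suite exercises the stacking claims on a restricted census
(4 families × 6 encoders, n = 500 + 500 windows, enrichment 0.7) and the
null check on the same data size — a census size chosen so the properties
of interest (stacking does not fall below the best single baseline; the
top-n curve is non-decreasing within noise; null data scores at chance)
are measurable with stable estimates. The full 8 × 18 = 144-baseline
census runs through the identical code path (`build_all_baselines` with
defaults) and is intended as an offline batch job.

## Known limitations

* The CBC family slot is a histogram gradient-boosting implementation; it
  follows the same boosted-tree methodology but is not the CatBoost
  codebase, so numeric outputs differ from CatBoost-trained models.
* The skip-gram trainer is deliberately minimal (vocabulary ≤ 64 for
  3-mer tokens); it is not suitable for large NLP vocabularies.
* No secondary/tertiary-structure features; sequence-only by design.
* Hyperparameter grids are compact defaults, not an exhaustive search;
  widen `ClassifierSpec.grid` for production-scale tuning.
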