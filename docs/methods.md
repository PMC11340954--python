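# Methods

## The model

stackpep estimates a binary peptide-activity classifier as a two-level
stacked generalization. Level one is a grid of *single-feature models*:
each cell pairs one sequence encoding with one classifier and is trained by
stratified 5-fold cross-validation on the training split, yielding one
out-of-fold (OOF) probability per training peptide — a prediction from a
fold model that excluded that peptide. Level two is a meta-classifier
(logistic regression by default) fitted on the matrix whose columns are the
members' OOF probability vectors. For the LR meta-classifier the fitted
probability obeys

    ln(p / (1 − p)) = β₀ + Σᵢ βᵢ xᵢ ,

with xᵢ the probability emitted by member i. |βᵢ| — the absolute weight
coefficient of logistic regression (AWCLR) — is the member-importance
measure driving subset selection. Because probability features already
share the [0, 1] scale, the meta-level applies no standardization; doing so
would change what the weights measure.

Assumptions worth stating: members are exchangeable evidence sources whose
errors are partially independent (otherwise stacking adds nothing); a
single shared fold assignment across all cells makes the stacked columns
comparable and prevents inter-level leakage; labels are binary with the
positive class the rare one.

## Data handling

Splitting is stratified per class with floor rounding on the test side
(default test fraction 0.2, i.e. a 4:1 train/test ratio), and CV folds are
dealt round-robin within class after a seeded shuffle, so per-fold class
counts differ by at most one. No over- or under-sampling is ever applied;
class imbalance is handled at the threshold, not in the data. Sequences are
validated against the 20-letter alphabet; records with non-standard
residues (B, J, O, U, X, Z) are rejected by default or dropped on request.

## Encoders

Composition encoders (k-mer, grouped k-mer, conjoint triad, CKSAAP gap
blocks, the CTD composition part) are frequency vectors normalized by their
count denominators, so blocks sum to one whenever populated; CKSAAP blocks
whose gap exceeds the sequence emit zeros with a warning rather than
failing on short peptides. The CTD descriptors use 13 three-way property
partitions (seven hydrophobicity scales, van der Waals volume, polarity,
polarizability, charge, secondary structure, solvent accessibility): the
13 × 3 = 39 composition/transition widths and the 13 × 15 = 195
distribution width require 13 properties, and the bundled partitions follow
the established Dubchak-style convention. The distribution part reports the
sequence positions (percent of L) of the first, 25 %, 50 %, 75 % and last
occurrence of each group, zero when absent.

Pseudo-amino-acid composition standardizes the three bundled property
scales (hydrophobicity, hydrophilicity, side-chain mass) over the 20
residues, computes rank-d correlation factors θ_d as mean squared property
differences at sequence distance d, and normalizes the 20 frequencies and
λ = 5 factors by 1 + w Σθ with weight w = 0.05 — the standard defaults; the
25-feature width forces λ = 5.

Per-residue encodings (one-hot, BLOSUM62 rows, 5-component z-scales,
ordinal index, sliding-window composition) are flattened and zero-padded to
a fixed length, by default the longest training sequence; classical
learners consume the flattened vector. BLOSUM62 comes from Biopython's
published matrices; z-scales are the Sandberg five-descriptor table. The
amino-acid-index encoder mean-pools each index scale over the sequence;
its width follows the bundled table, a reduced curated snapshot of
well-known published scales (the public collection has several hundred;
the encoder accepts any complete table).

The skip-gram k-mer embedding treats each peptide as a sentence of
overlapping k-mers (k = 1..4) and trains skip-gram with negative sampling
(dim 128, window 40, 100 epochs, 5 negatives by default) in seeded,
single-threaded numpy; the window exceeds peptide lengths, so every token
is context for every other. Batch gradients hitting the same embedding row
are averaged rather than summed — with vocabularies this small, summed
stale-gradient updates diverge. Sequences are pooled as the mean of their
token vectors; out-of-vocabulary tokens are skipped, all-OOV sequences map
to zero with a warning. By default the embedding trains on the training
split itself; any external corpus can be supplied.

Protein-language-model embeddings go through a provider registry. The
bundled `stub` provider is a deterministic hash-seeded residue projection,
mean-pooled — it honours every shape/determinism contract and carries
composition-level signal only, which is exactly what pipeline tests need;
the `esm2` adapter imports the external package at call time and is an
optional extension. Tests never require the real model.

## The grid

The default census is 168 cells: 7 classical classifiers (RF, XGB, LGBM,
SVM, KN, NB, LR) × 21 fixed-vector encodings, plus 3 further learners ×
7 sequence-level encodings (one-hot, ordinal index, language-model and the
four k-mer embeddings). The latter slots are designed for deep sequence
learners; absent that optional plugin they fall back to multilayer
perceptrons on the flattened inputs, preserving the census. Margin- and
distance-based learners are wrapped with a standard scaler fitted on
training folds only; tree ensembles are unscaled. Hyperparameters are fixed
sensible defaults (documented in `base.make_classifier`), deliberately not
tuned per dataset; a caller can pass overrides per cell.

## Threshold and metrics

Seven measures are reported (SEN, SPE, PRE, ACC, MCC, ROC AUC, PR AUC).
The decision threshold maximizes MCC over the meta-level OOF
probabilities; candidates are all distinct probabilities plus 0 and 1, a
sample is called positive at prob ≥ θ, and the smallest maximizer wins
ties. Zero-denominator conventions: MCC is 0 when any confusion factor is
0; undefined precision is reported as 0 with a flag. Test-set metrics
always use the training-derived threshold.

## Selection algorithms

SAAUC adds members in descending CV-AUC order (ties break
lexicographically by model key); SAWC adds in descending AWCLR order from
one meta-fit on all members; both produce nested subsets. SDIWC refits the
LR meta-classifier at every step, deletes the minimum-AWCLR member (ties
delete the lexicographically last key) and re-ranks, recording one step per
subset size from n down to 1. Each step's AUC/MCC come from meta-level OOF
probabilities, not a refit-on-all evaluation. The best subset is the
argmax-AUC step with smallest X on ties; since a near-maximal AUC at a
plateau can be preferable to a sharp peak, the trace also reports the
smallest X opening a run of ≥ 3 consecutive sizes within 0.002 of the
maximum AUC. The accuracy pre-filter keeps members whose CV accuracy
reaches the majority-class baseline N_neg/(N_neg+N_pos), always computed
from the training labels at run time.

## Synthetic data

The generator draws negatives i.i.d. from a background residue
distribution (uniform by default; a Swiss-Prot-like preset is bundled) with
lengths uniform in 9–25, and positives from the same background plus
implanted motifs (each with its own implant probability, uniform position)
and/or a composition shift. Default class sizes (313/2908) mirror the
imbalance of curated cytokine-induction benchmarks, where the all-negative
baseline accuracy exceeds 0.902. A complementary-signal variant implants
motif A in half the positives and motif B in the other half, so one
detector view is informative on only half the positive class — the fixture
behind the stacking-dominance checks.

What this emulates — and does not: implanted motifs give a clean,
compositionally detectable signal with independent residues elsewhere.
Real bioactive peptides carry correlated residues, homologous clusters,
length–label confounds and label noise. Passing the synthetic suites
therefore demonstrates that the machinery (encodings, OOF construction,
stacking, selection, thresholding) is correct and recovers known signal;
it does not certify real-data performance levels.

## Problem sizes and numerical choices

The test and acceptance suites run small, seeded configurations chosen to
exercise every code path quickly: 12-cell mini-grids (LR/RF/LGBM × four
composition encodings) on 200/800 motif datasets for end-to-end recovery,
200/800 complementary-signal data for stacking dominance, ≤ 6-column
matrices for the SDIWC reference comparison. The full 168-cell grid is
enumerated and census-checked but trained only on demand. Tolerances: the
LR log-odds identity is asserted at 1e-6 relative; OOF reproducibility at
1e-9 absolute; the threshold scan is exact by construction (it enumerates
every achievable confusion table). Degenerate inputs are errors, not
silent fixes: single-class folds, unlabeled training rows, non-finite
features, sequences shorter than an encoder's support.

## Known limitations

- The deep-learner slots use MLP fallbacks, not the transformer/CNN/biLSTM
  architectures they are named for; the final selected stacks in practice
  contain classical members anyway.
- The bundled amino-acid-index snapshot is a small curated subset; widths
  follow the table.
- The skip-gram trainer is plain numpy and single-threaded; for corpora
  beyond tens of thousands of sequences a dedicated embedding library is
  the right tool.
- `stackpep predict` reconstructs a run from its manifest and seed rather
  than deserializing fitted estimators; exact reproduction therefore
  assumes unchanged library versions.
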