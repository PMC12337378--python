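# Methods

This note documents the models, defaults and design choices behind `icenv`,
and what the synthetic experiments do and do not demonstrate about real
metagenomic data.

## The problem and the study design

The package asks whether aligned amino-acid domain sequences (the motivating
case is the DUF3494 ice-binding-like domain, Pfam PF11999) carry
environment-specific signatures, using five environment labels: polar
marine, frozen sediment, rock, glacier ice and subsurface. The design is
heavily imbalanced — the default class ratios are
polar_marine : rock : frozen_sediment : glacier_ice : subsurface ≈
32649 : 7849 : 7563 : 4987 : 453, scaled to a user-chosen total by
largest-remainder rounding with a floor of two sequences per class so
stratified splitting stays defined. The imbalance is the point: it exercises
the class-weighting machinery exactly where a real survey needs it.

## Synthetic data generator

`generate_dataset` draws a rectangular alignment (default 185 columns, the
width of the filtered study alignment) in which every cell is an i.i.d. draw
from a background distribution (default uniform over the 20 residues),
except at *planted* positions, where each environment draws from its own
residue distribution. Gaps are then injected independently per cell at
`gap_rate`; a sequence's unaligned form is its aligned form with gaps
removed. Generation is bit-for-bit reproducible for a fixed config.

What the generator emulates: environment-specific column conservation (a
dominant residue per environment with configurable consistency), class
imbalance, and light gap structure. What it does not emulate: phylogenetic
autocorrelation between sequences (every sequence is independent given its
label), insertion/deletion structure, alignment error, or any real
biochemistry in the embedding space. Consequently, passing the synthetic
suites shows that the *pipeline machinery* is correct and sensitive —
classifiers find planted signal and sit at chance without it — not that real
environments are separable; on real data, phylogenetic signal alone can
carry much of the classification.

The default face map reproduces the published assignment of alignment
positions to β-solenoid faces (e.g. 71–73 bottom b-face, 105–109
second-from-bottom a-face); rows spanning two faces are labelled `between`.
The named 7-residue vertical columns (`b_col2`, `b_col4`, `a_col0`) have
only their size and bottom residues (87 and 89, b-face) on record; the
remaining default membership takes one position per face row from the top
of the solenoid down and is an explicit placeholder — experiments that
depend on exact membership should pass their own column definitions, which
the `FaceMap` type accepts.

## Curation

Domain hits come from hmmer per-domain tables (`domtblout`): envelope
coordinates from the `env from`/`env to` columns, the independent e-value as
the domain e-value, 1-based inclusive coordinates throughout. Defaults
remove hits shorter than 150 *residues* or weaker than 1e-10; because the
removal rules are strict inequalities, boundary values pass. The length unit
is residues (the workflow filters translated gene models); a `unit="bp"`
flag divides the threshold by three for nucleotide-scale thresholds.
Multi-domain genes are renamed `<gene>_1 … <gene>_k` so every extracted
envelope is uniquely labelled.

## Diversity and conservation

Gap filtering is two-stage and order-sensitive: columns with > 50 % gaps are
removed first, then sequences with > 30 % gaps measured on the
column-filtered alignment — a sequence gappy only inside removed columns
survives, and the tests pin this ordering.

Shannon diversity is natural-log, per column, over the 20 residues with gaps
excluded from the proportions (an all-gap column is defined as H = 0);
a uniform column reaches ln 20 ≈ 2.996, which matches the ~[0, 3] range of
diversity profiles in this literature. The rolling mean uses a centred
window of 3 with edge truncation (symmetric choice; the window placement is
not otherwise constrained). A position is conserved when (a) its rolling
diversity is below 1.50 and (b) the next position's diversity is not more
than 0.1 below it — condition (b) guards against a single low column
dragging the window down. Whether (b) compares the rolling or the raw value
at the next position is ambiguous in the source protocol; the default
compares rolling values, and `compare_rolling=False` switches to raw.

## Encoding

The embedding contract is a fixed-length n × d real matrix, d = 1280 by
convention (the width of a mean-pooled penultimate-layer representation of a
large protein language model). The bundled `SurrogateEncoder` assigns each
residue a fixed d-vector drawn once from a seeded standard normal and embeds
a sequence as the mean of its residues' vectors. It is a pure function of
(sequence, d, seed) and is sensitive to single substitutions (a mutation at
one of L residues shifts the embedding by (v_new − v_old)/L) — the two
properties the downstream stages rely on — but it carries *only*
compositional information and no semantics of a trained language model.
Externally computed embeddings (real language-model averages) load from
delimited tables via `read_embeddings` and flow through the identical
downstream code. Tests and the acceptance script use d = 64: the analyses
are invariant to d beyond signal-to-noise, and 64 keeps the suites fast.

One-hot positional encoding expands each alignment column to a 21-symbol
block (20 residues + gap): a 185-column alignment yields 3885 features.

## Classification

`FeedForwardClassifier` is a NumPy implementation of the study's network:
dense hidden layers (default 800/400) with ReLU, inverted dropout at 50 %
during training only, softmax output, categorical crossentropy with
per-example class weights, and Adam (lr 1e-4, β₁ 0.9, β₂ 0.999, ε 1e-8 —
conventional values where unstated) at batch size 512 for 200 epochs.
(The source protocol states both 200 and 300 epochs in different places;
200 is the default and `epochs` is a parameter.) Weights are Glorot-style
uniform, seeded; training is deterministic single-threaded. The epoch loss
reported is the mean weighted crossentropy, so all-unit class weights
reproduce unweighted training exactly. Class weights follow the balanced
convention w_c = N/(K·n_c), which satisfies Σ w_c n_c = N.

The 80/20 split is a hand-implemented stratified contract: per class,
round(n_c·0.2) members to the test side, deterministic per seed.
Cross-validation uses stratified 5-fold splitting with per-fold
training/validation loss curves; the returned model is refit on the full
training data. Defaults at test scale are smaller (hidden 64/32, lr 1e-3,
60 epochs) purely for speed; the architecture code path is identical.

Benchmarks: (1) multinomial logistic regression via scikit-learn's saga
solver with L2 penalty and the same class weighting (a test verifies the
fitted optimum zeroes the gradient of the weighted ridge likelihood);
(2) a per-environment profile scorer — per-position residue frequencies
over the 21-symbol dictionary with Laplace pseudocount 1, query assigned to
argmax summed log frequency, ties broken toward the first environment in
sorted order with a warning. This is a gap-aware position-specific scoring
model without insert states; it preserves the logic of an
HMM-per-environment benchmark (train on 80 % per class, classify the rest
by best score) without reproducing bit-score semantics.

McFadden's pseudo-R² is 1 − ℓ_model/ℓ_null with the intercept-only
class-frequency model as the null.

## Genetic-algorithm rule mining

Rules are flat chains of atoms `(position op residue)` with `op ∈ {=, <>}`
over the 21 symbols (gap included), joined by AND/OR evaluated strictly
left-to-right with no precedence — matching the flat rule strings of the
discriminant-function-analysis formulation; a parenthesised tree mode is
deliberately out of scope. Fitness is the 2×2 phi coefficient of rule truth
versus one-vs-rest class membership, minus a linear complexity penalty
rate·(atoms − 1) with rate 0.005 by default: the penalty's functional form
is not on record, and linearity is the simplest monotone choice; the
published 2- and 20-parameter regimes map to `max_params` caps. Any zero
marginal defines phi = 0.

Evolution: a population (default 500) of random expressions — random atoms
draw their residue from the symbols *observed* at the chosen position,
keeping the search data-driven — is scored each generation; the top 50 %
breed, 10 % fresh immigrants enter, and the remainder are children made by
single-point recombination on atom lists (probability 0.3) or one of six
mutation moves (change position/residue/operator/connective, add or remove
an atom within `max_params`). The best-ever rule is tracked elitistically,
so best penalised phi is non-decreasing; ties break toward fewer atoms,
then lexicographic (position, operator, residue) for determinism.
Replicates run with independently derived seeds and the ± on aggregated
rule accuracies is across replicates (the source does not say whether its
spread is replicates or folds).

The default run length is 2500 generations; the recovery experiments in the
tests use 200 generations on 500 sequences, where a perfectly
discriminating single-position signal is recovered at phi = 1.0 in
essentially every replicate.

## In silico mutagenesis

A plan names a set of alignment positions. For each test sequence, every
non-gap cell at a plan position is replaced by a uniform draw over the 19
other residues (`allow_original=True` switches to all 20); gaps, ids and
lengths are untouched, so the Hamming distance to the original equals the
number of non-gap plan cells. Mutants are gap-stripped, re-encoded with the
training encoder, and re-predicted; results report overall and
per-environment accuracy before and after. Mutagenesis operates on the
curated envelope sequences (the aligned coordinate system), not on
full-length parent proteins. A stratified subsample (default 100 sequences,
equal per environment) reproduces the evaluation-subset protocol. On
synthetic data, randomising the planted columns collapses accuracy to
chance while randomising inert columns leaves it within binomial noise of
baseline — the synthetic analogue of the published 84 % → 21 % collapse
when the key b-face column is mutated.

## Feature attribution and physicochemical regression

Shapley attribution uses Monte-Carlo permutation sampling: per instance and
sampled feature ordering, features flip one at a time from a paired
background row's value to the instance's value, and each feature's marginal
change in the model output is accumulated. Because the chain telescopes,
per-instance attributions sum exactly to f(x) − f(z) per sample, so the
efficiency property f(x) − E[f(background)] holds up to the Monte-Carlo
error of the background mean; for a linear model the estimator recovers
w_j·(x_j − E[z_j]). Kernel-weighted SHAP is intentionally not reimplemented;
the estimator is labelled as permutation-sampling. Permutation importance
(scikit-learn) is the cheap cross-check; on a single-signal model both
methods rank the same top feature.

Selected embedding features are regressed (simple least squares, R² =
squared Pearson r) on sequence-averaged residue scales, whole-sequence or
restricted to one protein face. The bundled scales are Kyte–Doolittle
hydropathy, Zamyatnin residue volume (a side-chain-size scale), and
positive/negative charge; arbitrary scales (e.g. AAindex exports such as
VHSE descriptors) load from delimited text, since published analyses of
this kind use steric/electronic descriptor sets whose exact tables are
databases in their own right. Top-k feature selection defaults to k = 3 by
mean |attribution|.

## Pipeline

`run_pipeline` executes simulate → gap-filter → diversity → encode → train →
GA → mutagenesis → interpretation from one config mapping (YAML via the
CLI), with per-stage `enabled` toggles; disabling the GA leaves mutagenesis
running on face-map column plans alone. Every artifact is written with a
SHA-256 checksum into `manifest.json` together with the config and seeds;
deterministic stages reproduce identical checksums on rerun. Stage defaults
equal the study protocol values; the integration tests run the whole loop at
total = 240 sequences, d = 32, 15 epochs in about a second.

## Numerical choices and degenerate inputs

- Probabilities are clipped at 1e-12 inside crossentropy; a non-finite loss
  aborts training with diagnostics rather than continuing.
- Distributions must sum to 1 within 1e-9; gap_rate lives in [0, 1).
- All-gap columns: diversity 0; all-gap column summaries raise.
- Empty sequences (after degapping) are rejected by the encoder.
- Profile-score ties and equal-penalised-phi rules have deterministic,
  documented tie-breaks.
- Seeds: every stochastic component takes an explicit seed; derived seeds
  stay below 2³¹.

## Known limitations

- The surrogate encoder is order-invariant, so positional signal reaches
  the classifier only through composition; planted-signal experiments are
  designed accordingly. Real language-model embeddings would add
  order-sensitive structure the synthetic suites cannot probe.
- The profile benchmark assumes positional independence; it can match or
  beat the network whenever the signal is positional and i.i.d., and the
  test suite exploits exactly this to separate the two model families.
- The GA explores flat expressions only; deeply nested boolean structure is
  out of scope.
- Synthetic class counts, not real metagenome counts, drive all shipped
  experiments; no claim about real DUF3494 separability follows from the
  tests passing.
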