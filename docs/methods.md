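# Methods

## Problem and model

The package regresses drug–target binding affinity on Davis-style panels:
a dense matrix of dissociation constants Kd (nanomolar) over a drug
library and a protein set, transformed to pKd = −log10(Kd·10⁻⁹ + 10⁻¹⁰).
The 10⁻¹⁰ offset makes Kd = 0 finite (pKd = 10); we evaluate the
algebraically identical form 10 − log10(10·Kd + 1), which returns exactly
10.0 at Kd = 0 in floating point and is well conditioned near zero. Pairs
with Kd ≤ 50 nM are labeled positive; the boundary is inclusive and
configurable.

The estimator is a three-tunnel feed-forward network. The drug tunnel is
an MLP (1024 → 256 → 64 → 256, ReLU) on the 1024-bit radius-2 Morgan
fingerprint; the protein tunnel stacks three 1-D convolutions (32 filters
each) over the 1000 × 26 one-hot sequence matrix followed by global max
pooling; the negative tunnel is the drug tunnel applied with shared
weights to a sampled weak binder for the record's protein. Because the
two encoders end at different widths (256 vs 32), both are passed through
a learned affine projection into a common 256-d space; this is what makes
the triplet loss's Euclidean distances between protein and drug
representations well defined. Kernel lengths default to 4/8/12 (the
convention of the CNN encoders this architecture descends from); a
literal preset of 1/2/3 is selectable via
`ModelConfig.literal_kernels()`.

The head consumes the concatenated protein (anchor) and drug embeddings
of the record — the negative embedding feeds only the triplet term, since
the regression target belongs to the (drug, protein) pair, not to the
sampled negative. The objective is

    total = MSE(pKd̂, pKd) + λ · mean over positive records of
            max(‖a−p‖² − ‖a−n‖² + M, 0)

with margin M = 1 and λ = 1 by default; a batch without positive records
contributes no triplet term. Triplets are formed only for positive
records: the negative-sample matrix is fully populated, but a triplet
anchored at a weak-binding pair would not express "pull the true binder
closer".

## Negative sampling

The negative-sample matrix assigns each cell (i, j) a drug drawn
uniformly (seeded) from the drugs with Kd > boundary against protein j.
A column with no negative drug falls back, with a warning, to the pooled
negatives of the other proteins; a dataset with no negatives anywhere is
rejected. Validation of negative SMILES parses the set of unique strings
rather than every cell, which keeps a 68 × 442 panel (30 056 cells, at
most 68 unique drugs) fast.

## Training

Adam (lr 10⁻⁴, batch 256, 100 epochs by default) minimizes the combined
loss; the 7:1:2 train/validation/test split uses floor sizes for
validation and test with the remainder assigned to train. The checkpoint
with the lowest validation MSE is returned (MSE is the declared loss;
no early stopping, fixed epoch budget). Runs are bit-for-bit reproducible
for a fixed seed: parameter initialization, epoch shuffling and dropout
masks draw from generators seeded with `seed`, `seed+1`, `seed+2`.

Two numerical choices matter on small data and are part of the package's
training procedure:

* **He-scaled uniform initialization** (limit √6/√fan_in) for all weight
  matrices. The ReLU stacks are six and five layers deep per path; with
  smaller fan-in-only scaling the signal attenuates and most of a short
  training budget is spent recovering, which shows up as train-set CI
  barely above chance.
* **Output-bias initialization at the training-target mean.** pKd targets
  center near 5 while a fresh network predicts near 0; with Adam's
  step-size-bounded updates, walking the bias there would consume
  thousands of steps, so the bias starts at the mean and gradients go to
  structure from step one.

The implementation is NumPy with hand-derived reverse-mode gradients
(convolutions as im2col + GEMM); the test suite checks every parameter
block against central finite differences at 10⁻⁴ relative tolerance.
Inference is deterministic (dropout inactive).

## Evaluation

Concordance index: over ordered pairs with distinct true values, a
correctly ordered prediction scores 1, a tied prediction 0.5, a reversed
one 0; pairs tied in the truth are excluded, and an input whose true
values are all equal is an error. The implementation is vectorized
O(n²); tests compare it with an independent pure-Python double loop and
with lifelines' implementation.

## Repositioning

Candidates are ranked by predicted pKd descending (the transform is
decreasing in Kd, so the top of the list is the strongest predicted
binders). Filters are annotative: rows below the molecular-weight
threshold (average molecular weight, the pharmacology convention,
strictly < 200 Da by default) or on a user-supplied exclusion-id list —
the honest encoding of manual curation steps such as removing topical
drugs — keep their scores and are flagged; survivors are re-ranked
consecutively. Ties keep input order, making the ranking deterministic.

## Synthetic data

The generator emulates the panel shape, not kinase chemistry: drugs are
seeded concatenations of chemically closed SMILES fragments (validity
checked by parsing, distinctness on canonical form); proteins are uniform
random sequences of length 200–1200 over the 20 standard residues;
affinities follow a planted bilinear model pKd* = 5 + s·⟨u_d, v_p⟩ with
u, v ~ N(0, I_k), clipped to (0, 10], plus Gaussian noise (default sd
0.2 pKd units), then mapped back to Kd and clipped to [1, 10000] nM.
With latent dimension 4 and scale s = 1 the positive fraction lands near
10–15%, similar in spirit to a selectivity panel. What passing tests show
is that the pipeline can recover a planted low-rank interaction from
featurized identities; they do not show that real kinase affinities are
predictable at any particular accuracy — real sequences share family
structure, real fingerprints encode shared substructure, and real Davis
data has heavy censoring mass at 10 000 nM that the generator does not
reproduce.

The learning-sanity check trains on a 40-drug × 20-protein panel (800
records, 560 training) for 30 epochs with batch 16 and learning rate
10⁻³ — the package's small-data preset; the full-panel defaults
(batch 256, lr 10⁻⁴) would take only ~66 gradient steps on a panel this
size, too few for any optimizer to move. Success is held-out CI ≥ 0.7,
with a permuted-label control (labels shuffled before splitting, scored
against the true held-out labels) expected at chance.

## Known limitations

* The protein encoder discriminates sequences only through max-pooled
  motif detectors; unrelated random sequences are near the hard end for
  it, and short training budgets leave it the weaker tunnel.
* Checkpoints store weights as `.npz` plus a JSON sidecar with config,
  vocabulary and fingerprint parameters; there is no cross-version
  migration.
* No GPU or multi-device path; the implementation targets CPU panels up
  to a few hundred drugs/proteins.
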