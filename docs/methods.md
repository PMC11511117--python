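# Methods

## Model

Each stage of the cascade is the same small convolutional sequence
classifier. A peptide is mapped to a fixed-length integer vector: residue
*i* becomes the token of symbol *i* for the first `fixed_length` residues
(N-terminal prefix kept on truncation), the remainder is the pad token 0;
token 1 is reserved for out-of-vocabulary symbols and real residues start
at index 2. The vocabulary is the fixed 25-symbol alphabet (20 canonical
amino acids plus B, Z, X, U, O) in canonical order rather than a
data-derived frequency order, so tokenization never depends on the training
corpus.

The network is

    embedding (vocab 27 × dim 16)
    → IntDropout (training only)
    → Conv1D (32 filters, kernel 5, valid) + ReLU
    → Conv1D (32 filters, kernel 5, valid) + ReLU
    → global max pooling over positions
    → dropout
    → dense softmax

implemented directly in NumPy with hand-written gradients and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷). The default configuration has 8,308
trainable parameters; the constructor enforces a 50,000-parameter ceiling
implicitly through the declared layer sizes, and the count is exposed as
`n_parameters`. Global max pooling makes the classifier position-invariant
over the (truncated) input, which suits motif-bearing peptides.

*IntDropout* masks each non-pad integer token to the pad index with
probability equal to the dropout rate, before embedding and only during
training. The masked token therefore shares the pad embedding — the
"no information" vector — rather than a dedicated mask symbol; this is a
deliberate, switchable choice (`use_int_dropout`). Pad positions are never
masked: masking them would be a no-op for the loss but would distort the
masked-fraction statistics.

### Training hyperparameters

| parameter | default | notes |
|---|---|---|
| learning rate | 0.001 | Adam |
| dropout rate | 0.35 | all dropout layers, including IntDropout |
| epochs / batch | 24 / 32 | housekeeping and four-class toxin models |
| epochs / batch | 8 / 8 | each functional-ensemble member |
| fixed length | 128 residues | see truncation sweep below |
| embedding dim | 16 | |
| conv filters / kernel | (32, 32) / 5 | chosen to stay far under the parameter ceiling |

The housekeeping stage has no separately stated regime, so it trains with
the toxin model's (24 epochs, batch 32).

Determinism: initialization, batch shuffling and both dropouts draw from a
single `numpy.random.Generator` seeded from `TrainingSpec.seed`, so two
trainings with the same seed on the same numeric backend are bit-identical.
The test suite relies on within-process reproducibility only.

## Stratified splitting

`capped_fraction_split` draws, per class of size N, a validation set of
⌈0.25 N⌉ members, then moves training members beyond 150 into validation.
Ceiling rounding is derived, not assumed: it is the only rounding rule that
reproduces all four published per-class train/validation counts
simultaneously (89 → 66/23 excludes floor and round-to-nearest).
`fixed_train_split` takes exactly 32 members per class with no prior
fraction. Membership is uniform per class under a recorded seed; repeated
splits with different seeds give identical counts, which is what makes
split-to-split accuracy variance a meaningful summary (reported as mean and
*sample* SD, n−1 denominator — the convention that matches the published
ICK and KTx summary rows; the published NaTx and venom rows are internally
inconsistent with any rounding of their own split values and are not used
as anchors).

## Cascade semantics

Stage 1 classifies by argmax with no probability threshold. Stage 3
requires exactly three ensemble members and keeps a label only on a
unanimous vote; of the 27 ordered label triples over three classes exactly
3 classify and 24 discard. The result conserves its input
(classified + filtered_out + discarded_by_consensus = n) and the cascade
accepts entry without stage 1 for inputs already pre-selected by a
similarity screen. The unanimity rule trades recall for precision: on
synthetic functional hold-out data the ensemble keeps roughly two thirds of
sequences and is nearly always right on those it keeps, while sequences
without functional sub-class structure are overwhelmingly discarded rather
than guessed.

## BLAST concordance

Tabular 12-column hits are parsed verbatim; per query the best hit is the
lowest e-value, ties broken by highest bitscore, then first occurrence, so
the labeling is deterministic and line-order-independent whenever the
(e-value, bitscore) optimum is unique. The default acceptance cutoff is
e ≤ 10⁻¹⁰, the weak end of the range typically seen on accepted toxin
annotations; it is a parameter, not a constant. Query and subject ids are
trimmed at the first whitespace, mirroring FASTA header handling.

## Statistics

The multiclass MCC uses the covariance/sum form computed from the confusion
matrix; degenerate matrices (zero denominator) return 0 by documented
convention. The annotation-count comparison uses Welch's unequal-variance
two-sample t-test (two-sided); a paired variant is exposed but not the
default because the species sets need not coincide between analyses. Two
identical zero-variance samples return (t = 0, p = 1) where the raw formula
is 0/0.

## Synthetic data

The generator emulates what makes real toxin families learnable: a short
class-specific cysteine-scaffold motif against random background. Defaults
(the package's study conditions): four classes — ICK, KTx, NaTx, venom —
each with a distinct 8-residue motif, 250 sequences per class, substitution
noise 0.05 per motif position, uniform background over the 20 canonical
residues, and realistic length ranges (ICK 35–70, KTx 25–55, NaTx 58–78,
venom 80–160 residues). Motifs are implanted fully within the first 64
residues, so the truncation sweep is meaningful by construction: 16- and
32-residue inputs cut into motifs, 64 and 128 do not. The housekeeping
preset mixes all four scaffolds into one "toxin" class against
motif-free background (its classes are balanced, so it is split with a
plain 0.25 fraction — the 150-cap exists to rebalance uneven classes and
would only discard data here). A functional preset provides the three
NaTx sub-classes at 120/120/250.

What the generator does **not** emulate: homology within families (every
sequence is an independent draw, so there is no train/validation redundancy
problem), signal peptides and propeptides, realistic residue composition
(an optional background frequency table exists but is off by default), and
overlap between classes. Passing the recovery experiment therefore shows
that the pipeline's machinery — encoding, splitting, training, cascading,
scoring — is correct and that the architecture can learn scaffold-like
signal at these sample sizes; it does not certify accuracy on real venom
transcriptomes, where classes are less separable.

## Problem sizes and numerical choices

The recovery experiment trains the default model at truncation lengths 16,
32, 64 and 128 on the default 1,000-sequence dataset; the full run is a few
minutes on one CPU, which is the scale everything in the package is sized
to. Probability ties in argmax break to the lowest class index. Sequences
shorter than 9 tokens cannot pass two kernel-5 valid convolutions, so
`fixed_length ≥ 9` is enforced at construction. Softmax is computed with
max-subtraction; cross-entropy adds 10⁻¹² inside the log. Non-alphabet
characters in FASTA input are mapped to X with a logged warning rather than
rejected, because transcriptome translations routinely contain stray
symbols and a hard failure would abort batch runs.

## Known limitations

- No redundancy-aware splitting: real toxin datasets contain near-identical
  sequences, and random splits overestimate validation accuracy there. The
  synthetic generator sidesteps this by construction; the splitter
  deliberately does not deduplicate.
- The length filter operates on residues (amino acids), with 200 as the
  conventional threshold; it is inclusive at the boundary.
- Model serialization uses `.npz` weights plus a JSON sidecar; no
  cross-framework format is attempted.
- Training is single-threaded NumPy; there is no GPU path and no
  hyperparameter search beyond the truncation sweep.
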