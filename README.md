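# toxcascade

Cascaded convolutional classification of scorpion venom peptides from
protein FASTA.

## The problem

Scorpion toxins are short, cysteine-rich peptides (mostly under 150
residues) that act on ion channels. Their small size makes them easy to
miss or mislabel in transcriptome annotation: similarity search alone
struggles with divergent potassium-channel toxins, and curated HMMs lag
behind new venom sequencing. `toxcascade` annotates translated
transcriptomes with a cascade of three very small convolutional
classifiers:

1. **Housekeeping filter** — binary toxin vs non-toxin screen.
2. **Toxin classifier** — four classes: inhibitor-cystine-knot peptides
   (ICK, calcins/DDH), potassium-channel toxins (KTx, including scorpines
   and Kunitz-type inhibitors), sodium-channel toxins (NaTx), and other
   venom proteins.
3. **Functional ensemble** — three identically configured models vote on
   whether an NaTx acts on insect channels only, mammal channels only, or
   both; a sequence keeps a label only on a **unanimous** vote and is
   discarded otherwise.

Every model is the same compact architecture, implemented in NumPy and
fully seeded:

    token embedding → IntDropout → Conv1D → ReLU → Conv1D → ReLU
        → global max pool → dropout → dense softmax

trained with Adam (learning rate 10⁻³) on the sparse categorical
cross-entropy, dropout 0.35 everywhere (including *IntDropout*, which masks
integer residue tokens to the pad index before embedding). Sequences are
truncated or padded to a fixed length, 128 residues by default. The default
configuration has 8,308 trainable parameters — small networks are the
point.

Around the models the package provides the field-standard machinery:

- **Stratified splitting.** Per class, a 0.25 validation fraction
  (validation count = ⌈0.25 · N⌉) followed by capping the training set at
  150, surplus moved to validation (`capped_fraction_split`); or a fixed
  32-sequence training draw per class (`fixed_train_split`) for the
  functional dataset, where two classes have only 42 members.
- **Evaluation.** Confusion matrices, per-class accuracy, the
  multi-category Matthews correlation coefficient
  MCC = (c·s − Σₖ pₖtₖ) / √((s² − Σₖ pₖ²)(s² − Σₖ tₖ²)),
  mean/SD over repeated splits, and Welch's two-sample t-test.
- **BLAST concordance.** Parse 12-column tabular output (`-outfmt 6`),
  assign per-transcript best-hit classes (lowest e-value, ties by
  bitscore), and cross-classify similarity labels against cascade labels.
- **Synthetic data.** A seeded generator of class-structured peptides
  (distinct cysteine-scaffold motifs per class, configurable lengths and
  substitution noise), so the whole cascade is testable without any
  external download.

## Worked example

```python
import toxcascade as tc

ds = tc.generate(tc.default_toxin_spec(seed=7, n_per_class=120))
split = tc.capped_fraction_split(ds, tc.SplitSpec(seed=7))

clf = tc.TrainedClassifier(
    tc.EncoderSpec(fixed_length=128), ds.class_labels, tc.TrainingSpec(seed=7)
)
clf.fit(split.train_subset(ds), split.val_subset(ds))

val = split.val_subset(ds)
cm = tc.confusion(val.labels, clf.predict(val.records), labels=ds.class_labels)
print(cm.per_class_accuracy())
print(round(tc.multiclass_mcc(cm), 4))
```

prints

```
{'ICK': 1.0, 'KTx': 1.0, 'NaTx': 1.0, 'venom': 1.0}
1.0
```

— with 90 training sequences per class the 8,308-parameter model recovers
all four motif classes perfectly on held-out data (MCC 1.0 means a perfect
confusion-matrix diagonal). Truncating inputs to 16 or 32 residues instead
of 128 cuts into the implanted motifs and drops held-out accuracy to 45%
and 78% respectively, while 64 and 128 residues both reach 100%
(`examples/02_truncation_sweep.py`).

The same flows are scriptable from the shell:

```bash
toxcascade synth --preset toxin --fasta toxins.fasta --csv toxins.csv --seed 7
toxcascade train --csv toxins.csv --model toxin_model --seed 7
toxcascade cascade --fasta species.fasta --toxin toxin_model --out calls.tsv
```

See `examples/` for one narrative script per capability (training,
truncation sweep, full cascade, BLAST concordance, split statistics).

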