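# csopred

Prediction of **cysteine S-sulphenylation (CSO) sites** from protein
sequence.  CSO is the reversible oxidation of a cysteine thiol to sulphenic
acid — a regulatory post-translational modification that is expensive to map
experimentally, which makes sequence-based site predictors useful for
prioritising candidate cysteines.

The package is a complete, tested toolkit for building such predictors:

* **Data preparation** — FASTA + site-table ingestion, extraction of
  odd-length peptide windows centred on each candidate cysteine (gap-padded
  at protein termini, default L = 33), enumeration of negative sites (all
  unmodified cysteines of modified proteins), 40%-identity redundancy
  reduction with a class-asymmetric retention rule, and a stratified
  11-group split (10 cross-validation groups + 1 independent test group).
* **Six feature encodings** — integer indices (NUM), one-hot (binary),
  sliding amino-acid composition (EAAC), k-spaced residue-pair composition
  (CKSAAP), AAindex physicochemical profiles with forest-based property
  selection, and a class-contrast PSSM built from per-cell two-sample
  t-tests with Benjamini–Hochberg correction.
* **Five classifier families** — a recurrent network with a learned residue
  embedding (`lstm_we`, the flagship), a 1-D convolutional variant
  (`cnn1d_we`), a 2-D convolutional network on 20×20 PSSM images
  (`cnn2d_pssm`), random forests, and RBF-kernel SVMs.  The neural models
  run on a small, gradient-checked numpy engine shipped with the package
  (embedding, LSTM, convolutions, Adam, dropout, training-loss early
  stopping); forests and SVMs wrap scikit-learn.
* **Evaluation** — ACC / SN / SP / MCC at specificity-anchored thresholds,
  ROC-AUC, AUC01 (unnormalised area below 10% false-positive rate), k-fold
  cross-validation with per-fold encoder fitting, specificity-calibrated
  decision thresholds (80/85/90%), and paired-t model comparison with
  Benjamini–Hochberg adjustment.
* **Motif analysis** — a two-sample-logo style table of flank residues
  significantly enriched or depleted around modified cysteines (Bonferroni
  over L−1 positions × 20 residues).
* **Hyper-parameter search** — exhaustive grids for forests/SVMs, and a
  Gaussian-process Bayesian optimiser (Matérn + expected improvement) for
  the neural models.
* **Synthetic data** — a seeded generator of proteomes with a planted
  CSO-like motif (R/K enriched, C/L/E/G depleted in the flanks), so the
  entire pipeline is testable end-to-end without any download.

## The model at the core

A candidate site is the window `s = s₋₁₆ … s₀ … s₊₁₆` (L = 33) centred on a
cysteine.  Each symbol of the 21-letter alphabet `AVLIFWMPGSTCYNQHKRDE-` is
mapped to an integer, embedded into a learned 4-dimensional vector, fed
through an LSTM with 32 hidden units, a 16-unit ReLU dense layer, and a
sigmoid output giving `P(modified | s)`.  Training minimises binary
cross-entropy with Adam (batch 512), stopping early after 50 epochs without
training-loss improvement and restoring the best checkpoint.

Evaluation follows the conventions of this literature: AUC and AUC01 are
threshold-free; ACC/SN/SP/MCC are reported at the per-fold threshold whose
specificity is closest to 0.80.

## Worked example

```python
from csopred import models, synthetic
from csopred.dataio import segment_labels, split_dataset
from csopred.evaluation import evaluate_scores

spec = synthetic.SyntheticSpec(seed=1)          # ~500 pos / ~2650 neg sites
pos, neg = synthetic.generate_segments(spec)    # 33-mer windows
split = split_dataset(pos + neg, n_groups=11, seed=1)
train = [s for g in split.cv_groups for s in g]

model = models.train(models.build_lstm_we(max_epochs=150),
                     train, segment_labels(train), seed=1)
scores = models.predict_scores(model, split.independent_test)
print(evaluate_scores(scores, segment_labels(split.independent_test)))
```

On the held-out group this prints (seed 1, after redundancy reduction the
training pool is ~2450 windows):

```
{'ACC': 0.83, 'SN': 0.97, 'SP': 0.80, 'MCC': 0.61,
 'AUC': 0.99, 'AUC01': 0.094, 'threshold': 0.23}
```

meaning: at the specificity-0.80 operating point the model recovers 97% of
the truly modified cysteines, with a rank quality (AUC 0.99) close to the
generator's Bayes optimum (~0.98) and 94% of the achievable low-false-
positive-rate area (AUC01 0.094 of 0.1).

The same pipeline is available from the shell:

```bash
csopred simulate --seed 1 --out-dir data/
csopred train --config train.yaml            # checkpoint + CV report
csopred predict --model model/ --fasta query.fasta --out predictions.tsv
csopred logo --fasta data/proteins.fasta --annotations data/sites.tsv --out logo.tsv
```

`predict` writes one row per cysteine: header, position, window, score, and
Y/N calls at the stored 80/85/90% specificity thresholds.

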