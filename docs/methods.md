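# Methods

This note documents the statistical and numerical choices behind csopred:
what each stage assumes, which knobs matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Windows, negatives, and coordinates

All coordinates are 1-based and inclusive.  A site becomes the odd-length
window of `L` residues centred on its cysteine; positions beyond a protein
terminus are filled with the gap symbol `-`, so gaps occur only as a
contiguous prefix and/or suffix.  The default `L = 33` is the optimised
window length for this problem class; `L = 35` (the common pre-optimisation
choice) is accepted everywhere via the `L` argument.  Residues outside the
20-letter alphabet (X, B, Z, U, ...) are accepted on input and mapped to
`-` during windowing, with a logged warning — the encoders define exactly
21 symbols.

Negative sites are *all remaining cysteines of proteins that contain at
least one modified site*.  Proteins never seen modified contribute nothing:
absence of evidence in an unprofiled protein is not evidence of absence.

## Redundancy reduction

Identity between two windows is the fraction of positions (gaps included)
with equal symbols — no alignment, since windows are already registered on
the central cysteine.  A greedy scan keeps a window iff its identity with
every previously kept window is ≤ 0.40 (strictly greater removes).
Positives are scanned before negatives, so a cross-class conflict always
discards the negative; within a class, the scan order is a seeded
permutation of a canonical sort, making the surviving member random but
reproducible and independent of input order.  One practical consequence:
windows near protein termini share long gap runs that count as matches, so
terminal sites are removed at a somewhat higher rate.

## Encodings

* **NUM** — index into `AVLIFWMPGSTCYNQHKRDE-` (0..20).
* **Binary** — 21-wide one-hot per position.
* **EAAC** — amino-acid frequencies in every fully contained width-5
  sliding window.  The denominator is the fixed window width `w`, so gaps
  dilute the composition (a window's 20 frequencies sum to `1 − gaps/w`)
  and the feature count stays `20·(L−w+1)` regardless of padding.  Windows
  are not slid past the segment boundary.
* **CKSAAP** — ordered symbol-pair frequencies at separations k = 0..5 over
  all 21 symbols (441 pairs per k, each k-block normalised by its `L−k−1`
  pair count).  The gap symbol is retained: terminal gap pairs are
  informative about sequence ends.
* **AAindex** — per-residue physicochemical values; the gap maps to 0.
  Property selection drops scales with missing values, then ranks the rest
  by the cross-validated AUC of a single-property random forest, keeping
  those above a threshold (default 0.7).  A small bundled table of
  well-known published scales (hydropathy, hydrophilicity, mass, pI,
  polarity, volume, charge) plus one deliberately incomplete synthetic
  record supports tests and small analyses; any AAindex1-format flat file
  can be supplied instead.
* **PSSM** — per (position, symbol) cell, a two-sample t-test compares 0/1
  occurrence indicators between classes; p-values are Benjamini–Hochberg
  corrected over the L×21 family, and the score is
  `(f_pos − f_neg)·(−log10 p_adj)` where `p_adj < 0.05`, else 0 — monotone
  in both effect and evidence, exactly zero under the null.  The 20×20
  image form takes the central 20 positions (offsets −10..+9) × 20 amino
  acids; the default masks each row to the observed residue, a full-profile
  variant is available (`mode="profile"`).  PSSMs are always fitted on
  training folds only.

### Calibration of the indicator t-test

Two choices keep the t-test honest on 0/1 data, and both were driven by
label-permutation audits (200 permutations of the default synthetic
dataset):

1. **Pooled (Student) variance, not Welch.**  With unpooled variances, a
   residue absent from one class contributes zero variance on that side
   and the statistic explodes; the measured family-wise false-cell rate of
   the Bonferroni logo was ~0.61 at α = 0.05.  The pooled estimate draws
   on both samples and is the natural statistic under the exchangeable
   null that permutation tests (and the logo's own guarantee) assume.
2. **Continuity correction.**  The normal/t approximation to a difference
   of binomial proportions is anti-conservative precisely around |t| ≈ 4,
   where Bonferroni and BH thresholds live; shrinking the numerator by
   `(1/n₁ + 1/n₂)/2` brings the measured family-wise rate to 0.055 at
   α = 0.05.

## Motif analysis

The two-sample logo tests the 20 amino acids at the `L − 1` flank positions
(the centre is constant cysteine — zero variance — and the gap symbol is
excluded by convention), Bonferroni-corrects over that family, and calls
cells enriched or depleted by the sign of the frequency difference.  The
output is a tidy table (offset, residue, frequencies, t, p, corrected p,
call).

## Classifiers

The neural families run on an in-package numpy engine whose backward passes
are validated against central finite differences in the test suite:

* `lstm_we` — embedding (default 4-dim; 5 for the Arabidopsis-style
  variant) → LSTM (32 units) → ReLU dense (16; 32 for Arabidopsis) →
  sigmoid.
* `cnn1d_we` — same head/tail with an unpadded width-9 convolution (22
  filters; 20 for Arabidopsis) and global max pooling.
* `cnn2d_pssm` — 5×5 convolution, 15 filters, stride 1 on 20×20 PSSM
  images → 2×2 max pooling → flatten → ReLU dense → sigmoid.  Pooling type
  and size are not fixed by the problem; 2×2 max is the conventional
  default and is configurable.

Training: Adam (learning rate 10⁻³ — conventional default, configurable),
binary cross-entropy, batch 512, maximum 500 epochs, early stopping after
50 epochs without *training-loss* improvement, best-by-training-loss
checkpoint restored.  Monitoring training rather than validation loss is a
deliberate, documented convention of this protocol; dropout (default
rate 0.2) provides the regularisation.  Initialisation and batch order are
fully seeded; runs are bit-reproducible single-threaded.

Forests default to 580 trees; SVMs use the RBF kernel and min-max-normalise
any feature matrix not already within [0, 1] (fitted on training data
only), with sigmoid-squashed decision margins as scores — a monotone map,
so only rank-based metrics (AUC, AUC01) should be compared across SVMs.

The balanced-ensemble variant splits the negatives into `n` parts (indices
randomised but row order preserved, so a 1-part ensemble is exactly a
single model) and averages the sub-model scores.

## Evaluation

Scores ≥ threshold are called positive (tie-inclusive).  Because class
ratios are unbalanced, ACC/SN/SP/MCC are reported at the per-fold threshold
whose specificity is closest to 0.80; AUC and the unnormalised AUC01
(trapezoidal area at FPR ≤ 0.1, maximum 0.1; a normalised variant exists
behind a flag) are threshold-free.  MCC is defined as 0 when its
denominator vanishes.  Deployment thresholds at 80/85/90% specificity are
calibrated on pooled out-of-fold CV predictions (the smallest threshold
reaching each level).  Model comparison uses paired t-tests on per-fold
metrics with BH adjustment across the compared metrics.

## Hyper-parameter search

Grid search enumerates finite spaces with a documented tie-break (sorted
parameter names, values in listed order, first maximum wins).  The Bayesian
optimiser encodes mixed spaces (uniform / log-uniform / integer /
categorical) into the unit cube, fits a Matérn-5/2 Gaussian process to
standardised observations, and picks the next point by expected improvement
over random candidates; it is deterministic given the seed and never
exceeds its budget.  The neural objective is the mean AUC of a small inner
cross-validation on training groups only.  The default grids (tree counts;
SVM C/γ) and the ten-dimensional neural space are repository defaults, not
published values.

## Synthetic data

The generator emulates the *structure* of a sulphenylation dataset:
proteins with annotated positive cysteines, all remaining cysteines
negative, and position-specific residue preferences around true sites.
Defaults (the package's study conditions): 560 proteins, lengths
U(150, 250), background composition close to proteome averages with
cysteine raised to 0.05 so candidate sites are dense, 10% of cysteines
marked positive with a minimum spacing of 21 residues (one site's centre
never sits inside another's tilted flank region), and a motif at offsets
±1..±10 with log-odds {R: +1.1, K: +1.1, C: −2.5, L: −2.0, E: −2.0,
G: −2.0}.

Two design points matter.  First, the tilt is renormalised *within the
named residue set*: the enrichment mass of R/K is donated entirely by the
named depleted residues, so the other 14 residues keep exactly their
background frequencies and form a true null for the logo test — planted
cells are the only real signal.  Second, the magnitudes come from a power
analysis under the pooled, continuity-corrected t-test at ~500/2500 sites:
every planted cell is individually detectable with high probability
(weakest: the C-depletion cells), and the Bayes-optimal AUC of the
generative model is ≈ 0.98, leaving room for a trained classifier to clear
0.9 held-out AUC without the task being trivial.

What the generator does **not** emulate: real secondary-structure and
surface-accessibility context, homology between proteins (beyond chance),
compositional drift across proteins, and annotation noise in public data
(a `label_noise` rate exists but defaults to 0).  Passing tests therefore
demonstrate that the machinery recovers a known signal under controlled
conditions — not that these hyper-parameters transfer unchanged to any
real proteome.

## Problem sizes used by the test suite and acceptance script

The suite trains the flagship model on the default conditions
(~2450 training windows after redundancy reduction, 150-epoch cap), runs
the 10-seed logo-recovery audit, 200 label permutations for type-I control,
and a 3-fold architecture comparison at 250 proteins with an 80-epoch cap;
`scripts/acceptance.py` repeats the main pipeline at the default scale.
These sizes are the package's reproducibility baseline; all of them scale
up by passing larger `SyntheticSpec` values or higher epoch caps.

## Known limitations

* The PSSM-of-p-values integration rule is this package's documented
  construction; the prior literature it gestures at does not print one.
* Early stopping on training loss can overfit noisy data; a
  validation-monitored mode is the obvious extension.
* The numpy engine is single-threaded and CPU-bound; it is sized for
  datasets of order 10⁴ windows, not proteome-scale training.
* SVM scores are calibrated only up to rank.
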