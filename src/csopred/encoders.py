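"""Sequence-window feature encodings.

Six schemes are provided: integer indices (NUM), one-hot (binary), sliding
amino-acid composition (EAAC), k-spaced residue-pair composition (CKSAAP),
physicochemical property profiles (AAindex), and a class-contrast
position-specific scoring matrix (PSSM) built from two-sample t-tests on
per-position residue occurrence.  A trained embedding network additionally
yields learned word-embedding features.

All encoders are pure functions of the window strings: the same input gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from statsmodels.stats.multitest import multipletests

from .alphabet import ALPHABET, AMINO_ACIDS, GAP_INDEX, windows_to_indices
from .dataio import Segment, segment_labels


@dataclass
class FeatureMatrix:
    """Numeric encoding of a segment collection under one named scheme."""

    values: np.ndarray  # (n_segments, n_features)
    scheme: str
    feature_names: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix shape inconsistent with feature names")
        if not np.isfinite(self.values.astype(float)).all():
            raise ValueError("feature matrix contains non-finite values")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# scheme={self.scheme} params={self.params}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


def _windows(segments) -> list[str]:
    return [s.window if isinstance(s, Segment) else str(s) for s in segments]


def encode_num(segments) -> FeatureMatrix:
    """Each residue to its integer index in ``AVLIFWMPGSTCYNQHKRDE-``.

    "VAMR" encodes as 1, 0, 6, 17.
    """
    idx = windows_to_indices(_windows(segments))
    names = [f"pos{j}" for j in range(idx.shape[1])]
    return FeatureMatrix(idx, "num", names, {"L": idx.shape[1]})


def encode_binary(segments) -> FeatureMatrix:
    """One-hot over the 21-symbol alphabet, concatenated in sequence order."""
    idx = windows_to_indices(_windows(segments))
    n, L = idx.shape
    onehot = np.eye(21, dtype=np.float64)[idx].reshape(n, L * 21)
    names = [f"pos{j}_{s}" for j in range(L) for s in ALPHABET]
    return FeatureMatrix(onehot, "binary", names, {"L": L})


def encode_eaac(segments, w: int = 5) -> FeatureMatrix:
    """Amino-acid composition in every fully contained sliding window of
    width ``w``: ``f(t, win) = N(t, win) / w`` for the 20 amino acids ``t``.

    Gaps count in the denominator (the window size is fixed) but never in a
    numerator, so a window's composition sums to ``1 - gaps/w``.
    """
    idx = windows_to_indices(_windows(segments))
    n, L = idx.shape
    if w > L:
        raise ValueError(f"EAAC window {w} exceeds segment length {L}")
    onehot = np.eye(21, dtype=np.float64)[idx]  # (n, L, 21)
    csum = np.concatenate(
        [np.zeros((n, 1, 21)), np.cumsum(onehot, axis=1)], axis=1
    )
    counts = csum[:, w:, :] - csum[:, :-w, :]  # (n, L-w+1, 21)
    freq = counts[:, :, :20] / w
    n_win = L - w + 1
    names = [f"win{i}_{a}" for i in range(n_win) for a in AMINO_ACIDS]
    return FeatureMatrix(freq.reshape(n, n_win * 20), "eaac", names, {"L": L, "w": w})


def encode_cksaap(segments, k_max: int = 5) -> FeatureMatrix:
    """Composition of k-spaced symbol pairs for k = 0..k_max over all 21
    symbols (441 ordered pairs per k); each k-block is normalised by its
    number of pairs, L - k - 1."""
    idx = windows_to_indices(_windows(segments))
    n, L = idx.shape
    if L <= k_max + 1:
        raise ValueError(f"segment length {L} too short for k_max={k_max}")
    blocks = []
    for k in range(k_max + 1):
        first = idx[:, : L - k - 1]
        second = idx[:, k + 1 :]
        pair_code = first * 21 + second  # (n, L-k-1)
        counts = np.zeros((n, 441), dtype=np.float64)
        np.add.at(counts, (np.arange(n)[:, None], pair_code), 1.0)
        blocks.append(counts / (L - k - 1))
    names = [
        f"k{k}_{a}{b}" for k in range(k_max + 1) for a in ALPHABET for b in ALPHABET
    ]
    return FeatureMatrix(
        np.concatenate(blocks, axis=1), "cksaap", names, {"L": L, "k_max": k_max}
    )


# ---------------------------------------------------------------------------
# AAindex physicochemical encoding


def select_aaindex_properties(
    property_table: pd.DataFrame,
    segments,
    labels: np.ndarray | None = None,
    auc_threshold: float = 0.7,
    n_trees: int = 580,
    n_splits: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank AAindex properties by single-property forest AUC and keep the
    ones above ``auc_threshold``.

    Properties with any missing value are dropped first.  Each remaining
    property is scored by the cross-validated ROC AUC of a random forest
    trained on that property's per-position encoding of ``segments``.
    Returns a DataFrame (accession, auc) sorted by AUC descending, restricted
    to AUC > threshold.
    """
    if property_table.empty:
        raise ValueError("empty AAindex property table")
    if labels is None:
        labels = segment_labels(list(segments))
    complete = property_table.dropna(axis=0, how="any")
    results = []
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for accession in complete.index:
        X = encode_aaindex(segments, complete.loc[[accession]]).values
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
        auc = cross_val_score(clf, X, labels, scoring="roc_auc", cv=cv).mean()
        results.append((accession, auc))
    ranked = pd.DataFrame(results, columns=["accession", "auc"]).sort_values(
        "auc", ascending=False, kind="mergesort"
    )
    return ranked[ranked["auc"] > auc_threshold].reset_index(drop=True)


def encode_aaindex(segments, properties: pd.DataFrame) -> FeatureMatrix:
    """Map each residue to its values under the given property rows; the gap
    symbol maps to 0 for every property."""
    if properties.empty:
        raise ValueError("no AAindex properties given")
    idx = windows_to_indices(_windows(segments))
    n, L = idx.shape
    # (21, P) lookup: amino-acid rows from the table, zero row for the gap
    lut = np.zeros((21, len(properties)), dtype=np.float64)
    for j, aa in enumerate(AMINO_ACIDS):
        lut[j] = properties[aa].to_numpy()
    if not np.isfinite(lut).all():
        raise ValueError("AAindex properties contain missing values; drop them first")
    values = lut[idx]  # (n, L, P)
    names = [f"pos{j}_{acc}" for j in range(L) for acc in properties.index]
    return FeatureMatrix(
        values.reshape(n, L * len(properties)),
        "aaindex",
        names,
        {"L": L, "properties": list(properties.index)},
    )


# ---------------------------------------------------------------------------
# Class-contrast PSSM


@dataclass
class PssmModel:
    """Position x symbol contrast between positive and negative windows.

    ``score = (pos_freq - neg_freq) * (-log10 p_adj)`` where the
    Benjamini-Hochberg adjusted two-sample t-test p-value is below ``alpha``,
    else 0 — monotone in both the frequency difference and the evidence,
    and exactly zero under the null.
    """

    pos_freq: np.ndarray  # (L, 21)
    neg_freq: np.ndarray
    t_stat: np.ndarray
    p_adj: np.ndarray
    score: np.ndarray
    alpha: float = 0.05

    @property
    def L(self) -> int:
        return self.pos_freq.shape[0]


def _indicator_ttest(f1, n1, f2, n2):
    """Vectorised two-sample t-test on 0/1 occurrence indicators given
    per-cell frequencies and class sizes.

    Two calibration choices matter because the data are 0/1 counts and the
    downstream corrections act on the far tail:

    * pooled (Student) variance, not Welch — with unpooled variances a
      symbol absent from one class contributes zero variance on that side
      and the statistic explodes for rare residues;
    * a continuity correction of (1/n1 + 1/n2)/2 on the frequency
      difference — the plain normal/t approximation to a binomial
      difference is anti-conservative around |t| ~ 4, exactly where
      Bonferroni and Benjamini-Hochberg thresholds live.

    Both keep the test calibrated under the exchangeable
    (label-permutation) null.
    """
    var1 = np.maximum(f1 * (1 - f1), 0.0) * n1
    var2 = np.maximum(f2 * (1 - f2), 0.0) * n2
    df = n1 + n2 - 2
    pooled = (var1 + var2) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    diff = f1 - f2
    cc = 0.5 * (1.0 / n1 + 1.0 / n2)
    num = np.sign(diff) * np.maximum(np.abs(diff) - cc, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, num / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (diff != 0), np.inf * np.sign(diff), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def build_pssm(pos_segments, neg_segments, alpha: float = 0.05) -> PssmModel:
    """Fit the contrast PSSM from positive and negative windows of equal L."""
    pos_idx = windows_to_indices(_windows(pos_segments))
    neg_idx = windows_to_indices(_windows(neg_segments))
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise ValueError("each class needs at least 2 segments")
    if pos_idx.shape[1] != neg_idx.shape[1]:
        raise ValueError("positive and negative windows have different lengths")
    n_pos, L = pos_idx.shape
    n_neg = neg_idx.shape[0]
    pos_freq = np.stack([(pos_idx == s).mean(axis=0) for s in range(21)], axis=1)
    neg_freq = np.stack([(neg_idx == s).mean(axis=0) for s in range(21)], axis=1)
    t, p = _indicator_ttest(pos_freq, n_pos, neg_freq, n_neg)
    p_adj = multipletests(p.ravel(), method="fdr_bh")[1].reshape(L, 21)
    p_floor = np.clip(p_adj, 1e-300, None)
    score = np.where(
        p_adj < alpha, (pos_freq - neg_freq) * (-np.log10(p_floor)), 0.0
    )
    return PssmModel(pos_freq, neg_freq, t, p_adj, score, alpha)


def encode_pssm(segments, model: PssmModel) -> FeatureMatrix:
    """Feature j is the model's score for (position j, observed symbol)."""
    idx = windows_to_indices(_windows(segments))
    n, L = idx.shape
    if L != model.L:
        raise ValueError(f"segment length {L} != PSSM length {model.L}")
    values = model.score[np.arange(L), idx]
    names = [f"pos{j}" for j in range(L)]
    return FeatureMatrix(values, "pssm", names, {"L": L})


def pssm_to_image(segment, model: PssmModel, mode: str = "onehot") -> np.ndarray:
    """A 20 x 20 image for one segment: the central 20 positions (offsets
    -10..+9 around the centre) by the 20 amino acids (gap column dropped).

    ``mode="onehot"`` masks each position's score row to the observed
    residue; ``mode="profile"`` keeps the full score row regardless of the
    observed residue.
    """
    window = segment.window if isinstance(segment, Segment) else str(segment)
    L = len(window)
    if L < 21:
        raise ValueError(f"segment length {L} too short for a 20x20 image")
    if L != model.L:
        raise ValueError(f"segment length {L} != PSSM length {model.L}")
    idx = windows_to_indices([window])[0]
    center = (L - 1) // 2
    positions = np.arange(center - 10, center + 10)
    profile = model.score[positions, :20]  # (20, 20)
    if mode == "profile":
        return profile.copy()
    if mode != "onehot":
        raise ValueError(f"unknown image mode {mode!r}")
    image = np.zeros((20, 20), dtype=np.float64)
    for row, p in enumerate(positions):
        s = idx[p]
        if s != GAP_INDEX:
            image[row, s] = profile[row, s]
    return image


def encode_pssm_images(segments, model: PssmModel, mode: str = "onehot") -> np.ndarray:
    """Stack :func:`pssm_to_image` over a collection: (n, 20, 20)."""
    return np.stack([pssm_to_image(s, model, mode) for s in segments])


def extract_embedding_features(model, segments) -> FeatureMatrix:
    """Flattened word-embedding layer output of a trained embedding network,
    one row per segment (L x embedding_dim features)."""
    from .models import extract_layer_outputs  # local import avoids a cycle

    values = extract_layer_outputs(model, segments, "embedding")
    names = [f"we{j}" for j in range(values.shape[1])]
    return FeatureMatrix(values, "we", names, {"n_features": values.shape[1]})
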