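"""Two-sample-logo style position-specific enrichment/depletion analysis.

For every (flank position, amino acid) cell the occurrence frequency in
positive windows is compared with that in negative windows by a pooled
two-sample t-test on 0/1 indicators; Bonferroni correction is applied over
the tested family and cells below alpha are called enriched (positive
frequency difference) or depleted (negative difference).

The centre position — always cysteine in both classes — has zero variance
and is excluded, as is the gap symbol: only the 20 amino acids at the
L - 1 flank positions are tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, windows_to_indices
from .encoders import _indicator_ttest, _windows


@dataclass
class LogoResult:
    table: pd.DataFrame  # offset, residue, freq_pos, freq_neg, diff, t, p, p_corrected, call
    L: int
    alpha: float
    n_tests: int

    @property
    def enriched(self) -> set[tuple[int, str]]:
        sub = self.table[self.table["call"] == "enriched"]
        return set(zip(sub["offset"].astype(int), sub["residue"]))

    @property
    def depleted(self) -> set[tuple[int, str]]:
        sub = self.table[self.table["call"] == "depleted"]
        return set(zip(sub["offset"].astype(int), sub["residue"]))

    @property
    def significant(self) -> set[tuple[int, str]]:
        return self.enriched | self.depleted

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def two_sample_logo(pos_segments, neg_segments, alpha: float = 0.05) -> LogoResult:
    """Per-cell enrichment/depletion calls between positive and negative
    windows (Bonferroni-corrected two-sample t-tests at level ``alpha``)."""
    pos_idx = windows_to_indices(_windows(pos_segments))
    neg_idx = windows_to_indices(_windows(neg_segments))
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise ValueError("each class needs at least 2 segments")
    if pos_idx.shape[1] != neg_idx.shape[1]:
        raise ValueError("positive and negative windows have different lengths")
    n_pos, L = pos_idx.shape
    n_neg = neg_idx.shape[0]
    center = (L - 1) // 2

    pos_freq = np.stack([(pos_idx == s).mean(axis=0) for s in range(20)], axis=1)
    neg_freq = np.stack([(neg_idx == s).mean(axis=0) for s in range(20)], axis=1)
    t, p = _indicator_ttest(pos_freq, n_pos, neg_freq, n_neg)

    flank = [j for j in range(L) if j != center]
    n_tests = len(flank) * 20
    rows = []
    for j in flank:
        offset = j - center
        for a, residue in enumerate(AMINO_ACIDS):
            p_corr = min(1.0, p[j, a] * n_tests)
            diff = pos_freq[j, a] - neg_freq[j, a]
            if p_corr < alpha and diff > 0:
                call = "enriched"
            elif p_corr < alpha and diff < 0:
                call = "depleted"
            else:
                call = "ns"
            rows.append({
                "offset": offset,
                "residue": residue,
                "freq_pos": pos_freq[j, a],
                "freq_neg": neg_freq[j, a],
                "diff": diff,
                "t": t[j, a],
                "p": p[j, a],
                "p_corrected": p_corr,
                "call": call,
            })
    return LogoResult(pd.DataFrame(rows), L, alpha, n_tests)
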