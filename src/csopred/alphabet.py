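"""The 21-symbol residue alphabet shared by every encoder.

Ordered so that each letter maps to the integer given by its index:
``A -> 0``, ``V -> 1``, ..., ``E -> 19``, ``- -> 20``.  The trailing gap
symbol pads windows that run past a protein terminus.
"""

from __future__ import annotations

import numpy as np

ALPHABET: str = "AVLIFWMPGSTCYNQHKRDE-"
AMINO_ACIDS: str = ALPHABET[:20]
GAP: str = "-"
GAP_INDEX: int = 20

SYMBOL_TO_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALPHABET)}

# byte-level lookup table for vectorised window -> index conversion
_LUT = np.full(256, -1, dtype=np.int16)
for _s, _i in SYMBOL_TO_INDEX.items():
    _LUT[ord(_s)] = _i


def windows_to_indices(windows: list[str] | np.ndarray) -> np.ndarray:
    """Convert equal-length residue windows to an (n, L) integer index matrix.

    Raises ``ValueError`` on any symbol outside the 21-letter alphabet.
    """
    if len(windows) == 0:
        return np.empty((0, 0), dtype=np.int64)
    arr = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8)
    idx = _LUT[arr].reshape(len(windows), -1)
    if (idx < 0).any():
        bad = sorted({chr(b) for b in arr[_LUT[arr] < 0]})
        raise ValueError(f"symbols outside alphabet {ALPHABET!r}: {bad}")
    return idx.astype(np.int64)
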