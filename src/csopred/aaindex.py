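"""Reader for AAindex1 flat files and a small bundled scale collection.

The AAindex1 record layout places, after the ``H`` (accession) and ``D``
(description) lines, an ``I`` line announcing two rows of ten values each in
the residue order ``A R N D C Q E G H I / L K M F P S T W Y V``.  Records end
with ``//``.  Missing values are written ``NA``.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

# residue order of the two value rows in an AAindex1 "I" block
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

BUNDLED_TABLE = "aaindex_mini.txt"


def read_aaindex(path_or_text) -> pd.DataFrame:
    """Parse an AAindex1 flat file into a (property x 20 residue) DataFrame.

    Index: accession; columns: one-letter residues in AAindex order; missing
    values become NaN.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    rows: dict[str, list[float]] = {}
    accession = None
    collecting = 0
    values: list[float] = []
    for line in text.splitlines():
        if line.startswith("H "):
            accession = line[2:].strip()
        elif line.startswith("I "):
            collecting = 2
            values = []
        elif collecting:
            parts = line.split()
            values.extend(np.nan if v.upper() == "NA" else float(v) for v in parts)
            collecting -= 1
            if collecting == 0:
                if accession is None:
                    raise ValueError("AAindex record with values but no H line")
                if len(values) != 20:
                    raise ValueError(
                        f"AAindex record {accession}: expected 20 values, got {len(values)}"
                    )
                rows[accession] = values
                accession = None
    if not rows:
        raise ValueError("no AAindex records found")
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(AAINDEX_ORDER)
    )


def load_bundled_aaindex() -> pd.DataFrame:
    """The packaged subset of physicochemical scales (see data/aaindex_mini.txt)."""
    ref = resources.files("csopred.data").joinpath(BUNDLED_TABLE)
    return read_aaindex(ref.open())
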