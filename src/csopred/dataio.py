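"""Reading sequences and site annotations, window extraction, dataset splitting.

Coordinates are 1-based and inclusive throughout, matching biological
convention.  A *segment* is a fixed odd-length window centred on a candidate
cysteine; positions that fall outside the protein are padded with ``'-'``.
Residues outside the 20-letter amino-acid alphabet (X, B, Z, U, ...) are
accepted on read and mapped to ``'-'`` when segments are built, with a logged
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import ALPHABET

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str


@dataclass(frozen=True)
class SiteAnnotation:
    protein_id: str
    position: int  # 1-based
    label: str = POSITIVE


@dataclass(frozen=True)
class Segment:
    protein_id: str
    center_position: int  # 1-based position of the central C in the protein
    window: str
    label: str

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE


@dataclass
class DatasetSplit:
    cv_groups: list[list[Segment]]
    independent_test: list[Segment]
    seed: int = 0

    @property
    def all_groups(self) -> list[list[Segment]]:
        return [*self.cv_groups, self.independent_test]


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Sequences are upper-cased.  Raises ``ValueError`` for an entry with an
    empty sequence or a duplicated identifier.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not entry.id:
            raise ValueError("FASTA entry with empty header")
        if not seq:
            raise ValueError(f"FASTA entry {entry.id!r} has an empty sequence")
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA identifier {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, seq))
    return records


def _read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError("annotation table needs >= 2 columns (protein_id, position)")
    # optional header row: detected when the position column is non-numeric
    first_pos = str(df.iloc[0, 1])
    if not first_pos.lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            return df
    return df


def read_site_annotations(path, proteins: list[ProteinRecord]) -> list[SiteAnnotation]:
    """Read a delimited site table (protein_id, position[, label]) and validate.

    The dialect (tab or comma) is auto-detected and a header row is optional.
    Rows with no label column are positives.  Raises ``ValueError`` listing the
    offending row numbers when a position is out of range or is not a cysteine,
    or when a protein id is unknown.
    """
    by_id = {p.id: p for p in proteins}
    df = _read_annotation_table(path)
    annotations: list[SiteAnnotation] = []
    errors: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        pid = str(row[0]).strip()
        try:
            pos = int(row[1])
        except (TypeError, ValueError):
            errors.append(f"row {row_no}: non-integer position {row[1]!r}")
            continue
        label = POSITIVE
        if len(row) > 2 and isinstance(row[2], str) and row[2].strip():
            raw = row[2].strip().lower()
            if raw in {"positive", "pos", "1", "true", "y"}:
                label = POSITIVE
            elif raw in {"negative", "neg", "0", "false", "n"}:
                label = NEGATIVE
            else:
                errors.append(f"row {row_no}: unrecognised label {row[2]!r}")
                continue
        protein = by_id.get(pid)
        if protein is None:
            errors.append(f"row {row_no}: unknown protein_id {pid!r}")
            continue
        if not (1 <= pos <= len(protein.sequence)):
            errors.append(f"row {row_no}: position {pos} outside protein {pid!r}")
            continue
        if protein.sequence[pos - 1] != "C":
            errors.append(
                f"row {row_no}: residue at {pid!r}:{pos} is "
                f"{protein.sequence[pos - 1]!r}, expected 'C'"
            )
            continue
        annotations.append(SiteAnnotation(pid, pos, label))
    if errors:
        raise ValueError("invalid site annotations:\n" + "\n".join(errors))
    return annotations


def enumerate_negatives(
    proteins: list[ProteinRecord], positives: list[SiteAnnotation]
) -> list[SiteAnnotation]:
    """All cysteines of positive-containing proteins that are not positives.

    Proteins with no annotated positive site contribute nothing: only proteins
    seen in a sulphenylation experiment define credible negatives.
    """
    pos_by_protein: dict[str, set[int]] = {}
    for a in positives:
        pos_by_protein.setdefault(a.protein_id, set()).add(a.position)
    negatives: list[SiteAnnotation] = []
    for p in proteins:
        taken = pos_by_protein.get(p.id)
        if not taken:
            continue
        for i, residue in enumerate(p.sequence, start=1):
            if residue == "C" and i not in taken:
                negatives.append(SiteAnnotation(p.id, i, NEGATIVE))
    return negatives


def extract_segments(
    proteins: list[ProteinRecord],
    annotations: list[SiteAnnotation],
    L: int = 33,
) -> list[Segment]:
    """Cut an odd-length window of ``L`` residues centred on each annotated C.

    Out-of-range flank positions become ``'-'``; non-standard residues are
    mapped to ``'-'`` as well (warned once per call).
    """
    if L % 2 == 0 or L < 3:
        raise ValueError(f"window length must be odd and >= 3, got {L}")
    by_id = {p.id: p for p in proteins}
    flank = (L - 1) // 2
    allowed = set(ALPHABET)
    segments: list[Segment] = []
    n_mapped = 0
    for a in annotations:
        seq = by_id[a.protein_id].sequence
        chars = []
        for p in range(a.position - flank, a.position + flank + 1):
            if 1 <= p <= len(seq):
                c = seq[p - 1]
                if c not in allowed or c == "-":
                    n_mapped += c != "-"
                    c = "-"
                chars.append(c)
            else:
                chars.append("-")
        window = "".join(chars)
        if window[flank] != "C":
            raise ValueError(
                f"annotation {a.protein_id}:{a.position} does not sit on a 'C'"
            )
        segments.append(Segment(a.protein_id, a.position, window, a.label))
    if n_mapped:
        logger.warning(
            "mapped %d non-standard residues to '-' during segment extraction",
            n_mapped,
        )
    return segments


def split_dataset(
    segments: list[Segment], n_groups: int = 11, seed: int = 0
) -> DatasetSplit:
    """Stratified random partition into ``n_groups``; the last group is the
    independent test set and the first ``n_groups - 1`` feed cross-validation.

    Positives and negatives are shuffled separately and dealt into groups whose
    per-class sizes differ by at most one, so the class ratio is preserved.
    Deterministic for a fixed seed.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    pos = [s for s in segments if s.is_positive]
    neg = [s for s in segments if not s.is_positive]
    if len(pos) < n_groups:
        raise ValueError(
            f"{len(pos)} positive segments cannot be split into {n_groups} groups"
        )
    groups: list[list[Segment]] = [[] for _ in range(n_groups)]
    for cls in (pos, neg):
        order = rng.permutation(len(cls))
        for chunk, grp in zip(np.array_split(order, n_groups), groups):
            grp.extend(cls[i] for i in chunk)
    return DatasetSplit(cv_groups=groups[:-1], independent_test=groups[-1], seed=seed)


def write_split_manifest(split: DatasetSplit, path) -> None:
    """Write a TSV mapping each segment to its group (10 CV groups then 'test')."""
    rows = []
    for g, group in enumerate(split.cv_groups):
        for s in group:
            rows.append((s.protein_id, s.center_position, s.label, str(g)))
    for s in split.independent_test:
        rows.append((s.protein_id, s.center_position, s.label, "test"))
    pd.DataFrame(rows, columns=["protein_id", "position", "label", "group"]).to_csv(
        path, sep="\t", index=False
    )


def segment_labels(segments: list[Segment]) -> np.ndarray:
    """0/1 label vector for a segment collection (1 = positive)."""
    return np.array([1 if s.is_positive else 0 for s in segments], dtype=np.int64)
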