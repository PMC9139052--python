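"""Sequence and PSSM input/output.

A position-specific scoring matrix (PSSM) is an L x 20 profile of per-position
amino-acid log-odds scores, typically produced by PSI-BLAST against a large
reference database.  It encodes how conserved each residue position is and
which substitutions it tolerates, and is the substrate for all featurization
in this package.

This module reads FASTA sequences (via Biopython), parses the standard
PSI-BLAST ASCII PSSM layout, and provides a substitution-matrix "pseudo-PSSM"
fallback so the full pipeline runs without a PSI-BLAST installation or a
reference database.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

#: Canonical amino-acid channel order used for every PSSM column axis.
#: This matches PSI-BLAST's own column header order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


class PSSMFormatError(ValueError):
    """Raised when a PSSM file does not follow the PSI-BLAST ASCII layout."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: a non-empty identifier and an upper-case sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence of {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSM:
    """L x 20 position-specific scoring matrix for one protein.

    Columns follow :data:`AA_ORDER`.  ``sequence`` is the residue string the
    rows correspond to, when known (always set by the parser and the
    pseudo-PSSM generator).
    """

    protein_id: str
    scores: np.ndarray
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM scores must be L x 20, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"PSSM for {self.protein_id!r} has non-finite entries")
        if self.sequence is not None and len(self.sequence) != self.scores.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != row count "
                f"{self.scores.shape[0]} for {self.protein_id!r}"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Sequences are upper-cased and input order is preserved.  An empty file or
    a duplicated identifier is an error.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def filter_min_length(
    records: Sequence[ProteinRecord], min_len: int = 50
) -> list[ProteinRecord]:
    """Drop fragments shorter than ``min_len`` residues, preserving order.

    Short fragments carry too little profile information to featurize; the
    default mirrors the 50-residue cut used when curating PPI benchmarks.
    """
    return [r for r in records if len(r) >= min_len]


def pseudo_pssm(record: ProteinRecord, matrix_name: str = "BLOSUM62") -> PSSM:
    """Build a substitution-matrix profile standing in for a PSI-BLAST PSSM.

    Row ``m`` is the ``matrix_name`` (BLOSUM62 or PAM250) row of residue ``m``
    over the 20 standard amino acids.  Non-standard residues (X, B, Z, U, ...)
    get an all-zero row: no information is invented for them.  Deterministic:
    depends only on (sequence, matrix_name).
    """
    if matrix_name not in ("BLOSUM62", "PAM250"):
        raise ValueError(f"unsupported substitution matrix {matrix_name!r}")
    subs = substitution_matrices.load(matrix_name)
    rows = np.zeros((len(record), 20))
    for m, res in enumerate(record.sequence):
        if res in _AA_INDEX:
            rows[m] = [subs[res, aa] for aa in AA_ORDER]
    return PSSM(protein_id=record.id, scores=rows, sequence=record.sequence)


def logistic_squash(pssm: PSSM) -> PSSM:
    """Optional element-wise squashing 1/(1+e^-x) of the scores; off by default
    everywhere in the pipeline."""
    return PSSM(
        protein_id=pssm.protein_id,
        scores=1.0 / (1.0 + np.exp(-pssm.scores)),
        sequence=pssm.sequence,
    )


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM format
# ---------------------------------------------------------------------------
#
# The standard layout:
#
#   <blank line>
#   Last position-specific scoring matrix computed, weighted ...
#               A   R   N   D ...  (40 letters: 20 log-odds + 20 percentage)
#       1 M    -2  -3  -4 ...
#       2 K    ...
#   <trailing statistics>
#
# We take the FIRST 20-column block (the log-odds scores); the second block
# holds weighted observed percentages.  Column order is read from the header
# line and reordered to AA_ORDER so downstream math never depends on the
# file's layout.


def parse_psiblast_pssm(path) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM file into a :class:`PSSM`.

    Returns the log-odds block as an L x 20 matrix with columns in
    :data:`AA_ORDER`; the concatenated residue letters of the rows give the
    query sequence.  Malformed score rows raise :class:`PSSMFormatError`
    citing the offending line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_cols: Optional[list[str]] = None
    rows: list[list[float]] = []
    residues: list[str] = []

    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if header_cols is None:
            # Column header: at least 20 single-letter amino-acid tokens.
            if len(tokens) >= 20 and all(
                t in _AA_INDEX and len(t) == 1 for t in tokens[:20]
            ):
                header_cols = tokens[:20]
            continue
        if not tokens:
            if rows:
                break  # blank line after the matrix: trailing stats follow
            continue
        if not tokens[0].isdigit():
            if rows:
                break
            continue
        if len(tokens) < 2 or tokens[1] not in _AA_INDEX and tokens[1] != "X":
            raise PSSMFormatError(
                f"{path.name}:{lineno}: expected '<pos> <residue> <scores...>'"
            )
        score_tokens = tokens[2 : 2 + 20]
        try:
            scores = [float(t) for t in score_tokens]
        except ValueError as exc:
            raise PSSMFormatError(
                f"{path.name}:{lineno}: non-numeric score in matrix row"
            ) from exc
        if len(scores) != 20:
            raise PSSMFormatError(
                f"{path.name}:{lineno}: expected 20 scores in first block, "
                f"found {len(scores)}"
            )
        rows.append(scores)
        residues.append(tokens[1])

    if header_cols is None:
        raise PSSMFormatError(f"{path.name}: no amino-acid column header found")
    if not rows:
        raise PSSMFormatError(f"{path.name}: empty matrix")

    raw = np.asarray(rows, dtype=float)
    # Reorder the file's column layout to the canonical alphabet.
    order = [header_cols.index(aa) for aa in AA_ORDER]
    return PSSM(
        protein_id=path.stem,
        scores=raw[:, order],
        sequence="".join(residues),
    )


def write_psiblast_pssm(pssm: PSSM, path, column_order: str = AA_ORDER) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout (integer scores).

    Used to emit synthetic fixtures; scores are rounded to the nearest
    integer because the format is integer-valued.  ``column_order`` permutes
    the emitted columns (the parser reads the header and reorders back).
    """
    seq = pssm.sequence or "X" * pssm.length
    order = [_AA_INDEX[aa] for aa in column_order]
    buf = io.StringIO()
    buf.write("\n")
    buf.write(
        "Last position-specific scoring matrix computed, weighted, "
        "observed percentages weighted\n"
    )
    buf.write("            " + "  ".join(column_order) + "\n")
    for i in range(pssm.length):
        scores = np.rint(pssm.scores[i, order]).astype(int)
        buf.write(
            f"{i + 1:5d} {seq[i]} " + " ".join(f"{s:3d}" for s in scores) + "\n"
        )
    buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Pair lists
# ---------------------------------------------------------------------------


def read_pairs(path) -> pd.DataFrame:
    """Read a pair-list TSV with columns (id_a, id_b[, label]).

    A header row is optional and detected by a non-numeric third field.
    Labels, when present, must be 0 or 1 (1 = interacting).
    """
    path = Path(path)
    first = None
    with path.open() as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line.rstrip("\n").split("\t")
                break
    if first is None:
        raise ValueError(f"empty pair list {path}")
    has_header = len(first) >= 3 and first[2] not in ("0", "1")
    if len(first) == 2 and not _looks_like_id_pair_header(first):
        has_header = False
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=0 if has_header else None,
        dtype=str,
    )
    df = df.iloc[:, :3] if df.shape[1] >= 3 else df.iloc[:, :2]
    df.columns = ["id_a", "id_b", "label"][: df.shape[1]]
    if "label" in df.columns:
        labels = df["label"].astype(int)
        if not set(labels.unique()) <= {0, 1}:
            raise ValueError(f"labels in {path} must be 0 or 1")
        df["label"] = labels
    if df.empty:
        raise ValueError(f"empty pair list {path}")
    return df.reset_index(drop=True)


def _looks_like_id_pair_header(fields: list[str]) -> bool:
    return [f.lower() for f in fields[:2]] == ["id_a", "id_b"]


def write_pairs(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
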