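"""Multiple sequence alignment containers, I/O and filtering.

Alignments are held as integer-coded matrices over a 21-letter alphabet
(20 amino acids plus the gap state). The query row anchors column
numbering: after query-mapping, every retained column corresponds to a
position of the query sequence and ``colmap`` records that (1-based)
position.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: Canonical residue order; gap is the final (21st) state.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = 20
_CODE = {c: i for i, c in enumerate(ALPHABET)}
# Nonstandard letters collapse to gap: they are too rare to support
# couplings and are not part of the 20-state model.
for _c in "BZXUOJ.*":
    _CODE[_c] = GAP


class AlignmentError(ValueError):
    """Raised on malformed or inconsistent alignment input."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned sequence string to integer codes (gap=20)."""
    return np.array([_CODE.get(c, GAP) for c in seq.upper()], dtype=np.uint8)


def decode_row(row: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in row)


@dataclasses.dataclass
class Alignment:
    """Rectangular alignment with a designated query row.

    Parameters
    ----------
    ids : list of str
        Sequence identifiers; by convention they carry a genome tag
        (anything before the first ``|`` or whitespace).
    seqs : ndarray of uint8, shape (n_rows, n_cols)
        Integer-coded residues, gap = 20.
    query_index : int
        Row index of the reference (query) sequence.
    colmap : ndarray of int
        1-based query positions for each retained column. Defaults to
        ``1..n_cols``.
    """

    ids: list[str]
    seqs: np.ndarray
    query_index: int = 0
    colmap: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype=np.uint8)
        if self.seqs.ndim != 2:
            raise AlignmentError("sequence matrix must be 2-D")
        if len(self.ids) != self.seqs.shape[0]:
            raise AlignmentError(
                f"{len(self.ids)} ids for {self.seqs.shape[0]} rows"
            )
        if not 0 <= self.query_index < self.seqs.shape[0]:
            raise AlignmentError("query_index out of range")
        if self.seqs.size and self.seqs.max() > GAP:
            raise AlignmentError("residue code outside the 21-state alphabet")
        if self.colmap is None:
            self.colmap = np.arange(1, self.seqs.shape[1] + 1)
        else:
            self.colmap = np.asarray(self.colmap, dtype=int)
            if self.colmap.shape[0] != self.seqs.shape[1]:
                raise AlignmentError("colmap length does not match columns")

    @property
    def n_rows(self) -> int:
        return self.seqs.shape[0]

    @property
    def n_cols(self) -> int:
        return self.seqs.shape[1]

    @property
    def query_seq(self) -> str:
        return decode_row(self.seqs[self.query_index])

    def row(self, i: int) -> str:
        return decode_row(self.seqs[i])

    @classmethod
    def from_strings(
        cls,
        ids: Sequence[str],
        seqs: Sequence[str],
        query_index: int = 0,
        colmap: Iterable[int] | None = None,
    ) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            ref = len(seqs[0])
            for sid, s in zip(ids, seqs):
                if len(s) != ref:
                    raise AlignmentError(
                        f"sequence {sid!r} has length {len(s)}, expected {ref}"
                    )
        mat = (
            np.vstack([encode_sequence(s) for s in seqs])
            if seqs
            else np.zeros((0, 0), dtype=np.uint8)
        )
        cm = None if colmap is None else np.asarray(list(colmap))
        return cls(list(ids), mat, query_index=query_index, colmap=cm)

    def take_rows(self, rows: Sequence[int], query_index: int | None = None) -> "Alignment":
        rows = list(rows)
        qi = query_index
        if qi is None:
            qi = rows.index(self.query_index) if self.query_index in rows else 0
        return Alignment(
            [self.ids[r] for r in rows],
            self.seqs[rows],
            query_index=qi,
            colmap=self.colmap.copy(),
        )

    def take_cols(self, cols: np.ndarray) -> "Alignment":
        return Alignment(
            list(self.ids),
            self.seqs[:, cols],
            query_index=self.query_index,
            colmap=self.colmap[cols],
        )


@dataclasses.dataclass
class SequenceWeights:
    """Per-row weights from identity-based down-weighting."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise AlignmentError("weights must lie in (0, 1]")

    @property
    def n_eff(self) -> float:
        """Effective sequence count (sum of weights)."""
        return float(self.weights.sum())


# ---------------------------------------------------------------------------
# reading


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return "a3m" if suffix == ".a3m" else "fasta"


def read_alignment(
    path: str | Path, format: str | None = None, query_index: int = 0
) -> Alignment:
    """Read a FASTA or A3M alignment.

    A3M lowercase insertion states are removed before validation, so the
    result is rectangular in match columns. Raises ``AlignmentError``
    naming the offending record if rows are ragged.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in ("fasta", "a3m"):
        raise ValueError(f"unknown alignment format {fmt!r}")
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if fmt == "a3m":
            s = "".join(c for c in s if not c.islower())
        ids.append(rec.id)
        seqs.append(s)
    if not ids:
        raise AlignmentError(f"no sequences parsed from {path}")
    return Alignment.from_strings(ids, seqs, query_index=query_index)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{decode_row(row)}\n")


def map_to_query(aln: Alignment) -> Alignment:
    """Drop columns where the query row is gapped.

    Residues not present in the query are removed; ``colmap`` afterwards
    gives the 1-based query position of every retained column.
    """
    keep = np.flatnonzero(aln.seqs[aln.query_index] != GAP)
    out = aln.take_cols(keep)
    out.colmap = np.arange(1, keep.size + 1)
    return out


# ---------------------------------------------------------------------------
# identity and filters


def pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fractional identity over columns where neither sequence is gapped."""
    both = (a != GAP) & (b != GAP)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    return float(((a == b) & both).sum()) / denom


def _identity_to_block(row: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Identity of one row against each row of a block (vectorized)."""
    both = (row[None, :] != GAP) & (block != GAP)
    denom = both.sum(axis=1)
    matches = ((block == row[None, :]) & both).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(denom > 0, matches / np.maximum(denom, 1), 0.0)
    return ident


def filter_redundancy(
    aln: Alignment, max_identity: float = 0.90, pin_query: bool = True
) -> Alignment:
    """Greedy redundancy filter.

    Scans rows in input order (query first when ``pin_query``) and keeps a
    row iff its identity to every previously kept row is <= ``max_identity``.
    Deterministic; the kept set has no pair above the threshold.
    """
    if aln.n_rows == 0:
        raise AlignmentError("empty alignment")
    order = list(range(aln.n_rows))
    if pin_query:
        order.remove(aln.query_index)
        order.insert(0, aln.query_index)
    kept: list[int] = []
    kept_block = np.empty((0, aln.n_cols), dtype=np.uint8)
    for r in order:
        if kept and np.any(_identity_to_block(aln.seqs[r], kept_block) > max_identity):
            continue
        kept.append(r)
        kept_block = np.vstack([kept_block, aln.seqs[r][None, :]])
    kept_sorted = sorted(kept)
    return aln.take_rows(kept_sorted)


def remove_gappy_columns(aln: Alignment, max_gap_frac: float = 0.75) -> Alignment:
    """Drop columns with gap fraction strictly greater than ``max_gap_frac``."""
    if aln.n_rows == 0:
        raise AlignmentError("empty alignment")
    gap_frac = (aln.seqs == GAP).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_frac)
    if keep.size == 0:
        raise AlignmentError("all columns exceed the gap threshold")
    return aln.take_cols(keep)


def sequence_weights(
    aln: Alignment, identity_threshold: float = 0.80
) -> SequenceWeights:
    """Down-weight redundant rows: weight = 1 / #{rows with identity >= t}.

    The count includes the row itself, so weights lie in (0, 1] and the
    effective count N_eff = sum of weights never exceeds the row count.
    """
    n = aln.n_rows
    counts = np.zeros(n, dtype=int)
    for r in range(n):
        ident = _identity_to_block(aln.seqs[r], aln.seqs)
        counts[r] = int((ident >= identity_threshold).sum())
    return SequenceWeights(1.0 / counts)


def summary_table(aln: Alignment) -> "pd.DataFrame":  # noqa: F821
    """Per-column summary (gap fraction, majority residue) as a DataFrame."""
    import pandas as pd

    gap_frac = (aln.seqs == GAP).mean(axis=0)
    maj = [ALPHABET[np.bincount(col, minlength=21).argmax()] for col in aln.seqs.T]
    return pd.DataFrame(
        {
            "column": np.arange(aln.n_cols),
            "query_pos": aln.colmap,
            "gap_frac": gap_frac,
            "majority": maj,
        }
    )
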