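"""Pair two protein families genome-by-genome using the gene-distance rule.

In prokaryotes, interacting proteins are frequently encoded in operons, so
the number of annotated genes between two genes (Δgene, proxied by the
difference of serially assigned accession indices) is small and conserved
across genomes for true ortholog pairs, while paralogs land at essentially
random distances. Pairing keeps, per genome, the candidate pair whose
Δgene belongs to the conserved set and concatenates the two sequences into
one paired-alignment row.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter, defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from .alignments import GAP, Alignment, AlignmentError, decode_row, filter_redundancy


class PairingError(ValueError):
    """Raised when no acceptable gene pairs can be formed."""


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """One gene of one family in one genome.

    ``accession_index`` is the serial position proxy (e.g. the numeric part
    of a serially assigned accession); ``sequence_row`` indexes the row of
    this family's alignment holding the gene's sequence.
    """

    genome_id: str
    accession_index: int
    family_id: str
    sequence_row: int

    def __post_init__(self) -> None:
        if self.accession_index < 0:
            raise ValueError("accession_index must be >= 0")


def read_gene_records(path: str | Path, family_id: str | None = None) -> list[GeneRecord]:
    """Read gene records from TSV (genome_id, accession_index, family_id, sequence_row)."""
    df = pd.read_csv(path, sep="\t")
    records = [
        GeneRecord(str(r.genome_id), int(r.accession_index), str(r.family_id), int(r.sequence_row))
        for r in df.itertuples()
    ]
    if family_id is not None:
        records = [r for r in records if r.family_id == family_id]
    return records


def write_gene_records(records: list[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(r) for r in records]
    ).to_csv(path, sep="\t", index=False)


def delta_gene(a: GeneRecord, b: GeneRecord, same_gene: str = "error") -> int:
    """Number of annotated genes between two genes of the same genome.

    ``|i_a - i_b| - 1``, floored at zero (adjacent genes have Δgene = 0).
    Identical indices denote the same gene; by default that is an error
    (``same_gene="zero"`` returns 0 instead).
    """
    if a.genome_id != b.genome_id:
        raise ValueError(
            f"records from different genomes: {a.genome_id!r} vs {b.genome_id!r}"
        )
    if a.accession_index == b.accession_index:
        if same_gene == "zero":
            return 0
        raise ValueError("identical accession indices: same gene")
    return max(abs(a.accession_index - b.accession_index) - 1, 0)


@dataclasses.dataclass
class ConservedPairResult:
    """Outcome of the Δgene conservation test."""

    passed: bool
    mode: int
    accepted: frozenset[int]
    conservation: float
    histogram: dict[int, int]


def conserved_pair_test(
    deltas: list[int] | np.ndarray,
    min_conservation: float = 0.60,
    max_delta: int = 20,
) -> ConservedPairResult:
    """Decide whether a family pair shows a conserved intergenic distance.

    The accepted Δgene set is the mode plus the second or third most common
    value when it lies within 1 of the mode (annotation-ambiguity
    allowance). The test passes iff the fraction of genomes whose Δgene is
    in the accepted set reaches ``min_conservation`` and the mode is
    strictly below ``max_delta``. Mode ties break toward the smaller Δgene.
    """
    deltas = list(int(d) for d in deltas)
    if not deltas:
        raise ValueError("no Δgene values supplied")
    hist = Counter(deltas)
    # sort by (-count, value): deterministic, ties toward smaller Δgene
    ranked = sorted(hist.items(), key=lambda kv: (-kv[1], kv[0]))
    mode = ranked[0][0]
    accepted = {mode}
    for value, _count in ranked[1:3]:
        if abs(value - mode) <= 1:
            accepted.add(value)
    n_in = sum(hist[d] for d in accepted)
    conservation = n_in / len(deltas)
    passed = conservation >= min_conservation and mode < max_delta
    return ConservedPairResult(
        passed=passed,
        mode=mode,
        accepted=frozenset(accepted),
        conservation=conservation,
        histogram=dict(sorted(hist.items())),
    )


@dataclasses.dataclass
class PairedAlignment:
    """Concatenated two-family alignment.

    Columns ``0..boundary-1`` hold protein A, ``boundary..`` protein B.
    ``genome_ids`` and ``source_rows`` record, per row, the genome and the
    (A-row, B-row) indices in the source family alignments.
    """

    aln: Alignment
    boundary: int
    genome_ids: list[str]
    source_rows: list[tuple[int, int]]
    colmap_a: np.ndarray | None = None
    colmap_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.boundary < self.aln.n_cols:
            raise ValueError("boundary must split the columns into two nonempty halves")
        if len(self.genome_ids) != self.aln.n_rows:
            raise ValueError("one genome id per row required")

    @property
    def n_rows(self) -> int:
        return self.aln.n_rows

    @property
    def n_cols(self) -> int:
        return self.aln.n_cols

    @property
    def p(self) -> int:
        """Length of the protein-A segment."""
        return self.boundary

    @property
    def q(self) -> int:
        """Length of the protein-B segment."""
        return self.aln.n_cols - self.boundary

    def is_inter(self, i: int, j: int) -> bool:
        return (i < self.boundary) != (j < self.boundary)


@dataclasses.dataclass
class PairingParams:
    min_conservation: float = 0.60
    max_delta: int = 20
    max_identity: float = 0.90
    max_gap_frac: float = 0.75


def _best_pair(
    recs_a: list[GeneRecord], recs_b: list[GeneRecord]
) -> tuple[int, GeneRecord, GeneRecord] | None:
    """Minimum-Δgene candidate pair within one genome (deterministic tie-break)."""
    best = None
    for ra in recs_a:
        for rb in recs_b:
            if ra.accession_index == rb.accession_index:
                continue
            d = delta_gene(ra, rb)
            key = (d, ra.accession_index, rb.accession_index)
            if best is None or key < best[0]:
                best = (key, ra, rb)
    if best is None:
        return None
    return best[0][0], best[1], best[2]


def build_paired_alignment(
    aln_a: Alignment,
    aln_b: Alignment,
    records_a: list[GeneRecord],
    records_b: list[GeneRecord],
    params: PairingParams | None = None,
) -> PairedAlignment:
    """Concatenate genome-matched sequences of two families.

    For each genome containing both families the minimum-Δgene candidate
    pair is formed; the conservation test runs over those per-genome Δgene
    values; rows are emitted only for genomes whose Δgene falls in the
    accepted set. The result is then column-filtered (75% gap rule) and
    redundancy-filtered (90% identity).
    """
    params = params or PairingParams()
    by_genome_a: dict[str, list[GeneRecord]] = defaultdict(list)
    by_genome_b: dict[str, list[GeneRecord]] = defaultdict(list)
    for r in records_a:
        by_genome_a[r.genome_id].append(r)
    for r in records_b:
        by_genome_b[r.genome_id].append(r)
    shared = sorted(set(by_genome_a) & set(by_genome_b))
    if not shared:
        raise PairingError("families share no genomes")

    genome_best: dict[str, tuple[int, GeneRecord, GeneRecord]] = {}
    for g in shared:
        best = _best_pair(by_genome_a[g], by_genome_b[g])
        if best is not None:
            genome_best[g] = best
    if not genome_best:
        raise PairingError("no candidate gene pairs in any shared genome")

    deltas = [genome_best[g][0] for g in sorted(genome_best)]
    result = conserved_pair_test(
        deltas, min_conservation=params.min_conservation, max_delta=params.max_delta
    )
    if not result.passed:
        raise PairingError(
            "no conserved intergenic distance: mode "
            f"{result.mode}, conservation {result.conservation:.2f}, "
            f"Δgene histogram {result.histogram}"
        )

    ids, rows, genomes, sources = [], [], [], []
    for g in sorted(genome_best):
        d, ra, rb = genome_best[g]
        if d not in result.accepted:
            continue
        rows.append(
            np.concatenate([aln_a.seqs[ra.sequence_row], aln_b.seqs[rb.sequence_row]])
        )
        ids.append(f"{g}|{ra.sequence_row}|{rb.sequence_row}")
        genomes.append(g)
        sources.append((ra.sequence_row, rb.sequence_row))
    if not rows:
        raise PairingError("conservation test passed but no rows selected")

    p0 = aln_a.n_cols
    merged = Alignment(ids, np.vstack(rows), query_index=0)
    # column filter first (75% gap rule), then row redundancy (90% identity)
    gap_frac = (merged.seqs == GAP).mean(axis=0)
    keep_cols = np.flatnonzero(gap_frac <= params.max_gap_frac)
    if keep_cols.size == 0:
        raise PairingError("all columns exceed the gap threshold")
    boundary = int((keep_cols < p0).sum())
    if boundary == 0 or boundary == keep_cols.size:
        raise PairingError("column filtering removed one protein entirely")
    colmap_a = aln_a.colmap[keep_cols[keep_cols < p0]]
    colmap_b = aln_b.colmap[keep_cols[keep_cols >= p0] - p0]
    merged = merged.take_cols(keep_cols)

    filtered = filter_redundancy(merged, max_identity=params.max_identity, pin_query=False)
    kept_ids = set(filtered.ids)
    mask = [i for i, sid in enumerate(merged.ids) if sid in kept_ids]
    return PairedAlignment(
        aln=filtered,
        boundary=boundary,
        genome_ids=[genomes[i] for i in mask],
        source_rows=[sources[i] for i in mask],
        colmap_a=colmap_a,
        colmap_b=colmap_b,
    )


def write_paired_alignment(paln: PairedAlignment, fasta_path: str | Path) -> None:
    """Write paired rows as FASTA plus a JSON sidecar with the boundary."""
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        for g, (ra, rb), row in zip(
            paln.genome_ids, paln.source_rows, paln.aln.seqs
        ):
            fh.write(f">{g}|{ra}|{rb}\n{decode_row(row)}\n")
    sidecar = {
        "boundary": int(paln.boundary),
        "colmap_a": None if paln.colmap_a is None else [int(x) for x in paln.colmap_a],
        "colmap_b": None if paln.colmap_b is None else [int(x) for x in paln.colmap_b],
    }
    fasta_path.with_suffix(fasta_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_paired_alignment(fasta_path: str | Path) -> PairedAlignment:
    from .alignments import read_alignment

    fasta_path = Path(fasta_path)
    aln = read_alignment(fasta_path, format="fasta")
    meta = json.loads(fasta_path.with_suffix(fasta_path.suffix + ".json").read_text())
    genomes, sources = [], []
    for sid in aln.ids:
        parts = sid.split("|")
        if len(parts) != 3:
            raise AlignmentError(f"paired-row header {sid!r} is not genome|rowA|rowB")
        genomes.append(parts[0])
        sources.append((int(parts[1]), int(parts[2])))
    return PairedAlignment(
        aln=aln,
        boundary=int(meta["boundary"]),
        genome_ids=genomes,
        source_rows=sources,
        colmap_a=None if meta["colmap_a"] is None else np.asarray(meta["colmap_a"]),
        colmap_b=None if meta["colmap_b"] is None else np.asarray(meta["colmap_b"]),
    )
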