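"""Synthetic inputs with known ground truth.

Three generators cover the pipeline's input types: paired alignments
Gibbs-sampled from a Potts model with planted inter-protein couplings,
operon-structured genome annotations with ortholog pairs at a conserved
gene distance plus paralog decoys, and idealized two-chain structures
with prescribed residue contacts.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .alignments import GAP, Alignment
from .evaluation import EvaluationError, Residue, StructureModel
from .pairing import GeneRecord, PairedAlignment
from .potts import Q, PottsModel

_SUPPRESS = -1e4  # field value that removes a state from sampling


@dataclasses.dataclass
class PlantedComplexSpec:
    """Ground-truth specification for a sampled two-protein complex.

    ``planted_pairs`` are inter-protein position pairs (i, j) with
    0 <= i < p <= j < p+q carrying a state-matching coupling of magnitude
    ``coupling`` (scalar, or one value per pair). ``field_sparsity`` is
    the fraction of (position, state) slots given a random field.
    ``burn_in`` counts Gibbs sweeps per chain; sequences are sampled as
    independent parallel chains, so ``thin`` is kept for API compatibility
    but has no effect.
    """

    p: int
    q: int
    planted_pairs: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    coupling: float | list[float] = 1.0
    field_sparsity: float = 0.0
    field_scale: float = 1.0
    n_seqs: int = 500
    n_states: int = 20
    burn_in: int = 100
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs <= 0:
            raise ValueError("n_seqs must be positive")
        if not 1 <= self.n_states <= 20:
            raise ValueError("n_states must be in 1..20")
        L = self.p + self.q
        for (i, j) in self.planted_pairs:
            if not (0 <= i < self.p <= j < L):
                raise ValueError(f"planted pair {(i, j)} not inter-protein")

    @property
    def L(self) -> int:
        return self.p + self.q

    def couplings(self) -> list[float]:
        if isinstance(self.coupling, (int, float)):
            return [float(self.coupling)] * len(self.planted_pairs)
        if len(self.coupling) != len(self.planted_pairs):
            raise ValueError("one coupling magnitude per planted pair required")
        return [float(c) for c in self.coupling]


def build_planted_model(spec: PlantedComplexSpec) -> PottsModel:
    """Potts model with sparse random fields and state-matching couplings."""
    rng = np.random.default_rng(spec.seed)
    L = spec.L
    v = np.zeros((L, Q))
    if spec.field_sparsity > 0:
        mask = rng.random((L, spec.n_states)) < spec.field_sparsity
        v[:, : spec.n_states][mask] = rng.normal(0.0, spec.field_scale, mask.sum())
    v[:, spec.n_states : 20] = _SUPPRESS
    v[:, GAP] = _SUPPRESS
    w = np.zeros((L, L, Q, Q))
    for (i, j), mag in zip(spec.planted_pairs, spec.couplings()):
        block = np.zeros((Q, Q))
        block[np.arange(spec.n_states), np.arange(spec.n_states)] = mag
        w[i, j] = block
        w[j, i] = block.T
    return PottsModel(v=v, w=w)


def _gibbs_sample(model: PottsModel, n_seqs: int, burn_in: int, rng) -> np.ndarray:
    """Parallel-chain Gibbs sampling: one independent chain per sequence.

    Only positions coupled in the model enter each conditional, so sweeps
    are cheap for sparse planted couplings; chains are independent, making
    the returned sequences independent draws after burn-in.
    """
    L = model.L_total
    norms = np.sqrt(np.sum(model.w**2, axis=(2, 3)))
    neighbors = [np.flatnonzero(norms[i] > 0) for i in range(L)]

    # independent-site initialization from the fields alone
    X = np.empty((n_seqs, L), dtype=np.intp)
    for i in range(L):
        logits = model.v[i] - model.v[i].max()
        prob = np.exp(logits)
        prob /= prob.sum()
        X[:, i] = rng.choice(Q, size=n_seqs, p=prob)

    for _ in range(burn_in):
        for i in range(L):
            logits = np.broadcast_to(model.v[i], (n_seqs, Q)).copy()
            for j in neighbors[i]:
                logits += model.w[i, j][:, X[:, j]].T
            logits -= logits.max(axis=1, keepdims=True)
            prob = np.exp(logits)
            prob /= prob.sum(axis=1, keepdims=True)
            cum = np.cumsum(prob, axis=1)
            r = rng.random(n_seqs)
            X[:, i] = np.minimum((cum < r[:, None]).sum(axis=1), Q - 1)
    return X


def sample_potts(spec: PlantedComplexSpec) -> tuple[PairedAlignment, dict]:
    """Sample a paired alignment from a planted Potts model.

    Returns the alignment plus a truth record holding the planted pairs,
    their magnitudes, and the generating model. Deterministic for a fixed
    seed.
    """
    model = build_planted_model(spec)
    rng = np.random.default_rng(spec.seed + 1)
    X = _gibbs_sample(model, spec.n_seqs, spec.burn_in, rng)
    ids = [f"s{k:05d}" for k in range(spec.n_seqs)]
    aln = Alignment(ids, X.astype(np.uint8), query_index=0)
    paln = PairedAlignment(
        aln=aln,
        boundary=spec.p,
        genome_ids=ids,
        source_rows=[(k, k) for k in range(spec.n_seqs)],
        colmap_a=np.arange(1, spec.p + 1),
        colmap_b=np.arange(1, spec.q + 1),
    )
    truth = {
        "planted_pairs": list(spec.planted_pairs),
        "couplings": spec.couplings(),
        "model": model,
        "seed": spec.seed,
    }
    return paln, truth


# ---------------------------------------------------------------------------
# genome annotations


def make_genomes(
    n_genomes: int,
    planted_delta: int = 3,
    conservation_frac: float = 0.7,
    paralog_rate: float = 0.3,
    seed: int = 0,
    family_ids: tuple[str, str] = ("famA", "famB"),
) -> tuple[list[GeneRecord], list[GeneRecord], dict]:
    """Operon-structured gene records for two families with known truth.

    In a ``conservation_frac`` fraction of genomes the true ortholog pair
    sits at Delta-gene = ``planted_delta``; elsewhere the family-B gene
    lands at a random larger, genome-specific distance. Paralog decoys of
    family B are inserted at distant loci with probability
    ``paralog_rate`` per genome. Truth lists the (genome, rowA, rowB)
    triples of the conserved ortholog pairs.
    """
    if not 0 < conservation_frac <= 1:
        raise ValueError("conservation_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    fam_a, fam_b = family_ids
    n_cons = round(conservation_frac * n_genomes)
    conserved = set(rng.permutation(n_genomes)[:n_cons].tolist())

    records_a: list[GeneRecord] = []
    records_b: list[GeneRecord] = []
    truth_pairs: list[tuple[str, int, int]] = []
    next_b_row = n_genomes  # paralog sequence rows follow the ortholog rows
    for g in range(n_genomes):
        gid = f"g{g:04d}"
        a_idx = int(rng.integers(100, 100_000))
        records_a.append(GeneRecord(gid, a_idx, fam_a, g))
        if g in conserved:
            delta = planted_delta
        else:
            delta = planted_delta + 5 + int(rng.integers(0, 11))
        b_idx = a_idx + delta + 1
        records_b.append(GeneRecord(gid, b_idx, fam_b, g))
        if g in conserved:
            truth_pairs.append((gid, g, g))
        if rng.random() < paralog_rate:
            par_idx = a_idx + 41 + int(rng.integers(0, 20))
            records_b.append(GeneRecord(gid, par_idx, fam_b, next_b_row))
            next_b_row += 1
    truth = {
        "pairs": truth_pairs,
        "conserved_genomes": sorted(f"g{g:04d}" for g in conserved),
        "planted_delta": planted_delta,
        "n_b_rows": next_b_row,
    }
    return records_a, records_b, truth


def make_family_alignment(n_rows: int, length: int, seed: int = 0, tag: str = "fam") -> Alignment:
    """Random ungapped alignment (rows mutually ~5% identical)."""
    rng = np.random.default_rng(seed)
    seqs = rng.integers(0, 20, size=(n_rows, length)).astype(np.uint8)
    ids = [f"{tag}_r{i}" for i in range(n_rows)]
    return Alignment(ids, seqs, query_index=0)


def make_genome_test_set(
    n_genomes: int,
    len_a: int = 30,
    len_b: int = 30,
    planted_delta: int = 3,
    conservation_frac: float = 0.7,
    paralog_rate: float = 0.3,
    seed: int = 0,
):
    """Genome records plus matching family alignments, ready for pairing."""
    records_a, records_b, truth = make_genomes(
        n_genomes,
        planted_delta=planted_delta,
        conservation_frac=conservation_frac,
        paralog_rate=paralog_rate,
        seed=seed,
    )
    aln_a = make_family_alignment(n_genomes, len_a, seed=seed + 101, tag="famA")
    aln_b = make_family_alignment(truth["n_b_rows"], len_b, seed=seed + 202, tag="famB")
    return aln_a, aln_b, records_a, records_b, truth


# ---------------------------------------------------------------------------
# toy structures


def make_toy_structure(
    contacts: list[tuple[int, int]],
    separation: float = 20.0,
    n_a: int = 10,
    n_b: int = 10,
    contact_distance: float = 5.0,
    spacing: float = 4.0,
) -> StructureModel:
    """Two idealized chains with prescribed cross-chain contacts.

    Residues are alanine-like (N, CA, C, CB). Chain A lies along the x
    axis; chain B is offset by ``separation`` except that each residue
    named in ``contacts`` (1-based pairs (res_A, res_B)) is brought to
    exactly ``contact_distance`` between Cbeta atoms. All other
    cross-chain pairs stay beyond the contact distance; infeasible
    requests (conflicting contacts, separation too small) raise.
    """
    if separation < contact_distance + 4.0:
        raise EvaluationError("separation too small to keep non-contacts apart")
    contact_of_b: dict[int, int] = {}
    for (i, j) in contacts:
        if not (1 <= i <= n_a and 1 <= j <= n_b):
            raise EvaluationError(f"contact {(i, j)} outside the chains")
        if j in contact_of_b and contact_of_b[j] != i:
            raise EvaluationError(f"residue B{j} requested in conflicting contacts")
        contact_of_b[j] = i

    def residue(x: float, y: float, flip: float) -> Residue:
        # CB displaced toward the partner chain (flip = -1 points down)
        return Residue(
            "A",
            {
                "N": np.array([x - 1.2, y, 0.6]),
                "CA": np.array([x, y, 0.0]),
                "C": np.array([x + 1.2, y, 0.6]),
                "CB": np.array([x, y + 1.5 * flip, 0.0]),
            },
        )

    chain_a = {i: residue(spacing * i, 0.0, +1.0) for i in range(1, n_a + 1)}
    chain_b = {}
    for j in range(1, n_b + 1):
        if j in contact_of_b:
            i = contact_of_b[j]
            # CB sits contact_distance above the A-residue's CB
            y_ca = 1.5 + contact_distance + 1.5
            chain_b[j] = residue(spacing * i, y_ca, -1.0)
        else:
            chain_b[j] = residue(spacing * j, separation, -1.0)
    s = StructureModel({"A": chain_a, "B": chain_b})

    # verify the construction delivered the requested geometry
    from .evaluation import pair_distances

    table = pair_distances(s, "A", "B")
    for row in table.itertuples():
        want = (int(row.res_j) in contact_of_b) and (
            contact_of_b[int(row.res_j)] == int(row.res_i)
        )
        if want and abs(row.d_sc_min - contact_distance) > 0.1:
            raise EvaluationError("requested contact not realized")
        if not want and row.d_sc_min <= contact_distance + 0.4:
            raise EvaluationError("non-contact pair fell inside the contact distance")
    return s
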