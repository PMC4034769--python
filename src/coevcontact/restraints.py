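"""Sigmoidal distance restraints from scored residue pairs.

Each restraint contributes weight / (1 + exp(-slope * (d - cutoff))) +
intercept to a model's score, so a positive-weight restraint penalizes
separation beyond the cutoff. Centroid-mode restraints act between Cbeta
atoms (Calpha for glycine) with residue-pair-specific cutoffs; full-atom
restraints are ambiguous over all side-chain heavy-atom combinations and
score as the minimum over alternatives.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

#: Side-chain heavy atoms per residue: Cbeta plus everything beyond it
#: (Calpha stands in for glycine).
SIDE_CHAIN_HEAVY: dict[str, tuple[str, ...]] = {
    "A": ("CB",),
    "C": ("CB", "SG"),
    "D": ("CB", "CG", "OD1", "OD2"),
    "E": ("CB", "CG", "CD", "OE1", "OE2"),
    "F": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "G": ("CA",),
    "H": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "I": ("CB", "CG1", "CG2", "CD1"),
    "K": ("CB", "CG", "CD", "CE", "NZ"),
    "L": ("CB", "CG", "CD1", "CD2"),
    "M": ("CB", "CG", "SD", "CE"),
    "N": ("CB", "CG", "OD1", "ND2"),
    "P": ("CB", "CG", "CD"),
    "Q": ("CB", "CG", "CD", "OE1", "NE2"),
    "R": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "S": ("CB", "OG"),
    "T": ("CB", "OG1", "CG2"),
    "V": ("CB", "CG1", "CG2"),
    "W": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "Y": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
}


def centroid_atom(residue: str) -> str:
    """Cbeta, except Calpha for glycine."""
    return "CA" if residue.upper() in ("G", "GLY") else "CB"


@dataclasses.dataclass(frozen=True)
class AtomSelector:
    chain: str
    resnum: int
    atom: str

    def __str__(self) -> str:
        return f"{self.atom} {self.resnum}{self.chain}"


@dataclasses.dataclass
class SigmoidRestraint:
    """restraint(d) = weight / (1 + exp(-slope (d - cutoff))) + intercept."""

    atom_i: AtomSelector
    atom_j: AtomSelector
    weight: float
    slope: float
    cutoff: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")

    def evaluate(self, d: float) -> float:
        return eval_restraint(self, d)


def eval_restraint(r: SigmoidRestraint, d: float) -> float:
    """Evaluate a sigmoidal restraint at distance ``d`` (Angstrom)."""
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return r.weight / (1.0 + math.exp(-r.slope * (d - r.cutoff))) + r.intercept


@dataclasses.dataclass
class AmbiguousRestraint:
    """One residue pair, many atom-pair alternatives; min-scored.

    Satisfying any single alternative satisfies the restraint, so the
    effective score never exceeds any individual alternative's score.
    """

    alternatives: list[SigmoidRestraint]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError("ambiguous restraint needs at least one alternative")

    def evaluate(self, distances: Sequence[float]) -> float:
        if len(distances) != len(self.alternatives):
            raise ValueError("one distance per alternative required")
        return min(r.evaluate(d) for r, d in zip(self.alternatives, distances))


# ---------------------------------------------------------------------------
# construction from scores


DEFAULT_CENTROID_CUTOFF = 8.0
DEFAULT_CENTROID_SLOPE = 2.0


def load_centroid_table(path: str | Path) -> dict[tuple[str, str], tuple[float, float]]:
    """Residue-pair-specific (cutoff, slope) table from YAML.

    Keys are two-letter residue pairs (order-insensitive), values
    ``[cutoff, slope]``; missing pairs fall back to the defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    table = {}
    for key, val in raw.items():
        a, b = key[0].upper(), key[1].upper()
        table[(a, b)] = (float(val[0]), float(val[1]))
        table[(b, a)] = (float(val[0]), float(val[1]))
    return table


def _centroid_params(aa_i, aa_j, table):
    if table:
        hit = table.get((aa_i, aa_j))
        if hit is not None:
            return hit
    return DEFAULT_CENTROID_CUTOFF, DEFAULT_CENTROID_SLOPE


FULLATOM_CUTOFF = 5.5
FULLATOM_SLOPE = 4.0


def build_restraints(
    scores,
    mode: str,
    seq_a: str,
    seq_b: str,
    top_k: int | None = None,
    weight_scale: float = 1.0,
    centroid_table: dict | None = None,
    chain_a: str = "A",
    chain_b: str = "B",
) -> list[SigmoidRestraint] | list[AmbiguousRestraint]:
    """Restraints for the top-ranked inter-protein pairs.

    ``top_k`` defaults to round(3L/2) — roughly the number of true
    contacts expected for a complex of L positions. Weight is
    ``weight_scale * ncs`` so stronger couplings pull harder. Residue
    numbering follows the score table's query positions into ``seq_a`` and
    ``seq_b`` (1-based).
    """
    from .scoring import rank_pairs

    if mode not in ("centroid", "fullatom"):
        raise ValueError(f"unknown mode {mode!r}")
    if top_k is None:
        top_k = round(3 * scores.L / 2)
    chosen = rank_pairs(scores, which="inter", top_n=top_k)

    out: list = []
    for row in chosen.itertuples():
        qi, qj = int(row.i_query), int(row.j_query)
        if not 1 <= qi <= len(seq_a):
            raise IndexError(f"position {qi} outside protein A sequence")
        if not 1 <= qj <= len(seq_b):
            raise IndexError(f"position {qj} outside protein B sequence")
        aa_i, aa_j = seq_a[qi - 1].upper(), seq_b[qj - 1].upper()
        weight = weight_scale * float(row.ncs)
        if mode == "centroid":
            cutoff, slope = _centroid_params(aa_i, aa_j, centroid_table)
            out.append(
                SigmoidRestraint(
                    AtomSelector(chain_a, qi, centroid_atom(aa_i)),
                    AtomSelector(chain_b, qj, centroid_atom(aa_j)),
                    weight=weight,
                    slope=slope,
                    cutoff=cutoff,
                )
            )
        else:
            alts = [
                SigmoidRestraint(
                    AtomSelector(chain_a, qi, ai),
                    AtomSelector(chain_b, qj, aj),
                    weight=weight,
                    slope=FULLATOM_SLOPE,
                    cutoff=FULLATOM_CUTOFF,
                )
                for ai in SIDE_CHAIN_HEAVY.get(aa_i, ("CA",))
                for aj in SIDE_CHAIN_HEAVY.get(aa_j, ("CA",))
            ]
            out.append(AmbiguousRestraint(alts))
    return out


# ---------------------------------------------------------------------------
# writers


def write_restraints_tsv(restraints: Iterable, path: str | Path) -> None:
    """Native tab-separated restraint format (one alternative per line)."""
    with open(path, "w") as fh:
        fh.write(
            "group\tchain_i\tres_i\tatom_i\tchain_j\tres_j\tatom_j"
            "\tweight\tslope\tcutoff\tintercept\n"
        )
        for g, r in enumerate(restraints):
            alts = r.alternatives if isinstance(r, AmbiguousRestraint) else [r]
            for a in alts:
                fh.write(
                    f"{g}\t{a.atom_i.chain}\t{a.atom_i.resnum}\t{a.atom_i.atom}"
                    f"\t{a.atom_j.chain}\t{a.atom_j.resnum}\t{a.atom_j.atom}"
                    f"\t{a.weight:.6f}\t{a.slope:.3f}\t{a.cutoff:.3f}"
                    f"\t{a.intercept:.3f}\n"
                )


def _rosetta_atom_pair(r: SigmoidRestraint) -> str:
    func = (
        f"SCALARWEIGHTEDFUNC {r.weight:.6f} SUMFUNC 2 "
        f"SIGMOID {r.cutoff:.3f} {r.slope:.3f} CONSTANTFUNC {r.intercept:.3f}"
    )
    return (
        f"AtomPair {r.atom_i.atom} {r.atom_i.resnum}{r.atom_i.chain} "
        f"{r.atom_j.atom} {r.atom_j.resnum}{r.atom_j.chain} {func}"
    )


def write_rosetta_constraints(restraints: Iterable, path: str | Path) -> None:
    """Rosetta constraint-file lines (AtomPair / AmbiguousConstraint)."""
    lines = []
    for r in restraints:
        if isinstance(r, AmbiguousRestraint):
            lines.append("AmbiguousConstraint")
            lines.extend(_rosetta_atom_pair(a) for a in r.alternatives)
            lines.append("END_AMBIGUOUS")
        else:
            lines.append(_rosetta_atom_pair(r))
    Path(path).write_text("\n".join(lines) + "\n")
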