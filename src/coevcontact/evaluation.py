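"""Structure-based evaluation of contact predictions and complex models.

Conventions: "within X Angstrom" is read inclusively (<= X) everywhere; a
protein pair is in contact when any cross-chain Calpha pair is within
12 A; interface residue contacts use the minimal side-chain heavy-atom
distance below 5 A; iRMSD superposes interface Calpha atoms by
least-squares (Kabsch) rotation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .restraints import SIDE_CHAIN_HEAVY

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


class EvaluationError(ValueError):
    pass


@dataclasses.dataclass
class Residue:
    name: str  # one-letter code ("X" for nonstandard)
    atoms: dict[str, np.ndarray]

    def side_chain_atoms(self) -> dict[str, np.ndarray]:
        wanted = SIDE_CHAIN_HEAVY.get(self.name, ("CA",))
        return {a: xyz for a, xyz in self.atoms.items() if a in wanted}


@dataclasses.dataclass
class StructureModel:
    """Chains of residues with named heavy-atom coordinates (Angstrom).

    ``chains`` maps chain id -> ordered dict of residue number -> Residue.
    Residue numbers are expected to correspond to alignment query
    positions (renumber before evaluation if they do not).
    """

    chains: dict[str, dict[int, Residue]]

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            for num, res in residues.items():
                for name, xyz in res.atoms.items():
                    xyz = np.asarray(xyz, dtype=float)
                    if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                        raise EvaluationError(
                            f"bad coordinates for {cid}/{num}/{name}"
                        )
                    res.atoms[name] = xyz

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def ca_coords(self, chain: str) -> tuple[np.ndarray, np.ndarray]:
        """(residue numbers, Calpha coordinates) for one chain."""
        nums, xyz = [], []
        for num, res in self.chains[chain].items():
            if "CA" in res.atoms:
                nums.append(num)
                xyz.append(res.atoms["CA"])
        return np.asarray(nums), np.asarray(xyz, dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        out: dict[str, dict[int, Residue]] = {}
        for cid, residues in self.chains.items():
            out[cid] = {
                num: Residue(
                    res.name,
                    {a: rotation @ xyz + translation for a, xyz in res.atoms.items()},
                )
                for num, res in residues.items()
            }
        return StructureModel(out)


def read_pdb(path: str | Path) -> StructureModel:
    """Parse a PDB file: first model, altloc A (or blank), HETATM ignored."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains: dict[str, dict[int, Residue]] = {}
    for chain in model:
        residues: dict[int, Residue] = {}
        for res in chain:
            if res.het_flag != "A":  # ATOM records only
                continue
            one = THREE_TO_ONE.get(res.name.upper(), "X")
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                if atom.altloc not in ("", "A"):
                    continue
                if atom.element.is_hydrogen:
                    continue
                atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
            if atoms:
                residues[res.seqid.num] = Residue(one, atoms)
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise EvaluationError(f"no protein chains parsed from {path}")
    return StructureModel(chains)


def write_pdb(s: StructureModel, path: str | Path) -> None:
    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    serial = 0
    lines = []
    for cid, residues in s.chains.items():
        for num, res in residues.items():
            resname = one_to_three.get(res.name, "UNK")
            for name, xyz in res.atoms.items():
                serial += 1
                element = name[0]
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{resname:>3s} {cid:1s}{num:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# distances and contacts


def _min_side_chain_distance(r1: Residue, r2: Residue) -> float:
    a1 = list(r1.side_chain_atoms().values())
    a2 = list(r2.side_chain_atoms().values())
    if not a1 or not a2:
        return float("nan")
    d = np.linalg.norm(
        np.asarray(a1)[:, None, :] - np.asarray(a2)[None, :, :], axis=2
    )
    return float(d.min())


def _atom_distance(r1: Residue, r2: Residue, name1: str, name2: str) -> float:
    if name1 not in r1.atoms or name2 not in r2.atoms:
        return float("nan")
    return float(np.linalg.norm(r1.atoms[name1] - r2.atoms[name2]))


def pair_distances(s: StructureModel, chain_a: str, chain_b: str) -> pd.DataFrame:
    """Residue-pair distance table between two chains.

    Columns: res_i, res_j, d_sc_min (minimal side-chain heavy-atom
    distance; Cbeta counts as side chain, Calpha for glycine), d_cb
    (Cbeta-Cbeta, Calpha for glycine), d_ca. Missing atoms yield NaN,
    never zero.
    """
    for c in (chain_a, chain_b):
        if c not in s.chains or not s.chains[c]:
            raise EvaluationError(f"chain {c!r} absent or empty")
    rows = []
    for ni, ri in s.chains[chain_a].items():
        cb_i = "CA" if ri.name == "G" else "CB"
        for nj, rj in s.chains[chain_b].items():
            cb_j = "CA" if rj.name == "G" else "CB"
            rows.append(
                (
                    ni,
                    nj,
                    _min_side_chain_distance(ri, rj),
                    _atom_distance(ri, rj, cb_i, cb_j),
                    _atom_distance(ri, rj, "CA", "CA"),
                )
            )
    return pd.DataFrame(rows, columns=["res_i", "res_j", "d_sc_min", "d_cb", "d_ca"])


def protein_pair_in_contact(
    s: StructureModel, chain_a: str, chain_b: str, d_cut: float = 12.0
) -> bool:
    """True iff any cross-chain Calpha-Calpha distance is <= ``d_cut``."""
    _, xa = s.ca_coords(chain_a)
    _, xb = s.ca_coords(chain_b)
    if xa.size == 0 or xb.size == 0:
        raise EvaluationError("missing Calpha atoms")
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    return bool(d.min() <= d_cut)


def interface_contacts(
    contacts: pd.DataFrame, d_cut: float = 5.0
) -> set[tuple[int, int]]:
    """Residue pairs whose minimal side-chain heavy-atom distance is < d_cut."""
    hit = contacts[contacts.d_sc_min < d_cut]
    return {(int(r.res_i), int(r.res_j)) for r in hit.itertuples()}


def precision_curve(
    scores: pd.DataFrame,
    contacts: pd.DataFrame,
    bins: np.ndarray,
    contact_cut: float = 12.0,
    score_column: str = "gremlin_score",
) -> pd.DataFrame:
    """Fraction of predicted pairs in structural contact, per score bin.

    ``scores`` must carry i_query/j_query matching the contact table's
    res_i/res_j numbering. Empty bins report n=0 and a missing fraction.
    """
    dist = {
        (int(r.res_i), int(r.res_j)): r.d_sc_min for r in contacts.itertuples()
    }
    rows = []
    svals = scores[score_column].to_numpy()
    pairs = list(zip(scores.i_query.astype(int), scores.j_query.astype(int)))
    for lo, hi in zip(bins[:-1], bins[1:]):
        in_bin = [
            pr for pr, sv in zip(pairs, svals) if lo <= sv < hi and pr in dist
        ]
        n = len(in_bin)
        if n == 0:
            frac = float("nan")
        else:
            hits = sum(1 for pr in in_bin if dist[pr] < contact_cut)
            frac = hits / n
        rows.append((lo, hi, n, frac))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n", "fraction_contact"])


# ---------------------------------------------------------------------------
# model-vs-reference metrics


def fnat(
    model: StructureModel,
    reference: StructureModel,
    chain_a: str | None = None,
    chain_b: str | None = None,
    d_cut: float = 5.0,
) -> float:
    """Fraction of native interface contacts reproduced by the model."""
    if chain_a is None or chain_b is None:
        ids = reference.chain_ids()
        if len(ids) < 2:
            raise EvaluationError("reference has fewer than two chains")
        chain_a, chain_b = ids[0], ids[1]
    native = interface_contacts(pair_distances(reference, chain_a, chain_b), d_cut)
    if not native:
        raise EvaluationError("reference has no interface contacts")
    modeled = interface_contacts(pair_distances(model, chain_a, chain_b), d_cut)
    return len(native & modeled) / len(native)


def kabsch(P: np.ndarray, Q_: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation/translation mapping P onto Q_ (row vectors)."""
    Pc, Qc = P.mean(axis=0), Q_.mean(axis=0)
    A = (P - Pc).T @ (Q_ - Qc)
    U, _, Vt = np.linalg.svd(A)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    return R, t


def interface_rmsd(
    model: StructureModel,
    reference: StructureModel,
    chain_a: str | None = None,
    chain_b: str | None = None,
    interface_cut: float = 12.0,
) -> float:
    """Interface Calpha RMSD after optimal superposition.

    Interface residues are those of the reference with any cross-chain
    Calpha within ``interface_cut``; the model's corresponding Calpha set
    is superposed onto the reference's by least squares.
    """
    if chain_a is None or chain_b is None:
        ids = reference.chain_ids()
        if len(ids) < 2:
            raise EvaluationError("reference has fewer than two chains")
        chain_a, chain_b = ids[0], ids[1]
    na, xa = reference.ca_coords(chain_a)
    nb, xb = reference.ca_coords(chain_b)
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    sel_a = na[(d <= interface_cut).any(axis=1)]
    sel_b = nb[(d <= interface_cut).any(axis=0)]

    ref_pts, mod_pts = [], []
    for cid, sel in ((chain_a, sel_a), (chain_b, sel_b)):
        for num in sel:
            ref_res = reference.chains[cid].get(int(num))
            mod_res = model.chains.get(cid, {}).get(int(num))
            if ref_res is None or mod_res is None:
                continue
            if "CA" in ref_res.atoms and "CA" in mod_res.atoms:
                ref_pts.append(ref_res.atoms["CA"])
                mod_pts.append(mod_res.atoms["CA"])
    if len(ref_pts) < 3:
        raise EvaluationError("fewer than 3 interface residues in common")
    Pm = np.asarray(mod_pts)
    Pr = np.asarray(ref_pts)
    R, t = kabsch(Pm, Pr)
    aligned = Pm @ R.T + t
    return float(np.sqrt(np.mean(np.sum((aligned - Pr) ** 2, axis=1))))
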