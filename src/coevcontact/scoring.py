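"""Reduce coupling matrices to calibrated per-pair contact scores.

The pipeline is: raw coupling strength s_ij (RMS of the coupling matrix),
a block-restricted average product correction (APC) that removes
per-position background separately for each protein and for the
inter-protein block, normalization by the mean of the top 3L/2 corrected
values (ncs), and a sigmoid calibration mapping sqrt(ncs) and alignment
depth N/L to an empirical contact probability.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class ScoreCalibration:
    """Constants of the depth-aware sigmoid contact-probability model.

    Fitted once on the bacterial 50S ribosomal complex; shipped as given,
    not refit.
    """

    m: float = 0.47
    c: float = 0.96
    sigma: float = 9.77

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


DEFAULT_CALIBRATION = ScoreCalibration()


def coupling_strength(w_ij: np.ndarray, include_gap: bool = False) -> float:
    """Scalar coupling strength: RMS of the coupling-matrix entries.

    By default the 20x20 amino-acid sub-block is used; gap couplings
    largely reflect alignment artifacts. ``include_gap=True`` averages over
    the full 21x21 matrix.
    """
    w_ij = np.asarray(w_ij, dtype=float)
    block = w_ij if include_gap else w_ij[:20, :20]
    return float(np.sqrt(np.mean(block**2)))


def coupling_strength_matrix(w: np.ndarray, include_gap: bool = False) -> np.ndarray:
    """(L, L) symmetric table of per-pair coupling strengths, zero diagonal."""
    L = w.shape[0]
    block = w if include_gap else w[:, :, :20, :20]
    s = np.sqrt(np.mean(block**2, axis=(2, 3)))
    s[np.arange(L), np.arange(L)] = 0.0
    return s


def block_apc(s: np.ndarray, p: int) -> np.ndarray:
    """Average product correction with block-restricted index sets.

    The correction subtracted from s_ij is <s_ik> <s_kj> / <s_kl>, with
    the averaging sets chosen so each protein's evolutionary rate is
    averaged separately: both positions in protein A (B) -> averages over
    A (B) only; i in A and j in B -> the i-average runs over B, the
    j-average over A, and the grand mean over the inter block. For any
    rank-one inter block the corrected inter values vanish identically.
    """
    s = np.asarray(s, dtype=float)
    L = s.shape[0]
    if s.shape != (L, L):
        raise ValueError("strength table must be square")
    if not np.allclose(s, s.T):
        raise ValueError("strength table must be symmetric")
    if not 1 <= p < L:
        raise ValueError("boundary must split positions into two nonempty blocks")
    out = np.zeros_like(s)
    for lo, hi in ((0, p), (p, L)):
        n = hi - lo
        blk = s[lo:hi, lo:hi]
        if n < 2:
            raise ValueError("intra block too small for APC")
        row_mean = blk.sum(axis=1) / (n - 1)  # excludes the zero diagonal
        grand = blk.sum() / (n * (n - 1))
        if grand == 0:
            raise ValueError("degenerate intra block: zero mean strength")
        corr = blk - np.outer(row_mean, row_mean) / grand
        np.fill_diagonal(corr, 0.0)
        out[lo:hi, lo:hi] = corr
    inter = s[:p, p:]
    mean_over_b = inter.mean(axis=1)  # <s_ik>, k over protein B
    mean_over_a = inter.mean(axis=0)  # <s_kj>, k over protein A
    grand = inter.mean()
    if grand == 0:
        raise ValueError("degenerate inter block: zero mean strength")
    corr = inter - np.outer(mean_over_b, mean_over_a) / grand
    out[:p, p:] = corr
    out[p:, :p] = corr.T
    return out


def normalize_ncs(s_corr: np.ndarray, top_k: int | None = None) -> np.ndarray:
    """Divide corrected strengths by the mean of the top 3L/2 values.

    The normalizer pool is all unordered pairs, intra and inter; ncs > 1
    marks couplings stronger than a typical contact-level coupling.
    """
    s_corr = np.asarray(s_corr, dtype=float)
    L = s_corr.shape[0]
    if top_k is None:
        top_k = round(3 * L / 2)
    iu, ju = np.triu_indices(L, k=1)
    vals = s_corr[iu, ju]
    if top_k > vals.size:
        raise ValueError(f"top_k={top_k} exceeds the {vals.size} available pairs")
    top = np.sort(vals)[-top_k:]
    norm = top.mean()
    if norm <= 0:
        raise ValueError("nonpositive normalizer: corrected strengths degenerate")
    return s_corr / norm


def score_midpoint(N: float, L: float, cal: ScoreCalibration = DEFAULT_CALIBRATION,
                   mu_form: str = "reciprocal") -> float:
    """Sigmoid midpoint mu as a function of alignment depth N/L.

    ``reciprocal`` (default): mu = m / (N/L + 1) + c, decreasing toward c
    as alignments deepen — deeper alignments need weaker couplings for the
    same contact probability. ``linear`` gives mu = m * (N/L + 1) + c.
    """
    ratio = N / L
    if mu_form == "reciprocal":
        return cal.m / (ratio + 1.0) + cal.c
    if mu_form == "linear":
        return cal.m * (ratio + 1.0) + cal.c
    raise ValueError(f"unknown mu_form {mu_form!r}")


def gremlin_score(
    ncs: float,
    N: float,
    L: float,
    top_score: float | None = None,
    cal: ScoreCalibration = DEFAULT_CALIBRATION,
    mu_form: str = "reciprocal",
) -> float:
    """Calibrated contact probability for one pair.

    x = sqrt(ncs) for the complex's top-ranked pair; every other pair uses
    x = sqrt(ncs) scaled by the top pair's score (``top_score``). Negative
    corrected strengths are floored at zero before the square root.
    """
    if N <= 0 or L <= 0:
        raise ValueError("N and L must be positive")
    x = math.sqrt(max(float(ncs), 0.0))
    if top_score is not None:
        x *= top_score
    mu = score_midpoint(N, L, cal=cal, mu_form=mu_form)
    return 1.0 / (1.0 + math.exp(-cal.sigma * (x - mu)))


@dataclasses.dataclass
class CouplingScores:
    """Per-pair score table for one protein complex.

    ``table`` columns: i, j (0-based paired-alignment positions, i < j),
    i_query / j_query (1-based positions in each protein's query sequence,
    B positions counted within protein B), region (AA / BB / AB), s,
    s_corr, ncs, gremlin_score.
    """

    table: pd.DataFrame
    boundary: int
    N: int
    L: int

    def inter(self) -> pd.DataFrame:
        return self.table[self.table.region == "AB"]

    def matrix(self, column: str = "ncs") -> np.ndarray:
        M = np.zeros((self.L, self.L))
        M[self.table.i, self.table.j] = self.table[column]
        return M + M.T


def score_pairs(
    model,
    boundary: int,
    N: int,
    colmap_a: np.ndarray | None = None,
    colmap_b: np.ndarray | None = None,
    cal: ScoreCalibration = DEFAULT_CALIBRATION,
    mu_form: str = "reciprocal",
    include_gap: bool = False,
    top_pool: str = "inter",
) -> CouplingScores:
    """Full scoring pipeline from a fitted Potts model.

    ``N`` is the sequence count entering the depth ratio N/L (raw
    post-filter row count by convention; pass an effective count to use
    reweighted depth). The top-scoring pair that anchors the calibration
    chain is taken from the inter-protein pairs (``top_pool="all"`` widens
    the pool to every pair).
    """
    L = model.L_total
    p = boundary
    s = coupling_strength_matrix(model.w, include_gap=include_gap)
    s_corr = block_apc(s, p)
    ncs = normalize_ncs(s_corr)

    iu, ju = np.triu_indices(L, k=1)
    region = np.where(
        (iu < p) & (ju < p), "AA", np.where((iu >= p) & (ju >= p), "BB", "AB")
    )
    ncs_pairs = ncs[iu, ju]
    pool = ncs_pairs if top_pool == "all" else np.where(region == "AB", ncs_pairs, -np.inf)
    top_idx = int(np.argmax(pool))
    top = gremlin_score(ncs_pairs[top_idx], N, L, cal=cal, mu_form=mu_form)
    scores = np.array(
        [
            top
            if k == top_idx
            else gremlin_score(x, N, L, top_score=top, cal=cal, mu_form=mu_form)
            for k, x in enumerate(ncs_pairs)
        ]
    )

    def qpos(idx: np.ndarray) -> np.ndarray:
        out = np.empty(idx.size, dtype=int)
        for k, t in enumerate(idx):
            if t < p:
                out[k] = colmap_a[t] if colmap_a is not None else t + 1
            else:
                out[k] = colmap_b[t - p] if colmap_b is not None else t - p + 1
        return out

    table = pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "i_query": qpos(iu),
            "j_query": qpos(ju),
            "region": region,
            "s": s[iu, ju],
            "s_corr": s_corr[iu, ju],
            "ncs": ncs_pairs,
            "gremlin_score": scores,
        }
    )
    return CouplingScores(table=table, boundary=p, N=N, L=L)


def summed_pair_coupling(scores: CouplingScores, threshold: float = 1.5) -> float:
    """Interaction-evidence statistic: sum of inter-protein ncs >= threshold.

    Protein pairs that physically interact accumulate several strong
    inter-protein couplings; non-interacting pairs rarely exceed the
    threshold at all, so the sum separates the two populations.
    """
    vals = scores.inter().ncs.to_numpy()
    return float(vals[vals >= threshold].sum())


def rank_pairs(
    scores: CouplingScores, which: str = "inter", top_n: int | None = None
) -> pd.DataFrame:
    """Pairs ordered by descending calibrated score, ties broken by (i, j)."""
    t = scores.table
    if which == "inter":
        t = t[t.region == "AB"]
    elif which == "intra":
        t = t[t.region != "AB"]
    elif which != "all":
        raise ValueError(f"unknown selection {which!r}")
    t = t.sort_values(
        ["gremlin_score", "i", "j"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return t if top_n is None else t.head(top_n)


def write_scores(scores: CouplingScores, path: str | Path) -> None:
    t = scores.table.copy()
    t["inter"] = (t.region == "AB").astype(int)
    t.to_csv(path, sep="\t", index=False, float_format="%.6g")
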