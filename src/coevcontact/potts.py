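"""Global Potts (pairwise Markov random field) model of a paired alignment.

The model assigns every sequence X = (X_1, ..., X_{p+q}) the probability

    p(X) = (1/Z) exp( sum_i v_i(X_i) + sum_{i<j} w_ij(X_i, X_j) )

with per-position fields ``v_i`` (21-vectors) and symmetric per-pair
couplings ``w_ij`` (21x21 matrices). Parameters are estimated by
maximizing the L2-regularized pseudo-likelihood — the sum over positions
of the log conditional probability of each residue given the rest of the
sequence — which never touches the global normalizer Z and is convex.

Gaps are treated as a 21st state: they carry structural/phylogenetic
signal and make every conditional a proper 21-way softmax.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize

from .alignments import SequenceWeights
from .pairing import PairedAlignment

Q = 21  # alphabet size including gap


@dataclasses.dataclass
class RegularizationSpec:
    """L2 penalties: R(v, w) = lambda_v ||v||^2 + lambda_w ||w||^2.

    ``lambda_w`` defaults to ``0.01 * (L_total - 1)``, scaling with the
    number of neighbors each position couples to (the usual convention for
    pseudo-likelihood contact prediction); pass a number to override.
    """

    lambda_v: float = 0.01
    lambda_w: float | None = None

    def resolved_lambda_w(self, L: int) -> float:
        if self.lambda_w is not None:
            if self.lambda_w < 0:
                raise ValueError("lambda_w must be >= 0")
            return self.lambda_w
        return 0.01 * (L - 1)

    def __post_init__(self) -> None:
        if self.lambda_v < 0:
            raise ValueError("lambda_v must be >= 0")


@dataclasses.dataclass
class PottsModel:
    """Fitted (or constructed) fields and couplings.

    ``w`` is stored as the full (L, L, 21, 21) array with
    ``w[i, j] == w[j, i].T`` and zero diagonal blocks; each unordered pair
    is a single parameter set.
    """

    v: np.ndarray
    w: np.ndarray
    converged: bool = True
    n_iter: int = 0
    objective: float = float("nan")

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        L = self.v.shape[0]
        if self.v.shape != (L, Q) or self.w.shape != (L, L, Q, Q):
            raise ValueError("inconsistent parameter shapes")

    @property
    def L_total(self) -> int:
        return self.v.shape[0]

    @classmethod
    def zeros(cls, L: int) -> "PottsModel":
        return cls(np.zeros((L, Q)), np.zeros((L, L, Q, Q)))

    def validate(self) -> None:
        if not np.all(np.isfinite(self.v)) or not np.all(np.isfinite(self.w)):
            raise ValueError("non-finite parameters")
        if not np.allclose(self.w, self.w.transpose(1, 0, 3, 2)):
            raise ValueError("couplings are not symmetric")
        L = self.L_total
        if np.abs(self.w[np.arange(L), np.arange(L)]).max() > 0:
            raise ValueError("diagonal couplings must be zero")

    def save(self, path) -> None:
        np.savez(path, v=self.v, w=self.w, objective=self.objective,
                 converged=self.converged, n_iter=self.n_iter)

    @classmethod
    def load(cls, path) -> "PottsModel":
        d = np.load(path)
        return cls(d["v"], d["w"], converged=bool(d["converged"]),
                   n_iter=int(d["n_iter"]), objective=float(d["objective"]))


@dataclasses.dataclass
class PottsGradient:
    """Gradient with the same layout as the model (pairs counted once)."""

    v: np.ndarray
    w: np.ndarray


# ---------------------------------------------------------------------------
# parameter packing: v (L*Q) followed by upper-triangle couplings (i < j)


def _pair_index(L: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(L, k=1)
    return iu, ju


def _pack(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    L = v.shape[0]
    iu, ju = _pair_index(L)
    return np.concatenate([v.ravel(), w[iu, ju].ravel()])


def _unpack(theta: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    v = theta[: L * Q].reshape(L, Q)
    iu, ju = _pair_index(L)
    wu = theta[L * Q :].reshape(len(iu), Q, Q)
    w = np.zeros((L, L, Q, Q))
    w[iu, ju] = wu
    w[ju, iu] = wu.transpose(0, 2, 1)
    return v, w


def _one_hot(X: np.ndarray, dtype=np.float64) -> np.ndarray:
    N, L = X.shape
    O = np.zeros((N, L * Q), dtype=dtype)
    O[np.arange(N)[:, None], np.arange(L) * Q + X] = 1.0
    return O


def _resolve_inputs(paln, wts):
    if hasattr(paln, "aln"):  # PairedAlignment
        X = paln.aln.seqs.astype(np.intp)
    elif hasattr(paln, "seqs"):  # Alignment
        X = paln.seqs.astype(np.intp)
    else:
        X = np.asarray(paln, dtype=np.intp)
    N = X.shape[0]
    if wts is None:
        wvec = np.ones(N)
    elif isinstance(wts, SequenceWeights):
        wvec = wts.weights
    else:
        wvec = np.asarray(wts, dtype=float)
    if wvec.shape != (N,):
        raise ValueError("one weight per sequence required")
    return X, wvec


def _npll_core(
    v: np.ndarray,
    w: np.ndarray,
    X: np.ndarray,
    wvec: np.ndarray,
    lam_v: float,
    lam_w: float,
    want_grad: bool,
    dtype=np.float64,
):
    """Weighted negative pseudo-log-likelihood and (optionally) its gradient.

    The conditional logits for all positions at once are a single matmul of
    the one-hot data against the (L*Q, L*Q) coupling matrix; the gradient
    is the mirrored matmul of the (probability - observation) residuals.
    """
    N, L = X.shape
    W = np.ascontiguousarray(
        w.transpose(0, 2, 1, 3).reshape(L * Q, L * Q), dtype=dtype
    )
    O = _one_hot(X, dtype=dtype)
    H = O @ W  # (N, L*Q): sum_j w_ij(a, x_j) for every (i, a)
    H = H.reshape(N, L, Q) + v[None, :, :].astype(dtype)
    Hmax = H.max(axis=2, keepdims=True)
    E = np.exp(H - Hmax)
    Zloc = E.sum(axis=2)
    logZ = np.log(Zloc) + Hmax[:, :, 0]
    obs = np.take_along_axis(H, X[:, :, None], axis=2)[:, :, 0]
    data_nll = -float(np.einsum("n,ni->", wvec, (obs - logZ).astype(np.float64)))

    reg = lam_v * float(np.sum(v * v))
    iu, ju = _pair_index(L)
    reg += lam_w * float(np.sum(w[iu, ju] ** 2))
    f = data_nll + reg
    if not want_grad:
        return f, None

    P = E / Zloc[:, :, None]
    D = (P - np.eye(Q, dtype=dtype)[X]) * wvec[:, None, None].astype(dtype)
    gv = D.sum(axis=0).astype(np.float64) + 2.0 * lam_v * v
    Df = D.reshape(N, L * Q)
    G = (O.T @ Df).astype(np.float64)  # dNLL/dW[(j,b),(i,a)] contributions
    G4 = G.reshape(L, Q, L, Q).transpose(0, 2, 1, 3)  # (j, i, b, a) -> indexed [k,i,b,a]
    # unordered-pair derivative: contribution with (i, j) conditioning on i
    # plus the mirrored contribution conditioning on j
    gw_full = G4.transpose(1, 0, 3, 2) + G4
    gw_full[np.arange(L), np.arange(L)] = 0.0
    gw = np.zeros_like(gw_full)
    gw[iu, ju] = gw_full[iu, ju] + 2.0 * lam_w * w[iu, ju]
    gw[ju, iu] = gw[iu, ju].transpose(0, 2, 1)
    return f, (gv, gw)


def neg_pseudo_loglikelihood(
    model: PottsModel,
    paln: PairedAlignment | np.ndarray,
    wts: SequenceWeights | np.ndarray | None = None,
    reg: RegularizationSpec | None = None,
) -> float:
    """Regularized negative pseudo-log-likelihood of the data under ``model``."""
    X, wvec = _resolve_inputs(paln, wts)
    if model.L_total != X.shape[1]:
        raise ValueError(
            f"model has {model.L_total} positions, alignment has {X.shape[1]}"
        )
    reg = reg or RegularizationSpec()
    f, _ = _npll_core(
        model.v, model.w, X, wvec,
        reg.lambda_v, reg.resolved_lambda_w(X.shape[1]), want_grad=False,
    )
    return f


def npll_gradient(
    model: PottsModel,
    paln: PairedAlignment | np.ndarray,
    wts: SequenceWeights | np.ndarray | None = None,
    reg: RegularizationSpec | None = None,
) -> PottsGradient:
    """Exact analytic gradient of :func:`neg_pseudo_loglikelihood`.

    The returned ``w`` gradient treats each unordered pair once and is
    mirrored into both (i, j) and (j, i) slots for convenience.
    """
    X, wvec = _resolve_inputs(paln, wts)
    if model.L_total != X.shape[1]:
        raise ValueError("dimension mismatch")
    reg = reg or RegularizationSpec()
    _, g = _npll_core(
        model.v, model.w, X, wvec,
        reg.lambda_v, reg.resolved_lambda_w(X.shape[1]), want_grad=True,
    )
    return PottsGradient(v=g[0], w=g[1])


@dataclasses.dataclass
class FitOptions:
    max_iter: int = 500
    tol: float = 1e-5  # projected-gradient tolerance for L-BFGS
    seed: int | None = None  # reserved for optional stochastic variants
    dtype: type = np.float64  # float32 trades gradient precision for speed
    init: PottsModel | None = None


def fit_plm(
    paln: PairedAlignment | np.ndarray,
    wts: SequenceWeights | np.ndarray | None = None,
    reg: RegularizationSpec | None = None,
    opts: FitOptions | None = None,
) -> PottsModel:
    """Fit fields and couplings by regularized pseudo-likelihood maximization.

    The objective is smooth and convex, so the L-BFGS solution is unique
    for any positive regularization; initialization (zero by default) only
    affects the path. Non-convergence within ``max_iter`` is flagged on
    the result (``converged=False``), not raised.
    """
    opts = opts or FitOptions()
    reg = reg or RegularizationSpec()
    X, wvec = _resolve_inputs(paln, wts)
    N, L = X.shape
    if N < 2 or L < 2:
        raise ValueError("need at least 2 sequences and 2 positions")
    lam_v = reg.lambda_v
    lam_w = reg.resolved_lambda_w(L)

    def fun(theta: np.ndarray):
        v, w = _unpack(theta, L)
        f, g = _npll_core(v, w, X, wvec, lam_v, lam_w, True, dtype=opts.dtype)
        iu, ju = _pair_index(L)
        grad = np.concatenate([g[0].ravel(), g[1][iu, ju].ravel()])
        return f, grad

    x0 = (
        _pack(opts.init.v, opts.init.w)
        if opts.init is not None
        else np.zeros(L * Q + (L * (L - 1) // 2) * Q * Q)
    )
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": opts.max_iter, "gtol": opts.tol, "ftol": 1e-12},
    )
    v, w = _unpack(res.x, L)
    return PottsModel(
        v=v,
        w=w,
        converged=bool(res.success),
        n_iter=int(res.nit),
        objective=float(res.fun),
    )
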