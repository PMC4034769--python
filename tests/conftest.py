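import numpy as np
import pytest

from coevcontact.potts import Q


def brute_force_npll(v, w, X, weights, lam_v, lam_w):
    """Naive pseudo-likelihood: explicit loops over sequences, positions
    and the 21-state conditional normalizers. Independent of the
    vectorized implementation under test."""
    N, L = X.shape
    total = 0.0
    for n in range(N):
        for i in range(L):
            logits = np.array(v[i], dtype=float).copy()
            for j in range(L):
                if j != i:
                    logits = logits + w[i, j][:, X[n, j]]
            m = logits.max()
            logZ = m + np.log(np.sum(np.exp(logits - m)))
            total -= weights[n] * (logits[X[n, i]] - logZ)
    total += lam_v * float(np.sum(np.asarray(v) ** 2))
    iu, ju = np.triu_indices(L, k=1)
    total += lam_w * float(np.sum(np.asarray(w)[iu, ju] ** 2))
    return total


def random_symmetric_params(rng, L, v_scale=0.3, w_scale=0.2):
    v = rng.normal(0.0, v_scale, (L, Q))
    w = rng.normal(0.0, w_scale, (L, L, Q, Q))
    w = (w + w.transpose(1, 0, 3, 2)) / 2.0
    w[np.arange(L), np.arange(L)] = 0.0
    return v, w


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
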