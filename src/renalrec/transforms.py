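"""Unconstrained parameterization of correlation-matrix Cholesky factors.

A correlation matrix C factors as C = L L' with L lower triangular and
unit-norm rows.  L is parameterized by d(d-1)/2 unconstrained reals y through
canonical partial correlations z = tanh(y):

    w_ij = prod_{k<j} sqrt(1 - z_ik^2),   L_ij = z_ij * w_ij (j < i),
    L_ii = w_ii.

Under an LKJ(eta) prior on C, the induced log density on y (prior plus
transform Jacobian) separates per entry:

    log p(y) = sum_{i>k} gamma_k * log(1 - tanh(y_ik)^2),
    gamma_k  = (d - k)/2 + eta - 1        (k = 0-based column index)

which makes the prior gradient simply -2 * gamma_k * tanh(y_ik).

Block-diagonal structures (independent per-response correlation blocks, no
cross-response blocks) are supported by applying the transform per block.
"""

from __future__ import annotations

import numpy as np

__all__ = ["n_corr_params", "corr_chol_forward", "corr_chol_backward",
           "lkj_logprior", "lkj_logprior_grad", "BlockCholesky"]


def n_corr_params(d):
    return d * (d - 1) // 2


_CACHE = {}


def _tril_idx(d):
    if d not in _CACHE:
        idx = np.tril_indices(d, -1)
        mask = np.tril(np.ones((d, d)))
        # gamma coefficients of the LKJ(eta) density in y space (eta part
        # added at use): (d - k)/2 - 1 + eta with k the column index
        half_dk = (d - idx[1]) / 2.0
        _CACHE[d] = (idx, mask, half_dk)
    return _CACHE[d][0]


def _tril_mask(d):
    _tril_idx(d)
    return _CACHE[d][1]


def _lkj_gamma(d, eta):
    _tril_idx(d)
    return _CACHE[d][2] + (eta - 1.0)


def _log1m_tanh2(y):
    """log(1 - tanh(y)^2), stable for large |y| (= 2 log sech y)."""
    ay = np.abs(y)
    return 2.0 * (np.log(2.0) - ay - np.log1p(np.exp(-2.0 * ay)))


def corr_chol_forward(yvec, d):
    """Map unconstrained vector to (L, cache) for a d x d correlation
    Cholesky factor."""
    idx = _tril_idx(d)
    yvec = np.asarray(yvec, float)
    z = np.zeros((d, d))
    z[idx] = np.tanh(yvec)
    log1mz2 = np.zeros((d, d))
    log1mz2[idx] = _log1m_tanh2(yvec)
    cum = np.cumsum(log1mz2, axis=1)
    w = np.ones((d, d))
    w[:, 1:] = np.exp(0.5 * cum[:, :-1])
    L = z * w
    di = np.arange(d)
    L[di, di] = w[di, di]
    return L, (z, w, idx)


def corr_chol_backward(grad_L, cache):
    """Pull a gradient w.r.t. L back to the unconstrained vector y."""
    z, w, idx = cache
    d = z.shape[0]
    gL = np.asarray(grad_L, float)
    L = z * w
    di = np.arange(d)
    L[di, di] = w[di, di]
    gLw = gL * w
    gLw *= _tril_mask(d)
    np.fill_diagonal(gLw, 0.0)
    P = gL * L
    # suffix sums over columns j >= k, restricted to the lower triangle
    P *= _tril_mask(d)
    suff = np.cumsum(P[:, ::-1], axis=1)[:, ::-1]
    S = np.zeros((d, d))
    S[:, :-1] = suff[:, 1:]          # S_ik = sum_{j>k, j<=i} gL_ij * L_ij
    # chain rule through z = tanh(y): dz/dy = 1 - z^2; the 1/(1-z^2) inside
    # dL/dz for downstream entries cancels against it, leaving -z * S
    grad_y = gLw[idx] * (1 - z[idx] ** 2) - z[idx] * S[idx]
    return grad_y


def lkj_logprior(yvec, d, eta=2.0):
    """LKJ(eta) log prior on C plus the transform log-Jacobian, in y space."""
    yvec = np.asarray(yvec, float)
    gam = _lkj_gamma(d, eta)
    return float(np.sum(gam * _log1m_tanh2(yvec)))


def lkj_logprior_grad(yvec, d, eta=2.0):
    yvec = np.asarray(yvec, float)
    gam = _lkj_gamma(d, eta)
    return -2.0 * gam * np.tanh(yvec)


class BlockCholesky:
    """Correlation Cholesky assembled from independent diagonal blocks.

    ``block_sizes=[d]`` gives the full matrix; ``[p]*M`` restricts to
    within-response correlations (no cross-response blocks).
    """

    def __init__(self, block_sizes):
        self.block_sizes = list(block_sizes)
        self.d = sum(self.block_sizes)
        self.n_params = sum(n_corr_params(b) for b in self.block_sizes)
        self._offsets = []
        off_y, off_d = 0, 0
        for b in self.block_sizes:
            self._offsets.append((off_y, off_d, b))
            off_y += n_corr_params(b)
            off_d += b

    def forward(self, yvec):
        L = np.eye(self.d)
        caches = []
        for off_y, off_d, b in self._offsets:
            Lb, cache = corr_chol_forward(
                yvec[off_y:off_y + n_corr_params(b)], b)
            L[off_d:off_d + b, off_d:off_d + b] = Lb
            caches.append(cache)
        return L, caches

    def backward(self, grad_L, caches):
        out = np.empty(self.n_params)
        for (off_y, off_d, b), cache in zip(self._offsets, caches):
            gLb = grad_L[off_d:off_d + b, off_d:off_d + b]
            out[off_y:off_y + n_corr_params(b)] = corr_chol_backward(gLb, cache)
        return out

    def logprior(self, yvec, eta=2.0):
        return sum(
            lkj_logprior(yvec[off_y:off_y + n_corr_params(b)], b, eta)
            for off_y, off_d, b in self._offsets)

    def logprior_grad(self, yvec, eta=2.0):
        out = np.empty(self.n_params)
        for off_y, off_d, b in self._offsets:
            out[off_y:off_y + n_corr_params(b)] = lkj_logprior_grad(
                yvec[off_y:off_y + n_corr_params(b)], b, eta)
        return out
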