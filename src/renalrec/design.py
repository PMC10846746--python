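"""Stacked block-diagonal design system and thin-QR decorrelation.

The M response regressions share one predictor matrix ``X`` (N x p).  Stacking
them into a single univariate system uses Kronecker block diagonals:

    X_full  = I_M (x) X                      -> columns indexed (m, j)
    Zg_full = [I_M (x) X_l]_{l=1..L}         -> columns indexed (l, m, j)
    Zb_full = [I_M (x) X_k]_{k=1..K}         -> columns indexed (k, m, j)

where ``X_l`` (``X_k``) is ``X`` with rows outside treatment l (patient k)
zeroed.  Multiplying by stacked coefficient vectors reproduces the additive
linear predictor row by row.

Nutrient intakes span four orders of magnitude (mg/d to ml/d), so the common
effects are estimated after scaling the predictor columns by their sample sd
and a thin QR factorization ``X = Q* R*`` with ``Q* = Q sqrt(n-1)``,
``R* = R / sqrt(n-1)``; original-scale coefficients are recovered through
``R*^{-1}`` and the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solve_triangular

__all__ = ["DesignSystem", "QRDecorrelation", "Standardizer",
           "build_design", "thin_qr", "recover_beta"]


@dataclass
class DesignSystem:
    X_full: sp.spmatrix           # (M*N, M*p)
    Zg_full: sp.spmatrix          # (M*N, L*M*p)
    Zb_full: sp.spmatrix          # (M*N, K*M*p)
    row_index: list               # (patient, response, obs) per stacked row
    col_index_beta: list          # (j, m) per X_full column
    col_index_g: list             # (l, j, m)
    col_index_b: list             # (k, j, m)
    X: np.ndarray                 # the plain (N, p) predictor matrix
    treatments: np.ndarray        # (K,) treatment of each patient (by position)
    patient_ids: np.ndarray

    def predict(self, beta, g, b):
        """mu for stacked coefficient vectors (flattened m-major within level)."""
        return (self.X_full @ np.ravel(beta)
                + self.Zg_full @ np.ravel(g)
                + self.Zb_full @ np.ravel(b))


@dataclass
class QRDecorrelation:
    Q_star: np.ndarray
    R_star: np.ndarray
    R_star_inv: np.ndarray
    n: int


def build_design(cohort) -> DesignSystem:
    """Assemble the block-diagonal system from a cohort (response-major rows:
    row t = m*N + n)."""
    X = cohort.x_matrix()
    N, p = X.shape
    M = len(cohort.response_names)
    patients = cohort.patients
    K = len(patients)
    pat_pos = {int(k): idx for idx, k in enumerate(patients)}
    treat_of = np.array([cohort.treatment_of(k) for k in patients])
    labels = np.unique(treat_of)
    L = len(labels)
    lab_pos = {int(t): idx for idx, t in enumerate(labels)}

    row_pat = cohort.df["patient"].to_numpy()
    row_obs = cohort.df["obs"].to_numpy()
    row_tr = cohort.df["treatment"].to_numpy()
    for t in np.unique(row_tr):
        if int(t) not in lab_pos:  # pragma: no cover - labels derive from rows
            raise ValueError(f"patient with unknown treatment label {t}")

    I_M = sp.identity(M, format="csr")
    Xs = sp.csr_matrix(X)
    X_full = sp.kron(I_M, Xs, format="csr")

    def selector(groups, positions, n_groups):
        blocks = []
        for gidx in range(n_groups):
            mask = (positions == gidx).astype(float)
            blocks.append(sp.kron(I_M, sp.csr_matrix(X * mask[:, None]),
                                  format="csr"))
        return sp.hstack(blocks, format="csr")

    row_tr_pos = np.array([lab_pos[int(t)] for t in row_tr])
    row_pat_pos = np.array([pat_pos[int(k)] for k in row_pat])
    Zg_full = selector(labels, row_tr_pos, L)
    Zb_full = selector(patients, row_pat_pos, K)

    row_index = [(int(row_pat[n]), m, int(row_obs[n]))
                 for m in range(M) for n in range(N)]
    col_beta = [(j, m) for m in range(M) for j in range(p)]
    col_g = [(int(labels[l]), j, m)
             for l in range(L) for m in range(M) for j in range(p)]
    col_b = [(int(patients[k]), j, m)
             for k in range(K) for m in range(M) for j in range(p)]
    return DesignSystem(X_full, Zg_full, Zb_full, row_index,
                        col_beta, col_g, col_b, X, treat_of, patients)


def thin_qr(X, n=None, names=None) -> QRDecorrelation:
    """Thin QR scaled by sqrt(n-1); errors on rank deficiency naming the
    collinear column pair."""
    X = np.asarray(X, float)
    if n is None:
        n = X.shape[0]
    if n <= 1:
        raise ValueError("thin_qr requires n > 1")
    Q, R = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.flatnonzero(diag <= max(tol, 1e-12))
    if bad.size:
        j = int(bad[0])
        # most correlated earlier column is the collinear partner
        Xc = X - X.mean(0)
        norms = np.linalg.norm(Xc, axis=0)
        norms[norms == 0] = 1.0
        corr = (Xc[:, :j].T @ Xc[:, j]) / (norms[:j] * norms[j] + 1e-300)
        partner = int(np.argmax(np.abs(corr))) if j > 0 else j
        nm = (lambda i: names[i]) if names else (lambda i: f"column {i}")
        raise ValueError(
            f"design is rank deficient: {nm(j)} is collinear with "
            f"{nm(partner)} (|R| diagonal {diag[j]:.3e})")
    s = np.sqrt(n - 1.0)
    R_star = R / s
    R_star_inv = solve_triangular(R_star, np.eye(R.shape[0]))
    return QRDecorrelation(Q_star=Q * s, R_star=R_star,
                           R_star_inv=R_star_inv, n=int(n))


def recover_beta(beta_star, qr: QRDecorrelation):
    """Map decorrelated coefficients back: beta = R*^{-1} beta*."""
    beta_star = np.asarray(beta_star, float)
    if beta_star.shape[0] != qr.R_star_inv.shape[1]:
        raise ValueError(
            f"beta_star has leading dimension {beta_star.shape[0]}, "
            f"expected {qr.R_star_inv.shape[1]}")
    return qr.R_star_inv @ beta_star


class Standardizer:
    """Scale predictor columns by their sample sd (and optionally center).

    Binary covariates are left unscaled by default (``scale_binary=False``)
    so their coefficients keep a per-category interpretation.  Centering is
    off by default: with patient-varying coefficients and a single shared
    intercept per response, centering would implicitly introduce
    patient-specific intercept offsets (coef_k . center) that the additive
    hierarchical model cannot represent — scale-only standardization keeps
    the fitted model in the same class as the raw-predictor model while
    still conditioning the QR decomposition.
    """

    def __init__(self, X, binary=None, scale_binary=False, center=False):
        X = np.asarray(X, float)
        self.center = X.mean(axis=0) if center else np.zeros(X.shape[1])
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        if binary is None:
            binary = np.zeros(X.shape[1], bool)
        self.binary = np.asarray(binary, bool)
        self.scale = np.where(self.binary & ~scale_binary, 1.0, sd)
        self.scale = np.where(self.scale == 0, 1.0, self.scale)

    def transform(self, X):
        return (np.asarray(X, float) - self.center) / self.scale

    def coef_to_original(self, beta_std):
        """Per-unit coefficients on the raw predictor scale."""
        return beta_std / self.scale[:, None]

    def intercept_to_original(self, intercept_std, beta_std):
        """Intercept on the raw scale given standardized-scale coefficients."""
        return intercept_std - (self.center / self.scale) @ beta_std
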