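"""Spatial principal component analysis (sPCA) eigen-problem.

The spatial PCs are the eigenvectors of the symmetric p x p matrix

    H = 1/(2n) X^T (L^T + L) X

where X is the n x p centred allele-frequency matrix and L the spatial
weight matrix.  Each eigenvalue factorises as the product of the variance
of the corresponding score X v and its Moran's I on the network, so
positive eigenvalues capture global (positively autocorrelated) structure
and negative eigenvalues local (negatively autocorrelated) structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .genodata import CentredFreqMatrix, ValidationError
from .spatial import SpatialWeights

__all__ = ["SpcaResult", "spca", "moran_index"]

#: relative cut below which eigenvalues are treated as rank-deficiency zeros
DEFAULT_TOL = 1e-9


@dataclass
class SpcaResult:
    """Eigen-decomposition of the sPCA matrix H.

    ``lambda_pos`` holds the r positive eigenvalues sorted decreasing;
    ``lambda_neg`` the s negative eigenvalues sorted by decreasing absolute
    value (stored signed).  Loadings are unit-norm columns of ``V_pos`` /
    ``V_neg`` aligned with the eigenvalues; scores are ``X @ v``.
    ``var_moran`` maps each axis to its (variance, Moran's I) pair, with
    positive axes first.
    """

    lambda_pos: np.ndarray  # (r,)
    lambda_neg: np.ndarray  # (s,) signed, |.| decreasing
    V_pos: np.ndarray  # (p, r)
    V_neg: np.ndarray  # (p, s)
    scores_pos: np.ndarray  # (n, r)
    scores_neg: np.ndarray  # (n, s)
    var_moran: np.ndarray  # (r+s, 2)
    n: int
    p: int
    rank: int

    @property
    def r(self) -> int:
        return self.lambda_pos.size

    @property
    def s(self) -> int:
        return self.lambda_neg.size

    @property
    def eigenvalues(self) -> np.ndarray:
        """All retained eigenvalues, positive side first."""
        return np.concatenate([self.lambda_pos, self.lambda_neg])


def _symmetric_weight(W: SpatialWeights) -> np.ndarray:
    return (W.L + W.L.T) / 2.0


def moran_index(z: np.ndarray, W: SpatialWeights) -> float:
    """Moran's I spatial autocorrelation of a vector on the network.

    For row-standardised weights I = z^T M z / z^T z with M = (L + L^T)/2
    and z centred; for binary weights the classical n/S0 normalisation is
    applied, S0 being the total weight.
    """
    z = np.asarray(z, dtype=float)
    z = z - z.mean()
    denom = z @ z
    if denom == 0:
        raise ValidationError("Moran's I is undefined for a constant vector")
    M = _symmetric_weight(W)
    value = (z @ M @ z) / denom
    if W.style == "binary":
        value *= z.size / W.L.sum()
    return float(value)


def _eigh_split(
    H: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecompose symmetric H; return (lam_pos, V_pos, lam_neg, V_neg)."""
    lam, V = scipy.linalg.eigh(H)
    cut = tol * np.max(np.abs(lam)) if lam.size else 0.0
    keep = np.abs(lam) > cut
    lam, V = lam[keep], V[:, keep]
    pos = lam > 0
    order_pos = np.argsort(-lam[pos])
    order_neg = np.argsort(-np.abs(lam[~pos]))
    return (
        lam[pos][order_pos],
        V[:, pos][:, order_pos],
        lam[~pos][order_neg],
        V[:, ~pos][:, order_neg],
    )


def spca_eigenvalues(
    X: np.ndarray, M: np.ndarray, tol: float = DEFAULT_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Retained (lambda_pos, lambda_neg) of H = X^T M X / n, eigenvalues only.

    Fast path used inside the permutation loop; ``M`` is the symmetrised
    weight matrix (L + L^T)/2.
    """
    n = X.shape[0]
    H = X.T @ (M @ X) / n
    lam = scipy.linalg.eigh(H, eigvals_only=True)
    cut = tol * np.max(np.abs(lam)) if lam.size else 0.0
    lam = lam[np.abs(lam) > cut]
    pos = lam[lam > 0]
    neg = lam[lam < 0]
    return np.sort(pos)[::-1], neg[np.argsort(-np.abs(neg))]


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|loading| entry is positive."""
    if V.size == 0:
        return V
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def spca(
    X: CentredFreqMatrix, W: SpatialWeights, tol: float = DEFAULT_TOL
) -> SpcaResult:
    """Solve the sPCA eigen-problem for centred data X on the network W.

    Eigenvalues with |lambda| <= tol * max|lambda| are discarded as
    rank-deficiency zeros (centring alone removes one dimension).
    """
    if X.n != W.n:
        raise ValidationError(
            f"genotype units ({X.n}) and network size ({W.n}) do not match"
        )
    if np.max(np.abs(X.X.mean(axis=0))) > 1e-8:
        raise ValidationError("X columns are not centred")
    n = X.n
    M = _symmetric_weight(W)
    H = X.X.T @ (M @ X.X) / n
    lam_pos, V_pos, lam_neg, V_neg = _eigh_split(H, tol)
    V_pos, V_neg = _fix_signs(V_pos), _fix_signs(V_neg)
    scores_pos, scores_neg = X.X @ V_pos, X.X @ V_neg

    def _vm(scores: np.ndarray) -> np.ndarray:
        out = np.empty((scores.shape[1], 2))
        for k in range(scores.shape[1]):
            z = scores[:, k]
            out[k, 0] = float(z @ z) / n  # variance, divisor n (scores centred)
            out[k, 1] = moran_index(z, W)
        return out

    var_moran = np.vstack([_vm(scores_pos), _vm(scores_neg)])
    return SpcaResult(
        lambda_pos=lam_pos,
        lambda_neg=lam_neg,
        V_pos=V_pos,
        V_neg=V_neg,
        scores_pos=scores_pos,
        scores_neg=scores_neg,
        var_moran=var_moran,
        n=n,
        p=X.p,
        rank=lam_pos.size + lam_neg.size,
    )
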