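"""Linear-algebra helpers shared across modules.

A generator here always means a real square matrix with nonnegative
off-diagonals and zero row sums. Generators of Markov-modulated processes
are generally non-symmetric and possibly non-diagonalizable, so the matrix
exponential uses an eigendecomposition fast path (reusable across branch
lengths) with a scaling-and-squaring fallback.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .errors import ValidationError

#: relative condition limit above which the eigenvector basis is distrusted
_EIG_COND_LIMIT = 1e8
#: tolerance for the reconstruction check of the eigendecomposition
_EIG_RECON_TOL = 1e-10


def stationary_distribution(rate_matrix: np.ndarray, *, tol: float = 1e-9) -> np.ndarray:
    """Normalized left null vector of a CTMC generator.

    Solves pi @ Q = 0 with sum(pi) = 1 by replacing one equation of the
    transposed system with the normalization constraint, then verifies the
    residual. Raises :class:`ValidationError` when the chain has no unique
    strictly positive stationary distribution (reducible chain).
    """
    q = np.asarray(rate_matrix, dtype=float)
    n = q.shape[0]
    if q.shape != (n, n):
        raise ValidationError("rate matrix must be square")
    if n == 1:
        return np.ones(1)
    if not np.all(np.isfinite(q)):
        raise ValidationError("rate matrix contains non-finite entries")
    # replace one balance equation by the normalization constraint; fall
    # back to least squares if that square system is singular
    a = q.T.copy()
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        a_full = np.vstack([q.T, np.ones(n)])
        b_full = np.zeros(n + 1)
        b_full[-1] = 1.0
        try:
            pi, *_ = np.linalg.lstsq(a_full, b_full, rcond=None)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"stationary solve failed: {exc}") from exc
    residual = np.abs(pi @ q).max()
    if not np.isfinite(residual) or residual > tol or np.any(pi < -tol):
        raise ValidationError(
            "stationary distribution ill-defined (chain may be reducible); "
            f"residual={residual:.2e}"
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def is_irreducible(rate_matrix: np.ndarray, *, tol: float = 0.0) -> bool:
    """True when the directed graph of positive rates is strongly connected."""
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix

    q = np.asarray(rate_matrix, dtype=float)
    adj = csr_matrix((q > tol).astype(np.int8))
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    return n_comp == 1


class MatrixExponentiator:
    """Computes ``expm(t * Q)`` for many values of ``t``.

    Eigendecomposes ``Q`` once; when the eigenvector matrix is
    well-conditioned and reconstructs ``Q`` accurately, each call is three
    small matrix products. Otherwise every call falls back to
    scaling-and-squaring Pade (scipy.linalg.expm), which is robust for
    defective or badly conditioned generators.
    """

    def __init__(self, rate_matrix: np.ndarray):
        self.q = np.asarray(rate_matrix, dtype=float)
        self._use_eig = False
        try:
            w, v = np.linalg.eig(self.q)
            cond = np.linalg.cond(v)
            if np.isfinite(cond) and cond < _EIG_COND_LIMIT:
                vinv = np.linalg.inv(v)
                recon = (v * w) @ vinv
                scale = max(1.0, np.abs(self.q).max())
                if np.abs(recon.real - self.q).max() <= _EIG_RECON_TOL * scale * cond:
                    self._w, self._v, self._vinv = w, v, vinv
                    self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    def expm(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValidationError("elapsed time t must be nonnegative")
        if t == 0:
            return np.eye(self.q.shape[0])
        if self._use_eig:
            p = ((self._v * np.exp(self._w * t)) @ self._vinv).real
        else:
            p = scipy.linalg.expm(self.q * t)
        # clip tiny negative round-off and renormalize rows
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def expm_batch(self, ts: np.ndarray) -> np.ndarray:
        """``expm(t * Q)`` for a vector of times, shape (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValidationError("elapsed time t must be nonnegative")
        if self._use_eig:
            ew = np.exp(np.multiply.outer(ts, self._w))  # (B, n)
            p = ((self._v[None, :, :] * ew[:, None, :]) @ self._vinv).real
        else:
            p = np.stack([scipy.linalg.expm(self.q * t) for t in ts])
        zero = ts == 0
        if zero.any():
            p[zero] = np.eye(self.q.shape[0])
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p
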