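"""Sparsemax: Euclidean projection onto the probability simplex.

Unlike softmax, the projection yields exact zeros, which is what makes it
suitable for sparse cell-type compositions. The forward pass is the
sorted-threshold algorithm; the Jacobian-vector product needed for
backpropagation only involves the support of the output.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

__all__ = ["sparsemax", "sparsemax_jvp"]


def sparsemax(v: np.ndarray) -> np.ndarray:
    """Project each row of ``v`` (or a single vector) onto the simplex.

    Returns ``argmin_p ||p - v||^2  s.t.  p >= 0, sum(p) = 1``.
    Translation-invariant: adding a constant to a row leaves the result
    unchanged.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DomainError("sparsemax input contains non-finite entries")
    single = v.ndim == 1
    V = v[None, :] if single else v
    n, T = V.shape
    if T < 1:
        raise DomainError("sparsemax needs at least one coordinate")
    U = -np.sort(-V, axis=1)  # descending
    css = np.cumsum(U, axis=1)
    ks = np.arange(1, T + 1, dtype=float)
    # largest k with 1 + k*u_(k) > cumsum_k
    cond = 1.0 + ks * U > css
    k = cond.sum(axis=1)  # >= 1 always
    tau = (css[np.arange(n), k - 1] - 1.0) / k
    P = np.maximum(V - tau[:, None], 0.0)
    return P[0] if single else P


def sparsemax_jvp(p: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
    """Backpropagate ``grad_out`` (dL/dp) through sparsemax with output ``p``.

    On the support S of p the Jacobian is I - (1/|S|) 11^T; off-support
    coordinates receive zero gradient.
    """
    supp = (p > 0).astype(float)
    g = grad_out * supp
    mean_on_supp = g.sum(axis=-1, keepdims=True) / supp.sum(axis=-1, keepdims=True)
    return supp * (g - mean_on_supp)
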