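"""Shared helpers: packed amplitude vectors and DIIS acceleration.

Doubles amplitudes are symmetric under simultaneous (ai) <-> (bj) exchange.
Flat vectors stack the singles block with the packed upper triangle over
composite (ai) indices.  Inner products between amplitude-space objects are
always the *full* unrestricted sums ``x1.y1 + sum_aibj x2 y2`` (so einsum
transposition of a contraction is its adjoint); :func:`full_dot` implements
this pairing on flat vectors via weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pack", "unpack", "full_dot", "pack_weights", "n_packed", "DIIS"]


def n_packed(nv: int, no: int) -> int:
    ns = nv * no
    return ns + ns * (ns + 1) // 2


def _triu_indices(ns: int):
    return np.triu_indices(ns)


def pack(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Flatten (x1, symmetric x2) into a packed vector."""
    nv, no = x1.shape
    ns = nv * no
    m = x2.reshape(ns, ns)
    iu = _triu_indices(ns)
    return np.concatenate([x1.ravel(), m[iu]])


def unpack(z: np.ndarray, nv: int, no: int):
    ns = nv * no
    x1 = z[:ns].reshape(nv, no)
    m = np.zeros((ns, ns), dtype=z.dtype)
    iu = _triu_indices(ns)
    m[iu] = z[ns:]
    m = m + m.T - np.diag(np.diag(m))
    return x1, m.reshape(nv, no, nv, no)


def pack_weights(nv: int, no: int) -> np.ndarray:
    """Weights turning a packed dot product into the full-sum pairing."""
    ns = nv * no
    w2 = np.full((ns, ns), 2.0)
    np.fill_diagonal(w2, 1.0)
    iu = _triu_indices(ns)
    return np.concatenate([np.ones(ns), w2[iu]])


def full_dot(za: np.ndarray, zb: np.ndarray, nv: int, no: int) -> float:
    return float(np.sum(pack_weights(nv, no) * za * zb))


class DIIS:
    """Direct inversion in the iterative subspace (Pulay mixing)."""

    def __init__(self, depth: int = 8):
        self.depth = depth
        self.params: list[np.ndarray] = []
        self.errors: list[np.ndarray] = []

    def update(self, param: np.ndarray, error: np.ndarray) -> np.ndarray:
        self.params.append(param.copy())
        self.errors.append(error.copy())
        if len(self.params) > self.depth:
            self.params.pop(0)
            self.errors.pop(0)
        k = len(self.params)
        if k == 1:
            return param
        B = np.empty((k + 1, k + 1))
        B[:k, :k] = np.array(
            [[float(ei @ ej) for ej in self.errors] for ei in self.errors]
        )
        B[k, :] = -1.0
        B[:, k] = -1.0
        B[k, k] = 0.0
        rhs = np.zeros(k + 1)
        rhs[k] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:k]
        except np.linalg.LinAlgError:
            self.params = self.params[-1:]
            self.errors = self.errors[-1:]
            return param
        return sum(ci * pi for ci, pi in zip(c, self.params))
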