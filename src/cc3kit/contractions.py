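"""Instrumented tensor contractions.

All performance-relevant contractions in the package go through :func:`contract`,
a thin wrapper around ``numpy.einsum`` that, when a :class:`FlopCounter` is
active, records the multiply-add count of each contraction.  Following the
convention used when quoting coupled-cluster costs, a contraction with index
set I (union of free and summed indices) is charged ``2 * prod(dim(I))`` FLOP:
one multiplication and one addition per elementary update.
"""

from __future__ import annotations

import threading
from contextlib import contextmanager

import numpy as np

__all__ = ["contract", "FlopCounter", "count_flops"]

_state = threading.local()


class FlopCounter:
    """Accumulates multiply-add counts of contractions above a size cutoff.

    Parameters
    ----------
    cutoff:
        Contractions whose charged FLOP count is below ``cutoff`` are ignored.
        The default (0) counts everything.
    """

    def __init__(self, cutoff: int = 0):
        self.cutoff = int(cutoff)
        self.total = 0
        self.by_spec: dict[str, int] = {}
        self.n_contractions = 0

    def add(self, spec: str, flops: int) -> None:
        if flops < self.cutoff:
            return
        self.total += flops
        self.n_contractions += 1
        self.by_spec[spec] = self.by_spec.get(spec, 0) + flops

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"FlopCounter(total={self.total}, n={self.n_contractions})"


@contextmanager
def count_flops(cutoff: int = 0):
    """Context manager activating a :class:`FlopCounter` for the current thread."""
    counter = FlopCounter(cutoff)
    prev = getattr(_state, "counter", None)
    _state.counter = counter
    try:
        yield counter
    finally:
        _state.counter = prev


def _flops_of(spec: str, ops) -> int:
    inputs, _, out = spec.partition("->")
    dims: dict[str, int] = {}
    for term, op in zip(inputs.split(","), ops):
        for idx, d in zip(term, np.shape(op)):
            dims[idx] = d
    n = 1
    for d in dims.values():
        n *= d
    return 2 * n


def contract(spec: str, *ops: np.ndarray) -> np.ndarray:
    """``einsum`` with optional FLOP accounting.

    ``spec`` must be an explicit einsum subscript string (with ``->``).
    """
    counter = getattr(_state, "counter", None)
    if counter is not None:
        counter.add(spec, _flops_of(spec, ops))
    return np.einsum(spec, *ops, optimize=True)
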