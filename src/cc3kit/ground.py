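"""Blocked CC3 ground state: restricted i >= j >= k triples loop.

The production path of the package.  Triples amplitudes are materialized one
occupied triple at a time as (nv, nv, nv) blocks; each block is the permuted
sum over the six simultaneous permutations of the index pairs (ai), (bj),
(ck) of two matrix-multiplication seeds, divided by the orbital-energy
denominators.  All unique occupied orderings of a block are recovered by
transposing the virtual axes, so the loop runs over roughly nO^3/6 triples.
The dominant cost of one residual is 4 nV^4 nO^3 FLOP: half for constructing
the triples blocks, half for contracting them with integrals.

Residual conventions: the biorthonormal (amplitude-space) form is the
working representation (omega1 = F_ai and omega2 = g_aibj at t = 0); the
covariant projections <HF|E_ia H-bar|HF> and <HF|E_ia E_jb H-bar|HF> are
related by ``cov1 = 2 omega1`` and ``cov2 = 4 omega2 - 2 omega2^(ajbi)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from . import _equations as eq
from ._packing import DIIS, pack, unpack
from .contractions import contract
from .integrals import MOSystem, T1Hamiltonian, t1_transform

__all__ = [
    "Amplitudes",
    "TriplesBlock",
    "DenominatorBlock",
    "ResidualVector",
    "triples_denominator",
    "build_t3_block",
    "contravariant_triples",
    "ccsd_residual",
    "cc3_residual",
    "solve_ground_state",
    "cc3_energy",
    "covariant_residual",
    "biorthonormal_residual",
    "occupied_triples",
    "save_checkpoint",
    "load_checkpoint",
]

#: coefficients of the contravariant combination over the six virtual-index
#: permutations, in ``itertools.permutations`` order: 4 for the identity,
#: +1 for the cyclic, -2 for the pairwise-odd permutations (they sum to 0)
CONTRAVARIANT_COEFFS = (4.0, -2.0, -2.0, 1.0, 1.0, -2.0)

_PERMS3 = list(permutations(range(3)))
_INV_PERMS3 = [tuple(int(x) for x in np.argsort(p)) for p in _PERMS3]


@dataclass
class Amplitudes:
    """Singles (nv, no) and doubles (nv, no, nv, no) cluster amplitudes.

    ``t2`` is symmetric under simultaneous (ai) <-> (bj) exchange.
    """

    t1: np.ndarray
    t2: np.ndarray

    @classmethod
    def zeros(cls, nv: int, no: int) -> "Amplitudes":
        return cls(np.zeros((nv, no)), np.zeros((nv, no, nv, no)))


@dataclass
class DenominatorBlock:
    ijk: tuple
    eps3: np.ndarray  # (nv, nv, nv)


@dataclass
class TriplesBlock:
    ijk: tuple
    W: np.ndarray  # (nv, nv, nv) over (a, b, c)
    variance: str = "covariant"


@dataclass
class ResidualVector:
    omega1: np.ndarray
    omega2: np.ndarray
    variance: str = "biorthonormal"

    def max_norm(self) -> float:
        return max(np.abs(self.omega1).max(), np.abs(self.omega2).max())


def covariant_residual(res: ResidualVector) -> ResidualVector:
    """Map the biorthonormal residual to the covariant projections."""
    if res.variance == "covariant":
        return res
    om2 = res.omega2
    return ResidualVector(
        2.0 * res.omega1,
        4.0 * om2 - 2.0 * om2.transpose(0, 3, 2, 1),
        variance="covariant",
    )


def biorthonormal_residual(res: ResidualVector) -> ResidualVector:
    """Inverse of :func:`covariant_residual`."""
    if res.variance == "biorthonormal":
        return res
    om2 = res.omega2
    return ResidualVector(
        0.5 * res.omega1,
        (2.0 * om2 + om2.transpose(0, 3, 2, 1)) / 6.0,
        variance="biorthonormal",
    )


# ---------------------------------------------------------------------------
# triples machinery
# ---------------------------------------------------------------------------


def occupied_triples(no: int, core_occ=None):
    """Restricted i >= j >= k loop.

    Skips i = j = k (a triple excitation out of a single spatial orbital
    does not exist) and, when ``core_occ`` is given (CVS), every triple
    without a core index.
    """
    core = set(core_occ) if core_occ else None
    for i in range(no):
        for j in range(i + 1):
            for k in range(j + 1):
                if i == j == k:
                    continue
                if core is not None and not ({i, j, k} & core):
                    continue
                yield (i, j, k)


def triples_denominator(
    eps: np.ndarray,
    ijk,
    no: int,
    degeneracy_tol: float = 1e-10,
    on_degenerate: str = "raise",
) -> DenominatorBlock:
    """eps_a + eps_b + eps_c - eps_i - eps_j - eps_k for one occupied triple.

    Near-zero entries (|eps3| < ``degeneracy_tol``) indicate a degenerate
    zeroth-order partitioning; by default they raise, or warn when
    ``on_degenerate="warn"``.
    """
    i, j, k = ijk
    ev = eps[no:]
    e3 = ev[:, None, None] + ev[None, :, None] + ev[None, None, :]
    e3 = e3 - (eps[i] + eps[j] + eps[k])
    if np.abs(e3).min() < degeneracy_tol:
        msg = f"near-degenerate triples denominator in block {tuple(ijk)}"
        if on_degenerate == "raise":
            raise ZeroDivisionError(msg)
        warnings.warn(msg)
    return DenominatorBlock(ijk=tuple(ijk), eps3=e3)


class ReorderedIntegrals:
    """Integral slices pre-sorted into the layouts the triples loop consumes.

    The particle seed uses ``gvvv[k][d, b, c] = g[b, d, c, k]`` (a plain
    matrix multiplication per block); the hole seed uses the vooo block.
    The residual contractions consume the ovov / ooov / vvov blocks and the
    ov block of the dressed Fock matrix.
    """

    def __init__(self, g: np.ndarray, fock: np.ndarray, no: int):
        nv = g.shape[0] - no
        self.no, self.nv = no, nv
        self.gvvv = np.ascontiguousarray(g[no:, no:, no:, :no].transpose(3, 1, 0, 2))
        self.g_vooo = np.ascontiguousarray(g[no:, :no, :no, :no])
        self.g_ovov = np.ascontiguousarray(g[:no, no:, :no, no:])
        self.g_ooov = np.ascontiguousarray(g[:no, :no, :no, no:])
        self.g_ovoo = np.ascontiguousarray(g[:no, no:, :no, :no])
        self.g_vvov = np.ascontiguousarray(g[no:, no:, :no, no:])
        self.f_ov = np.ascontiguousarray(fock[:no, no:])

    @classmethod
    def from_ham(cls, ham: T1Hamiltonian) -> "ReorderedIntegrals":
        return cls(ham.g, ham.fock, ham.n_occ)


def _w_seeds(t2: np.ndarray, ints: ReorderedIntegrals, o1: int, o2: int, o3: int):
    s = contract("xd,dyz->xyz", t2[:, o1, :, o2], ints.gvvv[o3])
    s = s - contract("xyl,zl->xyz", t2[:, o1, :, :], ints.g_vooo[:, o3, :, o2])
    return s


def build_t3_block(
    ham: T1Hamiltonian | None,
    t2: np.ndarray,
    ijk,
    denom: DenominatorBlock | None,
    ints: ReorderedIntegrals | None = None,
    omega: float = 0.0,
    numerator_only: bool = False,
) -> TriplesBlock:
    """CC3 triples amplitudes for a fixed occupied triple i >= j >= k.

    The same routine builds response triples when called with a trial
    doubles vector as ``t2`` and/or dressed-derivative integral slices as
    ``ints`` ("called twice with different input tensors"); ``omega`` shifts
    the denominators for excited-state blocks.
    """
    i, j, k = ijk
    if not (i >= j >= k):
        raise ValueError("triples blocks require i >= j >= k")
    if ints is None:
        ints = ReorderedIntegrals.from_ham(ham)
    occ = (i, j, k)
    W = None
    seeds: dict = {}  # distinct occupied orderings only (three when two match)
    for perm, inv in zip(_PERMS3, _INV_PERMS3):
        o = tuple(occ[p] for p in perm)
        if o not in seeds:
            seeds[o] = _w_seeds(t2, ints, *o)
        s = np.transpose(seeds[o], inv)
        W = s if W is None else W + s
    if not numerator_only:
        W = -W / (denom.eps3 - omega)
    return TriplesBlock(ijk=tuple(ijk), W=W, variance="covariant")


def contravariant_triples(block: TriplesBlock) -> TriplesBlock:
    """Fixed linear combination of the six virtual-index permutations.

    ``W~[abc] = 4 W[abc] - 2 W[bac] - 2 W[acb] + W[cab] + W[bca] - 2 W[cba]``;
    the coefficients sum to zero.  In this form the spin-adapted singles
    contraction collapses to a single matrix multiplication per block.
    """
    if block.variance != "covariant":
        raise ValueError("input must be covariant")
    W = block.W
    Wt = sum(c * np.transpose(W, p) for c, p in zip(CONTRAVARIANT_COEFFS, _PERMS3))
    return TriplesBlock(ijk=block.ijk, W=Wt, variance="contravariant")


def _block_orderings(ijk):
    """Distinct occupied orderings of a block with the virtual-axis transpose
    recovering tau3[:, o1, :, o2, :, o3] from the sorted block."""
    out, seen = [], set()
    for perm in _PERMS3:
        occ = tuple(ijk[p] for p in perm)
        if occ in seen:
            continue
        seen.add(occ)
        out.append((occ, perm))
    return out


#: virtual-permutation combination collapsing the three vvvo-type doubles
#: couplings (2 g_bckd - g_bdkc paired with the exchange term) into a single
#: matrix multiplication per ordering; determined numerically against the
#: determinant engine (permutations in ``itertools.permutations`` order)
VVOV_COLLAPSE = (-1.0, 2.0, 0.0, 0.0, -1.0, 0.0)


def _block_couplings(
    blk: TriplesBlock,
    ints: ReorderedIntegrals,
    om1: np.ndarray | None,
    om2x: np.ndarray,
):
    """Triples contributions of one block.

    ``om2x`` accumulates the *unsymmetrized* doubles part (the caller applies
    the final (ai) <-> (bj) symmetrization).  The singles contraction uses the
    contravariant block; the dominant doubles contraction uses the collapsed
    vvvo combination -- one nv^4 matrix multiplication per occupied ordering.
    """
    W = blk.W
    Wt = sum(c * np.transpose(W, p) for c, p in zip(CONTRAVARIANT_COEFFS, _PERMS3))
    for (o1, o2, o3), axperm in _block_orderings(blk.ijk):
        Wp = np.transpose(W, axperm)
        Ws = sum(
            c * np.transpose(Wp, p) for c, p in zip(VVOV_COLLAPSE, _PERMS3) if c != 0.0
        )
        if om1 is not None:
            om1[:, o1] += 0.5 * contract(
                "acd,cd->a", np.transpose(Wt, axperm), ints.g_ovov[o2, :, o3, :]
            )
        # dressed-Fock couplings
        om2x[:, o1, :, o2] += contract("abc,c->ab", Wp, ints.f_ov[o3])
        om2x[:, o1, :, o3] -= contract("abc,c->ab", Wp, ints.f_ov[o2])
        # ooov-type couplings
        om2x[:, o1, :, :] += -2.0 * contract("abc,jc->abj", Wp, ints.g_ooov[o2, :, o3, :])
        om2x[:, o1, :, :] += contract("abc,cj->abj", Wp, ints.g_ovoo[o2, :, o3, :])
        om2x[:, o3, :, :] += contract("abc,cj->abj", Wp, ints.g_ovoo[o1, :, o2, :])
        # collapsed vvvo coupling (dominant cost)
        om2x[:, o1, :, o2] += contract("acd,bdc->ab", Ws, ints.g_vvov[:, :, o3, :])


# ---------------------------------------------------------------------------
# CCSD (dressed CCD) residual
# ---------------------------------------------------------------------------


_AMPLITUDE_OPS = {"t2", "t3", "r2", "l2", "l3", "r3", "t1", "r1", "l1"}


def _op_slice(name, letters, ops, no, n):
    """Blocked view of an operand: amplitudes are stored blocked, integral
    operands are sliced by the virtual/occupied letter pattern."""
    if name in _AMPLITUDE_OPS:
        return ops[name]
    arr = ops[name]
    idx = tuple(slice(no, n) if c in "abcde" else slice(0, no) for c in letters)
    return arr[idx]


def _eval_terms(terms, ops: dict, no: int, n: int, pair_sym: bool = False):
    """Evaluate a frozen term list on blocked operands.

    Three-operand terms are split into two explicit pairwise contractions
    (the inner one cached), so the FLOP accounting sees the factorized cost.
    """
    total = None
    cache: dict = {}
    for coef, spec, names in terms:
        ins, out = spec.split("->")
        parts = ins.split(",")
        arrs = [_op_slice(nm, p, ops, no, n) for nm, p in zip(names, parts)]
        if len(parts) == 2:
            res = contract(spec, *arrs)
        else:
            a, b, gspec = parts
            inner_out = "".join(
                ch for ch in dict.fromkeys(b + gspec) if ch in a or ch in out
            )
            key = (b, gspec, inner_out, names[1], names[2])
            if key not in cache:
                cache[key] = contract(f"{b},{gspec}->{inner_out}", arrs[1], arrs[2])
            res = contract(f"{a},{inner_out}->{out}", arrs[0], cache[key])
        res = coef * res
        total = res if total is None else total + res
    if pair_sym:
        total = total + total.transpose(2, 3, 0, 1)
    return total


def ccsd_residual(ham: T1Hamiltonian, amps: Amplitudes) -> ResidualVector:
    """T1-dressed closed-shell CCSD residual (biorthonormal convention).

    With the singles folded into the dressed integrals these are the CCD
    equations of the dressed Hamiltonian; quadratic contributions are
    factorized through four-index intermediates.
    """
    no, n = ham.n_occ, ham.n_orb
    ops = {"t2": amps.t2, "g": ham.g, "F": ham.fock}
    om1 = ham.fock[no:, :no] + _eval_terms(eq.OMEGA1_LIN, ops, no, n)
    om2 = ham.g[no:, :no, no:, :no] + _eval_terms(eq.OMEGA2_LIN, ops, no, n, pair_sym=True)
    om2 = om2 + _eval_terms(eq.OMEGA2_QUAD, ops, no, n, pair_sym=True)
    return ResidualVector(om1, om2)


# ---------------------------------------------------------------------------
# CC3 residual and energy
# ---------------------------------------------------------------------------


def cc3_energy(ham: T1Hamiltonian, t2: np.ndarray) -> float:
    """Total CC3 energy; the triples never enter the energy expression."""
    no = ham.n_occ
    g_ovov = ham.g[:no, no:, :no, no:]
    L = 2.0 * g_ovov - g_ovov.transpose(0, 3, 2, 1)
    return ham.reference_energy() + float(contract("aibj,iajb->", t2, L))


def cc3_residual(
    ham: T1Hamiltonian,
    amps: Amplitudes,
    ints: ReorderedIntegrals | None = None,
    core_occ=None,
    on_degenerate: str = "raise",
) -> ResidualVector:
    """CCSD residual plus triples contributions from the restricted block loop."""
    no, nv = ham.n_occ, ham.n_virt
    res = ccsd_residual(ham, amps)
    if no < 2:
        return res
    if ints is None:
        ints = ReorderedIntegrals.from_ham(ham)
    om1 = np.zeros_like(res.omega1)
    om2x = np.zeros_like(res.omega2)
    for ijk in occupied_triples(no, core_occ):
        denom = triples_denominator(ham.eps, ijk, no, on_degenerate=on_degenerate)
        blk = build_t3_block(ham, amps.t2, ijk, denom, ints=ints)
        _block_couplings(blk, ints, om1, om2x)
    return ResidualVector(
        res.omega1 + om1, res.omega2 + om2x + om2x.transpose(2, 3, 0, 1)
    )


def solve_ground_state(
    sys: MOSystem,
    conv: float = 1e-6,
    max_iter: int = 100,
    diis_depth: int = 8,
    triples: bool = True,
    core_occ=None,
    verbose: bool = False,
    callback=None,
):
    """DIIS-accelerated quasi-Newton solution of the CC3 amplitude equations.

    The error vectors are the orbital-energy-preconditioned residuals; the
    iteration stops when the residual infinity norm drops below ``conv``.
    Returns ``(Amplitudes, total energy, info dict)``.
    """
    no, nv = sys.n_occ, sys.n_virt
    eo, ev = sys.eps[:no], sys.eps[no:]
    d1 = ev[:, None] - eo[None, :]
    d2 = d1[:, :, None, None] + d1[None, None, :, :]
    amps = Amplitudes.zeros(nv, no)
    diis = DIIS(depth=diis_depth)
    history = []
    for it in range(max_iter):
        ham = t1_transform(sys, amps.t1)
        if triples:
            res = cc3_residual(ham, amps, core_occ=core_occ)
        else:
            res = ccsd_residual(ham, amps)
        err = res.max_norm()
        history.append(err)
        energy = cc3_energy(ham, amps.t2)
        if callback is not None:
            callback(it, err, energy)
        if verbose:
            print(f"  iter {it:3d}  E = {energy: .12f}  |Omega| = {err:.3e}")
        if err < conv:
            info = {"iterations": it, "residual_norm": err, "history": history}
            return amps, energy, info
        step1, step2 = -res.omega1 / d1, -res.omega2 / d2
        z = diis.update(pack(amps.t1 + step1, amps.t2 + step2), pack(step1, step2))
        t1, t2 = unpack(z, nv, no)
        amps = Amplitudes(t1, t2)
    raise RuntimeError(
        f"CC3 ground state did not converge in {max_iter} iterations; "
        f"residual history tail: {[f'{h:.2e}' for h in history[-5:]]}"
    )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(path, amps: Amplitudes, energy: float | None = None) -> None:
    """Store amplitudes in an HDF5 container (datasets t1, t2)."""
    import h5py

    with h5py.File(path, "w") as f:
        d1 = f.create_dataset("t1", data=amps.t1)
        d1.attrs["shape_convention"] = "(virtual, occupied)"
        d2 = f.create_dataset("t2", data=amps.t2)
        d2.attrs["shape_convention"] = "(a, i, b, j), pair symmetric"
        if energy is not None:
            f.attrs["energy"] = energy


def load_checkpoint(path) -> Amplitudes:
    import h5py

    with h5py.File(path, "r") as f:
        return Amplitudes(f["t1"][()], f["t2"][()])
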