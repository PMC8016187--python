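"""Unblocked dense CC3 reference implementation.

This module holds the *straightforward* form of the closed-shell CC3
equations: the full triples tensor is materialized in memory, no loop
restrictions, no precomputed intermediates and no covariant/contravariant
tricks.  It exists as the equivalence oracle for the blocked production code
in :mod:`cc3kit.ground` / :mod:`cc3kit.eom` and is only intended for tiny
systems (n_occ <= 4, n_virt <= 6).

Residuals are expressed in the biorthonormal (amplitude-space) convention:
at t = 0, ``omega1 = F_ai`` and ``omega2 = g_aibj``; the corresponding
covariant projections are ``2*omega1`` and ``4*omega2 - 2*omega2^(ajbi)``.

The working equations are spin-adapted closed-shell contractions of the
T1-dressed Hamiltonian (chemists' notation ``g_pqrs``):

* doubles->singles / doubles->doubles are the T1-dressed CCSD (CCD-form)
  equations;
* the triples amplitudes for CC3 are
  ``tau3 = -P^ [ t_aidj g_bdck - t_aibl g_cklj ] / eps3``
  with ``P^`` the sum over the six simultaneous permutations of the index
  pairs (ai), (bj), (ck);
* the Jacobian transform is the exact linearization of the residual, with
  the triples denominators shifted by the excitation energy.

Every term below was validated to machine precision against an exact
determinant-space evaluation of the same model (see :mod:`cc3kit.oracles`).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from .contractions import contract
from .integrals import MOSystem, T1Hamiltonian, t1_transform

__all__ = [
    "dense_energy",
    "dense_residual",
    "dense_tau3",
    "dense_jacobian_transform",
    "dense_eta",
    "DenseCC3Reference",
    "dense_cc3_reference",
]

# ---------------------------------------------------------------------------
# frozen working equations
# ---------------------------------------------------------------------------
# term = (coefficient, einsum spec, operand names); outputs are sliced blocks.
# Operands: t2 (vovo block), g / F (full dressed integrals), t3 (vovovo).

from ._equations import (
    OMEGA1_LIN,
    OMEGA2_LIN,
    OMEGA2_QUAD,
    W_TERMS,
    COUPLING1,
    COUPLING2,
)

_PAIR_PERMS = [
    tuple(sum(([2 * p, 2 * p + 1] for p in perm), [])) for perm in permutations(range(3))
]


def _pad(arr: np.ndarray, pattern: str, no: int, n: int) -> np.ndarray:
    """Zero-pad a blocked amplitude array to full orbital dimension."""
    shape = tuple(n for _ in pattern)
    out = np.zeros(shape, dtype=arr.dtype)
    idx = tuple(slice(no, n) if c == "v" else slice(0, no) for c in pattern)
    out[idx] = arr
    return out


def _slice_out(res: np.ndarray, out: str, no: int, n: int) -> np.ndarray:
    idx = tuple(slice(no, n) if c in "abc" else slice(0, no) for c in out)
    return res[idx]


def _eval(terms, ops: dict, no: int, n: int, pair_sym: bool = False):
    total = None
    for coef, spec, names in terms:
        res = coef * contract(spec, *(ops[nm] for nm in names))
        total = res if total is None else total + res
    out = terms[0][1].split("->")[1]
    total = _slice_out(total, out, no, n)
    if pair_sym:
        total = total + total.transpose(2, 3, 0, 1)
    return total


def _full_ops(ham: T1Hamiltonian, t2: np.ndarray, t3: np.ndarray | None = None) -> dict:
    no, n = ham.n_occ, ham.n_orb
    ops = {"g": ham.g, "F": ham.fock, "t2": _pad(t2, "vovo", no, n)}
    if t3 is not None:
        ops["t3"] = _pad(t3, "vovovo", no, n)
    return ops


def eps3_denominator(eps: np.ndarray, no: int) -> np.ndarray:
    """Full (nv,no,nv,no,nv,no) tensor of eps_a+eps_b+eps_c-eps_i-eps_j-eps_k."""
    ev, eo = eps[no:], eps[:no]
    d1 = ev[:, None] - eo[None, :]
    return (
        d1[:, :, None, None, None, None]
        + d1[None, None, :, :, None, None]
        + d1[None, None, None, None, :, :]
    )


def dense_tau3(ham: T1Hamiltonian, t2: np.ndarray, g=None, omega: float = 0.0,
               t2_name_ops: dict | None = None) -> np.ndarray:
    """Full CC3 triples tensor ``tau3 = -P^(W) / (eps3 - omega)``.

    ``g`` may override the dressed integrals (used for dressing-derivative
    directions in the Jacobian transform).
    """
    no, n = ham.n_occ, ham.n_orb
    ops = {"t2": _pad(t2, "vovo", no, n), "g": ham.g if g is None else g}
    W = None
    for coef, spec, names in W_TERMS:
        res = coef * contract(spec, *(ops[nm] for nm in names))
        W = res if W is None else W + res
    W = _slice_out(W, "aibjck", no, n)
    W = sum(np.transpose(W, p) for p in _PAIR_PERMS)
    return -W / (eps3_denominator(ham.eps, no) - omega)


def dense_energy(ham: T1Hamiltonian, t2: np.ndarray) -> float:
    """CC3 total energy (triples never enter the energy expression directly)."""
    no = ham.n_occ
    g_ovov = ham.g[:no, no:, :no, no:]
    L = 2.0 * g_ovov - g_ovov.transpose(0, 3, 2, 1)
    val = ham.reference_energy() + contract("aibj,iajb->", t2, L).item()
    return val if np.iscomplexobj(t2) or np.iscomplexobj(ham.h) else float(np.real(val))


def dense_residual(ham: T1Hamiltonian, t2: np.ndarray, triples: bool = True):
    """Biorthonormal-convention CC3 residual ``(omega1, omega2)``."""
    no, n, nv = ham.n_occ, ham.n_orb, ham.n_virt
    ops = _full_ops(ham, t2)
    om1 = ham.fock[no:, :no].copy()
    om1 = om1 + _eval(OMEGA1_LIN, ops, no, n)
    om2 = ham.g[no:, :no, no:, :no].copy()
    om2 = om2 + _eval(OMEGA2_LIN, ops, no, n, pair_sym=True)
    om2 = om2 + _eval(OMEGA2_QUAD, ops, no, n, pair_sym=True)
    if triples and no >= 2:
        t3 = dense_tau3(ham, t2)
        ops["t3"] = _pad(t3, "vovovo", no, n)
        om1 = om1 + _eval(COUPLING1, ops, no, n)
        om2 = om2 + _eval(COUPLING2, ops, no, n, pair_sym=True)
    return om1, om2


# ---------------------------------------------------------------------------
# dressing derivatives (response of the T1 transformation to a singles
# direction r1); delta g = sum of one-axis multiplications of the dressed g
# ---------------------------------------------------------------------------


def dressing_derivative(ham: T1Hamiltonian, r1: np.ndarray):
    """(dh, dg, dF): directional derivative of the dressed integrals along r1."""
    no, n = ham.n_occ, ham.n_orb
    R = np.zeros((n, n), dtype=np.result_type(ham.h, r1))
    R[no:, :no] = r1
    h, g = ham.h, ham.g
    dh = h @ R - R @ h
    dg = (
        -contract("pt,tqrs->pqrs", R, g)
        + contract("tq,ptrs->pqrs", R, g)
        - contract("rt,pqts->pqrs", R, g)
        + contract("ts,pqrt->pqrs", R, g)
    )
    o = slice(0, no)
    dF = dh + 2.0 * contract("pqii->pq", dg[:, :, o, o]) - contract("piiq->pq", dg[:, o, o, :])
    return dh, dg, dF


def dressing_adjoint(ham: T1Hamiltonian, Gh: np.ndarray | None, Gg: np.ndarray | None):
    """Adjoint of :func:`dressing_derivative`: gradient w.r.t. t1.

    Given gradients ``Gh = dL/d(h~)`` and ``Gg = dL/d(g~)`` (full-sum pairing),
    returns ``dL/dt1`` as an (nv, no) array.
    """
    no, n = ham.n_occ, ham.n_orb
    h, g = ham.h, ham.g
    M = np.zeros((n, n))  # dL/dR over the full matrix; only the vo block is free
    if Gh is not None:
        M += h.T @ Gh - Gh @ h.T
    if Gg is not None:
        M -= contract("pqrs,tqrs->pt", Gg, g)
        M += contract("pqrs,ptrs->qt", Gg, g).T
        M -= contract("pqrs,pqts->rt", Gg, g)
        M += contract("pqrs,pqrt->st", Gg, g).T
    return M[no:, :no]


# ---------------------------------------------------------------------------
# Jacobian transform: exact linearization of the residual, with the triples
# denominators shifted by omega
# ---------------------------------------------------------------------------


def _linearized(terms, ops: dict, dops: dict, no: int, n: int, pair_sym=False):
    """Sum of ``terms`` with each operand occurrence replaced by its direction."""
    total = None
    for coef, spec, names in terms:
        for pos, name in enumerate(names):
            if name not in dops:
                continue
            arrs = [dops[nm] if k == pos else ops[nm] for k, nm in enumerate(names)]
            res = coef * contract(spec, *arrs)
            total = res if total is None else total + res
    if total is None:
        out_shape = None
        raise ValueError("no linearization terms")
    out = terms[0][1].split("->")[1]
    total = _slice_out(total, out, no, n)
    if pair_sym:
        total = total + total.transpose(2, 3, 0, 1)
    return total


def cvs_triples_mask(no: int, nv: int, core) -> np.ndarray:
    """Boolean mask keeping triples entries with >= 1 core occupied index."""
    keep = np.zeros(no, bool)
    keep[list(core)] = True
    m = keep[None, :, None, None, None, None] | keep[None, None, None, :, None, None] \
        | keep[None, None, None, None, None, :]
    return np.broadcast_to(m, (nv, no, nv, no, nv, no))


def dense_jacobian_transform(
    ham: T1Hamiltonian,
    t2: np.ndarray,
    r1: np.ndarray,
    r2: np.ndarray,
    omega: float = 0.0,
    triples: bool = True,
    cvs_core=None,
):
    """Apply the CC3 Jacobian to the trial vector ``(r1, r2)``.

    The result is the directional derivative of the residual, except that the
    response-triples denominators are shifted: ``R3`` blocks are built with
    ``(eps3 - omega)``.  At ``omega = 0`` this is exactly ``d(Omega)/dt . r``.
    With ``cvs_core`` the triples tensors are restricted to entries carrying
    at least one core occupied index (the dense analogue of cycling the
    occupied triples loop).
    """
    no, n = ham.n_occ, ham.n_orb
    dh, dg, dF = dressing_derivative(ham, r1)
    ops = _full_ops(ham, t2)
    dops = {"t2": _pad(r2, "vovo", no, n), "g": dg, "F": dF}
    s1 = dF[no:, :no].copy()
    s1 = s1 + _linearized(OMEGA1_LIN, ops, dops, no, n)
    s2 = dg[no:, :no, no:, :no].copy()
    s2 = s2 + _linearized(OMEGA2_LIN, ops, dops, no, n, pair_sym=True)
    s2 = s2 + _linearized(OMEGA2_QUAD, ops, dops, no, n, pair_sym=True)
    if triples and no >= 2:
        tau3 = dense_tau3(ham, t2)
        r3 = dense_tau3(ham, r2, omega=omega) + dense_tau3(ham, t2, g=dg, omega=omega)
        if cvs_core is not None:
            mask = cvs_triples_mask(no, ham.n_virt, cvs_core)
            tau3 = np.where(mask, tau3, 0.0)
            r3 = np.where(mask, r3, 0.0)
        ops["t3"] = _pad(tau3, "vovovo", no, n)
        d3 = {"t3": _pad(r3, "vovovo", no, n)}
        # response triples contracted with ground-state integrals
        s1 = s1 + _linearized(COUPLING1, ops, d3, no, n)
        s2 = s2 + _linearized(COUPLING2, ops, d3, no, n, pair_sym=True)
        # ground-state triples contracted with r1-dressed integrals
        dints = {"g": dg, "F": dF}
        s1 = s1 + _linearized(COUPLING1, ops, dints, no, n)
        s2 = s2 + _linearized(COUPLING2, ops, dints, no, n, pair_sym=True)
    return s1, s2


def _sym6(x: np.ndarray) -> np.ndarray:
    return sum(np.transpose(x, p) for p in _PAIR_PERMS) / 6.0


def dense_l3(ham: T1Hamiltonian, l1: np.ndarray, l2: np.ndarray, omega: float = 0.0):
    """Folded left-triples tensor (Lambda3 for omega=0, L3 for excited states).

    Built as the adjoint of the triples->residual couplings applied to
    (l1, l2), symmetrized over the pair permutations and divided by
    ``-(eps3 - omega)``.
    """
    no, n = ham.n_occ, ham.n_orb
    ops = {"g": ham.g, "F": ham.fock}
    l1f = _pad(l1, "vo", no, n)
    l2f = _pad(l2, "vovo", no, n)
    G = np.zeros((n,) * 6)
    for coef, spec, names in COUPLING1:
        ins, out = spec.split("->")
        t3spec, gspec = ins.split(",")
        G += coef * contract(f"{out},{gspec}->{t3spec}", l1f, ops[names[1]])
    for coef, spec, names in COUPLING2:
        ins, out = spec.split("->")
        t3spec, gspec = ins.split(",")
        # the right-transform output is pair-symmetrized; for symmetric l2 the
        # adjoint doubles the plain term
        G += 2.0 * coef * contract(f"{out},{gspec}->{t3spec}", l2f, ops[names[1]])
    G = _slice_out(G, "aibjck", no, n)
    return -_sym6(G) / (eps3_denominator(ham.eps, no) - omega)


def dense_eta(ham: T1Hamiltonian, t2: np.ndarray):
    """Gradient of the energy w.r.t. the amplitudes (full-sum pairing)."""
    no, n = ham.n_occ, ham.n_orb
    g_ovov = ham.g[:no, no:, :no, no:]
    eta2 = 2.0 * g_ovov - g_ovov.transpose(0, 3, 2, 1)
    eta2 = contract("iajb->aibj", eta2)
    # energy h~/g~ gradients -> t1 gradient through the dressing adjoint
    Gh = np.zeros((n, n))
    Gh[:no, :no] = 2.0 * np.eye(no)
    Gg = np.zeros((n, n, n, n))
    o = slice(0, no)
    for i in range(no):
        for j in range(no):
            Gg[i, i, j, j] += 2.0
            Gg[i, j, j, i] -= 1.0
    # correlation part: E2 = sum t2_aibj (2 g_iajb - g_ibja)
    Gg[o, no:, o, no:] += 2.0 * contract("aibj->iajb", t2)
    Gg[o, no:, o, no:] -= contract("aibj->ibja", t2)
    eta1 = dressing_adjoint(ham, Gh, Gg)
    return eta1, eta2


# ---------------------------------------------------------------------------
# dense ground-state solver and reference bundle
# ---------------------------------------------------------------------------


def dense_solve_ground(sys: MOSystem, conv: float = 1e-10, max_iter: int = 200,
                       triples: bool = True):
    """Plain DIIS-accelerated solution of the dense CC3 equations."""
    from ._packing import DIIS, pack, unpack

    no, nv = sys.n_occ, sys.n_virt
    eo, ev = sys.eps[:no], sys.eps[no:]
    d1 = ev[:, None] - eo[None, :]
    d2 = d1[:, :, None, None] + d1[None, None, :, :]
    t1 = np.zeros((nv, no))
    t2 = np.zeros((nv, no, nv, no))
    diis = DIIS()
    for it in range(max_iter):
        ham = t1_transform(sys, t1)
        om1, om2 = dense_residual(ham, t2, triples=triples)
        err = max(np.abs(om1).max(), np.abs(om2).max())
        if err < conv:
            return t1, t2, dense_energy(ham, t2), it
        step1, step2 = -om1 / d1, -om2 / d2
        z = diis.update(pack(t1 + step1, t2 + step2), pack(step1, step2))
        t1, t2 = unpack(z, nv, no)
    raise RuntimeError(f"dense CC3 did not converge in {max_iter} iterations ({err:.2e})")


class DenseCC3Reference:
    """Converged dense CC3 state with on-demand Jacobian matrix and multipliers."""

    def __init__(self, sys: MOSystem, conv: float = 1e-11, triples: bool = True):
        if sys.n_occ > 4 or sys.n_virt > 6:
            raise ValueError("dense reference is restricted to n_occ <= 4, n_virt <= 6")
        self.sys = sys
        self.triples = triples
        self.t1, self.t2, self.energy, self.iterations = dense_solve_ground(
            sys, conv=conv, triples=triples
        )
        self.ham = t1_transform(sys, self.t1)

    # -- Jacobian ------------------------------------------------------------

    def jacobian_matrix(self, omega: float = 0.0) -> np.ndarray:
        """Explicit J(omega) over packed singles+doubles coordinates."""
        from ._packing import n_packed, pack, unpack

        nv, no = self.sys.n_virt, self.sys.n_occ
        dim = n_packed(nv, no)
        J = np.empty((dim, dim))
        for q in range(dim):
            e = np.zeros(dim)
            e[q] = 1.0
            r1, r2 = unpack(e, nv, no)
            s1, s2 = dense_jacobian_transform(
                self.ham, self.t2, r1, r2, omega=omega, triples=self.triples
            )
            J[:, q] = pack(s1, s2)
        return J

    def eigenvalues(self, n_roots: int, tol: float = 1e-10, max_cycles: int = 50):
        """Self-consistent eigenvalues of J(omega): omega_m = eig_m(J(omega_m))."""
        vals = np.sort(np.linalg.eigvals(self.jacobian_matrix(0.0)).real)
        out = []
        for m in range(n_roots):
            w = vals[m]
            for _ in range(max_cycles):
                ev = np.sort(np.linalg.eigvals(self.jacobian_matrix(w)).real)
                # home onto the eigenvalue closest to the current estimate
                w_new = ev[np.argmin(np.abs(ev - w))]
                if abs(w_new - w) < tol:
                    w = w_new
                    break
                w = w_new
            out.append(w)
        return np.array(sorted(out))

    def multipliers(self):
        """Solve eta + lambda J = 0 in packed coordinates (full-sum pairing)."""
        from ._packing import pack, pack_weights, unpack

        nv, no = self.sys.n_virt, self.sys.n_occ
        eta1, eta2 = dense_eta(self.ham, self.t2)
        w = pack_weights(nv, no)
        J = self.jacobian_matrix(0.0)
        # <eta, v> + <lam, J v> = 0 for all v:  (w*eta) + J^T (w*lam) = 0
        y = np.linalg.solve(J.T, -(w * pack(eta1, eta2)))
        lam = y / w
        return unpack(lam, nv, no)


def dense_cc3_reference(sys: MOSystem, conv: float = 1e-11, triples: bool = True):
    """Convenience constructor for :class:`DenseCC3Reference`."""
    return DenseCC3Reference(sys, conv=conv, triples=triples)


# ---------------------------------------------------------------------------
# dense densities (full-tensor evaluation of the frozen term lists)
# ---------------------------------------------------------------------------

from ._equations import DENSITY_GS, DENSITY_TDM


def _undress_dense(no, n, Dhat, t1):
    A = np.eye(n)
    A[no:, :no] -= t1
    B = np.eye(n)
    B[:no, no:] += t1.T
    return A.T @ Dhat @ B


def _density_blocks(terms_by_block, ops, no, n):
    D = np.zeros((n, n))
    SL = {"oo": (slice(0, no), slice(0, no)), "vv": (slice(no, n), slice(no, n)),
          "ov": (slice(0, no), slice(no, n)), "vo": (slice(no, n), slice(0, no))}
    for block, terms in terms_by_block.items():
        for coef, spec, names in terms:
            res = coef * contract(spec, *(ops[nm] for nm in names))
            out = spec.split("->")[1]
            if out == "":
                nb = no if block == "oo" else n - no
                res = float(res) * np.eye(nb)
            else:
                idx = tuple(slice(no, n) if c in "ab" else slice(0, no) for c in out)
                res = res[idx]
            D[SL[block]] += res
    return D


def dense_lambda_density(ham, t1, t2, l1, l2, omega=0.0, with_reference=True):
    """Unblocked D^{00}-type (or D^{m0} with a left eigenvector) density."""
    no, n = ham.n_occ, ham.n_orb
    tau3 = dense_tau3(ham, t2)
    l3 = dense_l3(ham, l1, l2, omega=omega)
    ops = {
        "t2": _pad(t2, "vovo", no, n), "t3": _pad(tau3, "vovovo", no, n),
        "l1": _pad(l1, "vo", no, n), "l2": _pad(l2, "vovo", no, n),
        "l3": _pad(l3, "vovovo", no, n),
    }
    Dhat = _density_blocks(DENSITY_GS, ops, no, n)
    if with_reference:
        Dhat[:no, :no] += 2.0 * np.eye(no)
    return _undress_dense(no, n, Dhat, t1)


def dense_left_transition_density(ham, t1, t2, l1, l2, r1, r2, omega_r,
                                  ref_weight=0.0, D00=None):
    """Unblocked D~^{0m} from the frozen term lists (full tensors)."""
    no, n = ham.n_occ, ham.n_orb
    tau3 = dense_tau3(ham, t2)
    lam3 = dense_l3(ham, l1, l2, omega=0.0)
    _, dg, _ = dressing_derivative(ham, r1)
    r3 = dense_tau3(ham, r2, omega=omega_r) + dense_tau3(ham, t2, g=dg, omega=omega_r)
    ops = {
        "t2": _pad(t2, "vovo", no, n), "t3": _pad(tau3, "vovovo", no, n),
        "l1": _pad(l1, "vo", no, n), "l2": _pad(l2, "vovo", no, n),
        "l3": _pad(lam3, "vovovo", no, n),
        "r1": _pad(r1, "vo", no, n), "r2": _pad(r2, "vovo", no, n),
        "r3": _pad(r3, "vovovo", no, n), "r1t": _pad(r1.T, "ov", no, n),
    }
    Dhat = _density_blocks(DENSITY_TDM, ops, no, n)
    D = _undress_dense(no, n, Dhat, t1)
    if ref_weight and D00 is not None:
        D = D + ref_weight * D00
    return D
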