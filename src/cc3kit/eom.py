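"""EOM-CC3: Jacobian transforms, Davidson eigensolver, multipliers, CVS.

The CC3 Jacobian is applied matrix-free.  Its action on a trial vector
``(r1, r2)`` is the exact linearization of the ground-state residual with
one modification: the response-triples denominators are shifted by the
excitation energy, ``R3 = -(eps3 - omega)^{-1} [W(r2, g) + W(t2, dg[r1])]``.
The implementation follows a two-loop structure:

* a preparation step (:func:`prepare_jacobian_intermediates`) contracts the
  ground-state triples with integrals in one restricted sweep into
  intermediates no larger than doubles, shared by the right and the
  transpose transformation;
* per transform, loop 1 reconstructs the ground-state triples blocks and
  contracts them with r1-dressed integral slices; loop 2 builds the response
  triples blocks (the tau3 routine called twice with different inputs) and
  contracts them with ground-state integrals, giving 8 nV^4 nO^3 FLOP per
  application -- twice the ground-state residual.

The transpose transformation is coded as the exact adjoint (under the
full-sum pairing) of every right-transform contraction: the left triples
block is assembled covariantly from the coupling adjoints (contractions plus
outer products with the singles), mapped by the contravariant combination
where the right path used it, divided by the shifted denominators, and fed
through the adjoint of the triples constructor.  One accumulated gradient is
of nV^3 nO size; its final contraction against the four-virtual integrals
can optionally run through Cholesky factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _equations as eq
from ._packing import DIIS, pack, unpack
from .contractions import contract
from .ground import (
    CONTRAVARIANT_COEFFS,
    VVOV_COLLAPSE,
    _PERMS3,
    Amplitudes,
    DenominatorBlock,
    ReorderedIntegrals,
    _block_orderings,
    build_t3_block,
    occupied_triples,
    triples_denominator,
)
from .integrals import T1Hamiltonian

__all__ = [
    "ExcitationVector",
    "MultiplierVector",
    "EtaVector",
    "JacobianIntermediates",
    "EigenSolution",
    "prepare_jacobian_intermediates",
    "jacobian_transform_right",
    "jacobian_transform_left",
    "eta_vector",
    "solve_multipliers",
    "davidson_solve",
    "solve_excited_states",
    "solve_left_states",
    "cvs_project",
    "excitation_overlap",
]

def _apply_perm_comb(x, coeffs):
    return sum(c * np.transpose(x, p) for c, p in zip(coeffs, _PERMS3) if c != 0.0)


def _apply_perm_comb_T(x, coeffs):
    """Adjoint of :func:`_apply_perm_comb`: same coefficients at the inverse
    permutations."""
    return sum(
        c * np.transpose(x, tuple(int(v) for v in np.argsort(p)))
        for c, p in zip(coeffs, _PERMS3)
        if c != 0.0
    )


@dataclass
class ExcitationVector:
    """EOM vector: reference weight plus singles/doubles amplitude blocks.

    The right ground state has ``ref_weight = 1`` and zero blocks; excited
    right vectors carry a weight fixed by biorthogonality against the left
    ground state, excited left vectors have zero weight.
    """

    x1: np.ndarray
    x2: np.ndarray
    side: str = "right"
    ref_weight: float = 0.0
    omega: float | None = None

    def copy(self):
        return ExcitationVector(
            self.x1.copy(), self.x2.copy(), self.side, self.ref_weight, self.omega
        )


@dataclass
class MultiplierVector:
    lambda1: np.ndarray
    lambda2: np.ndarray


@dataclass
class EtaVector:
    eta1: np.ndarray
    eta2: np.ndarray


@dataclass
class EigenSolution:
    omegas: np.ndarray
    vectors: list
    iterations: list
    residual_norms: list


# ---------------------------------------------------------------------------
# r1-dressed integral slices
# ---------------------------------------------------------------------------


class DressedDirections:
    """Blocks of d(g~)/dt1 . r1 consumed by the transforms.

    Only annihilation axes taking occupied values and creation axes taking
    virtual values respond to the dressing, so every block is one cheap
    contraction of r1 with a dressed integral block.
    """

    def __init__(self, ham: T1Hamiltonian, r1: np.ndarray):
        no, n = ham.n_occ, ham.n_orb
        g = ham.g
        o, v = slice(0, no), slice(no, n)
        self.r1 = r1
        # seeds of the response-triples construction
        g_vvvo = (
            -contract("bm,mdck->bdck", r1, g[o, v, v, o])
            - contract("cm,bdmk->bdck", r1, g[v, v, o, o])
            + contract("ek,bdce->bdck", r1, g[v, v, v, v])
        )
        self.g_vvvo = g_vvvo
        self.gvvv = np.ascontiguousarray(g_vvvo.transpose(3, 1, 0, 2))
        self.g_vooo = (
            -contract("cm,mklj->cklj", r1, g[o, o, o, o])
            + contract("ek,celj->cklj", r1, g[v, v, o, o])
            + contract("ej,ckle->cklj", r1, g[v, o, o, v])
        )
        # loop-1 coupling slices
        g_ovov = g[o, v, o, v]
        self.f_ov = 2.0 * contract("el,kcle->kc", r1, g_ovov) - contract(
            "el,kelc->kc", r1, g_ovov
        )
        self.g_ooov = contract("ej,kelc->kjlc", r1, g_ovov)
        self.g_ovoo = contract("ej,kcle->kclj", r1, g_ovov)

    def seeds_integrals(self) -> ReorderedIntegrals:
        ints = ReorderedIntegrals.__new__(ReorderedIntegrals)
        ints.gvvv = self.gvvv
        ints.g_vooo = self.g_vooo
        return ints


# ---------------------------------------------------------------------------
# precomputed Jacobian intermediates
# ---------------------------------------------------------------------------


@dataclass
class JacobianIntermediates:
    """Ground-triples-contracted tensors built once before the iterations.

    ``Z`` holds one (nv, no, no, no) tensor per vvvo-type coupling channel
    (no stored tensor exceeds doubles size); the same intermediates serve
    both the right and the transpose transformation.
    """

    Z: np.ndarray
    core_occ: tuple = ()
    ccsd_cache: dict = None

    def r1_coupling(self, r1: np.ndarray) -> np.ndarray:
        za, zb, zc = self.Z
        z = -2.0 * za + zb + zc
        return contract("bm,aijm->aibj", r1, z)

    def r1_coupling_adjoint(self, u2: np.ndarray) -> np.ndarray:
        za, zb, zc = self.Z
        z = -2.0 * za + zb + zc
        return 2.0 * contract("aibj,aijm->bm", u2, z)


def prepare_jacobian_intermediates(
    ham: T1Hamiltonian, amps: Amplitudes, core_occ=None
) -> JacobianIntermediates:
    """One restricted triples sweep contracting tau3 with ovov integrals.

    Channels (matching the vvvo-type couplings of the working equations):
    Z_A/Z_B from tau3[a,i,c,j,d,k] with g[m,c,k,d] / g[m,d,k,c], and Z_C
    from tau3[a,k,c,i,d,j] with g[m,d,k,c].
    """
    no, nv = ham.n_occ, ham.n_virt
    ints = ReorderedIntegrals.from_ham(ham)
    Z = np.zeros((3, nv, no, no, no))
    if no >= 2:
        for ijk in occupied_triples(no, core_occ):
            denom = triples_denominator(ham.eps, ijk, no)
            blk = build_t3_block(ham, amps.t2, ijk, denom, ints=ints)
            for (o1, o2, o3), axperm in _block_orderings(ijk):
                Wp = np.transpose(blk.W, axperm)
                gs = ints.g_ovov[:, :, o3, :]  # (m, c, d)
                Z[0, :, o1, o2, :] += contract("acd,mcd->am", Wp, gs)
                Z[1, :, o1, o2, :] += contract("acd,mdc->am", Wp, gs)
                gs1 = ints.g_ovov[:, :, o1, :]
                Z[2, :, o2, o3, :] += contract("acd,mdc->am", Wp, gs1)
    return JacobianIntermediates(Z=Z, core_occ=tuple(core_occ or ()), ccsd_cache={})


# ---------------------------------------------------------------------------
# CCSD-part linearization and its adjoint
# ---------------------------------------------------------------------------


def _slice_int(arr, letters, no, n):
    idx = tuple(slice(no, n) if c in "abcde" else slice(0, no) for c in letters)
    return arr[idx]


def _lin_operand(name, letters, ops, no, n):
    if name == "t2":
        return ops[name]
    return _slice_int(ops[name], letters, no, n)


def _dg_axis_variants(gspec):
    """Axis decomposition of the r1-dressing derivative of one integral block.

    Creation axes respond only for virtual letters (``-r1[L, z] g[.. z ..]``
    with z occupied), annihilation axes only for occupied letters
    (``+r1[z, L] g[.. z ..]`` with z virtual).
    """
    out = []
    for k, L in enumerate(gspec):
        if k in (0, 2) and L in "abcde":
            out.append((-1.0, L + "z", gspec[:k] + "z" + gspec[k + 1:], "o"))
        elif k in (1, 3) and L in "ijklm":
            out.append((1.0, "z" + L, gspec[:k] + "z" + gspec[k + 1:], "v"))
    return out


def _slice_z(arr, letters, no, n, ztype):
    idx = tuple(
        slice(no, n) if (c in "abcde" or (c == "z" and ztype == "v"))
        else slice(0, no)
        for c in letters
    )
    return arr[idx]


def _letters_needed(cands, *needed):
    keep = "".join(needed)
    return "".join(ch for ch in dict.fromkeys(cands) if ch in keep)


def _lin_terms(terms, ops, dops, no, n, r1=None, pair_sym=False, cache=None):
    """Directional derivative of a frozen term list.

    Amplitude directions replace their operand directly; the integral
    direction is expanded axis-by-axis so that the trial singles are
    contracted last (no dressed-derivative integrals are materialized).
    Ground-only inner contractions are cached across calls.
    """
    g = ops["g"]
    total = None

    def acc(x, c):
        nonlocal total
        x = c * x
        total = x if total is None else total + x

    for coef, spec, names in terms:
        ins, out = spec.split("->")
        parts = ins.split(",")
        for pos, nm in enumerate(names):
            if nm == "F":
                arrs = [
                    _lin_operand(n2, p, dops if k == pos else ops, no, n)
                    for k, (n2, p) in enumerate(zip(names, parts))
                ]
                acc(contract(spec, *arrs), coef)
            elif nm != "g":
                # amplitude direction
                arrs = [
                    _lin_operand(n2, p, dops if k == pos else ops, no, n)
                    for k, (n2, p) in enumerate(zip(names, parts))
                ]
                if len(parts) == 2:
                    acc(contract(spec, *arrs), coef)
                else:
                    a, b, gspec = parts
                    inner_out = _letters_needed(b + gspec, a, out)
                    if pos == 0:
                        key = ("amp0", spec)
                        if cache is not None and key in cache:
                            inner = cache[key]
                        else:
                            inner = contract(f"{b},{gspec}->{inner_out}", arrs[1], arrs[2])
                            if cache is not None:
                                cache[key] = inner
                    else:
                        inner = contract(f"{b},{gspec}->{inner_out}", arrs[1], arrs[2])
                    acc(contract(f"{a},{inner_out}->{out}", arrs[0], inner), coef)
            else:
                # integral direction: axis expansion, r1 contracted last
                gspec = parts[pos]
                amp_parts = [(k, p) for k, p in enumerate(parts) if k != pos]
                for sign, r1spec, gvar, ztype in _dg_axis_variants(gspec):
                    gv = _slice_z(g, gvar, no, n, ztype)
                    if len(amp_parts) == 1:
                        pA = amp_parts[0][1]
                        mid = _letters_needed(pA + gvar, out, r1spec)
                        key = ("dg1", spec, r1spec)
                        if cache is not None and key in cache:
                            X = cache[key]
                        else:
                            X = contract(f"{pA},{gvar}->{mid}", ops[names[amp_parts[0][0]]], gv)
                            if cache is not None:
                                cache[key] = X
                        acc(contract(f"{mid},{r1spec}->{out}", X, r1), sign * coef)
                    else:
                        (ka, pA), (kb, pB) = amp_parts
                        innr = _letters_needed(pB + gvar, pA, out, r1spec)
                        key = ("dg2", spec, r1spec)
                        if cache is not None and key in cache:
                            inner = cache[key]
                        else:
                            inner = contract(f"{pB},{gvar}->{innr}", ops[names[kb]], gv)
                            if cache is not None:
                                cache[key] = inner
                        mid = _letters_needed(pA + innr, out, r1spec)
                        tmp = contract(f"{pA},{innr}->{mid}", ops[names[ka]], inner)
                        acc(contract(f"{mid},{r1spec}->{out}", tmp, r1), sign * coef)
    if pair_sym:
        total = total + total.transpose(2, 3, 0, 1)
    return total


def dressing_direction_blocks(ham, r1):
    """(dg_vovo, dF): the only materialized dressing-derivative pieces."""
    no, n = ham.n_occ, ham.n_orb
    g, h = ham.g, ham.h
    o, v = slice(0, no), slice(no, n)
    dg_vovo = (
        -contract("am,mibj->aibj", r1, g[o, o, v, o])
        + contract("ei,aebj->aibj", r1, g[v, v, v, o])
        - contract("bm,aimj->aibj", r1, g[v, o, o, o])
        + contract("ej,aibe->aibj", r1, g[v, o, v, v])
    )
    R = np.zeros((n, n), dtype=r1.dtype)
    R[no:, :no] = r1
    # the p/q axis responses of the dressed Fock collapse to a commutator
    dF = ham.fock @ R - R @ ham.fock
    dF += 2.0 * contract("ei,pqie->pq", r1, g[:, :, o, v])
    dF -= contract("ei,peiq->pq", r1, g[:, v, o, :])
    return dg_vovo, dF


def _ccsd_linearized(ham, t2, r2, dg_vovo, dF, r1, cache=None):
    no, n = ham.n_occ, ham.n_orb
    ops = {"t2": t2, "g": ham.g, "F": ham.fock}
    dops = {"t2": r2, "F": dF}
    s1 = dF[no:, :no].copy()
    s2 = dg_vovo.copy()
    s1 += _lin_terms(eq.OMEGA1_LIN, ops, dops, no, n, r1=r1, cache=cache)
    s2 += _lin_terms(eq.OMEGA2_LIN, ops, dops, no, n, r1=r1, pair_sym=True, cache=cache)
    s2 += _lin_terms(eq.OMEGA2_QUAD, ops, dops, no, n, r1=r1, pair_sym=True, cache=cache)
    return s1, s2


def _ccsd_linearized_adjoint(ham, t2, u1, u2):
    """Adjoint of the CCSD-part linearization under the full-sum pairing.

    Returns ``(v1, v2)``; the t1 component is assembled from the accumulated
    integral gradients through the adjoint of the dressing derivative.
    """
    no, n = ham.n_occ, ham.n_orb
    ops = {"t2": t2, "g": ham.g, "F": ham.fock}
    v2 = np.zeros_like(t2)
    Gg = np.zeros_like(ham.g)
    GF = np.zeros_like(ham.fock)
    GF[no:, :no] += u1
    Gg[no:, :no, no:, :no] += u2
    for terms, u, w in (
        (eq.OMEGA1_LIN, u1, 1.0),
        (eq.OMEGA2_LIN, u2, 2.0),
        (eq.OMEGA2_QUAD, u2, 2.0),
    ):
        for coef, spec, names in terms:
            ins, out = spec.split("->")
            parts = ins.split(",")
            for pos, nm in enumerate(names):
                others = [(p, names[k]) for k, p in enumerate(parts) if k != pos]
                tgt = parts[pos]
                if len(others) == 1:
                    p1, n1 = others[0]
                    grad = contract(
                        f"{out},{p1}->{tgt}", u, _lin_operand(n1, p1, ops, no, n)
                    )
                else:
                    # contract the output gradient through one partner, then
                    # the other; pick the order with the smaller intermediate
                    (pa, na), (pb, nb) = others
                    def mid_of(p1, p2):
                        return "".join(
                            ch for ch in dict.fromkeys(out + p1)
                            if ch in p2 or ch in tgt
                        )
                    if len(mid_of(pb, pa)) < len(mid_of(pa, pb)):
                        (pa, na), (pb, nb) = (pb, nb), (pa, na)
                    mid = mid_of(pa, pb)
                    tmp = contract(
                        f"{out},{pa}->{mid}", u, _lin_operand(na, pa, ops, no, n)
                    )
                    grad = contract(
                        f"{mid},{pb}->{tgt}", tmp, _lin_operand(nb, pb, ops, no, n)
                    )
                grad = coef * w * grad
                if nm == "t2":
                    v2 += grad
                else:
                    G = Gg if nm == "g" else GF
                    idx = tuple(
                        slice(no, n) if c in "abcde" else slice(0, no) for c in tgt
                    )
                    G[idx] += grad
    Gh = GF.copy()
    for i in range(no):
        Gg[:, :, i, i] += 2.0 * GF
        Gg[:, i, i, :] -= GF
    v1 = _dressing_adjoint_vo(ham, Gh, Gg)
    v2b = 0.5 * (v2 + v2.transpose(2, 3, 0, 1))
    return v1, v2b


def _dressing_adjoint_vo(ham: T1Hamiltonian, Gh, Gg):
    """Gradient w.r.t. t1 of <G, dressed integrals> (vo block only)."""
    no, n = ham.n_occ, ham.n_orb
    h, g = ham.h, ham.g
    M = (h.T @ Gh - Gh @ h.T)[no:, :no]
    M -= contract("aqrs,mqrs->am", Gg[no:], g[:no])
    M += contract("pmrs,pars->am", Gg[:, :no], g[:, no:])
    M -= contract("pqas,pqms->am", Gg[:, :, no:], g[:, :, :no])
    M += contract("pqrm,pqra->am", Gg[:, :, :, :no], g[:, :, :, no:])
    return M


# ---------------------------------------------------------------------------
# blocked triples couplings (shared by ground residual and transforms)
# ---------------------------------------------------------------------------


def _couple_block(W, ijk, ints, om1, om2x, f_ov=None, g_ooov=None, g_ovoo=None,
                  vvov=True):
    """Triples contributions of one block, optionally with overridden
    (r1-dressed) coupling slices; ``om2x`` is unsymmetrized."""
    f_ov = ints.f_ov if f_ov is None else f_ov
    g_ooov = ints.g_ooov if g_ooov is None else g_ooov
    g_ovoo = ints.g_ovoo if g_ovoo is None else g_ovoo
    if om1 is not None:
        Wt = _apply_perm_comb(W, CONTRAVARIANT_COEFFS)
    for (o1, o2, o3), axperm in _block_orderings(ijk):
        Wp = np.transpose(W, axperm)
        if om1 is not None:
            om1[:, o1] += 0.5 * contract(
                "acd,cd->a", np.transpose(Wt, axperm), ints.g_ovov[o2, :, o3, :]
            )
        om2x[:, o1, :, o2] += contract("abc,c->ab", Wp, f_ov[o3])
        om2x[:, o1, :, o3] -= contract("abc,c->ab", Wp, f_ov[o2])
        om2x[:, o1, :, :] += -2.0 * contract("abc,jc->abj", Wp, g_ooov[o2, :, o3, :])
        om2x[:, o1, :, :] += contract("abc,cj->abj", Wp, g_ovoo[o2, :, o3, :])
        om2x[:, o3, :, :] += contract("abc,cj->abj", Wp, g_ovoo[o1, :, o2, :])
        if vvov:
            Ws = _apply_perm_comb(Wp, VVOV_COLLAPSE)
            om2x[:, o1, :, o2] += contract("acd,bdc->ab", Ws, ints.g_vvov[:, :, o3, :])


def _couple_block_adjoint(ijk, ints, u1, U2, omega_shift, eps3, all_perms=False):
    """Covariant left-triples block: adjoint of :func:`_couple_block`.

    Built from contractions with the doubles and six outer products with the
    singles, then divided by ``-(eps3 - omega)``.  With ``all_perms`` the sum
    runs over all six permutations (duplicates transposed differently); after
    division by six this reproduces the pair-symmetrized full-tensor left
    triples slice, which the biorthonormality pairing requires.
    """
    nv = ints.g_vvov.shape[0]
    G3 = np.zeros((nv, nv, nv))
    if all_perms:
        orderings = [(tuple(ijk[p] for p in perm), perm) for perm in _PERMS3]
    else:
        orderings = _block_orderings(ijk)
    for (o1, o2, o3), axperm in orderings:
        g3p = np.zeros_like(G3)
        if u1 is not None:
            outer = 0.5 * contract("a,cd->acd", u1[:, o1], ints.g_ovov[o2, :, o3, :])
            g3p += _apply_perm_comb(outer, CONTRAVARIANT_COEFFS)
        g3p += contract("ab,c->abc", U2[:, o1, :, o2], ints.f_ov[o3])
        g3p -= contract("ab,c->abc", U2[:, o1, :, o3], ints.f_ov[o2])
        g3p += -2.0 * contract("abj,jc->abc", U2[:, o1], ints.g_ooov[o2, :, o3, :])
        g3p += contract("abj,cj->abc", U2[:, o1], ints.g_ovoo[o2, :, o3, :])
        g3p += contract("abj,cj->abc", U2[:, o3], ints.g_ovoo[o1, :, o2, :])
        grad = contract("ab,bdc->acd", U2[:, o1, :, o2], ints.g_vvov[:, :, o3, :])
        g3p += _apply_perm_comb_T(grad, VVOV_COLLAPSE)
        inv = tuple(int(x) for x in np.argsort(axperm))
        G3 += np.transpose(g3p, inv)
    return -G3 / (eps3 - omega_shift)


def _w_adjoint_block(L3, ijk, t2, ints, v2, Ggvvv, Ggvooo):
    """Adjoint of the triples constructor for one block.

    Scatters the left-triples block into the doubles gradient (contractions
    with the particle/hole seed integrals) and accumulates the nV^3 nO-sized
    integral gradients for the t1 back-coupling.
    """
    occ = ijk
    for perm in _PERMS3:
        o = tuple(occ[p] for p in perm)
        S = np.transpose(L3, perm)
        v2[:, o[0], :, o[1]] += contract("xyz,dyz->xd", S, ints.gvvv[o[2]])
        v2[:, o[0], :, :] -= contract("xyz,zl->xyl", S, ints.g_vooo[:, o[2], :, o[1]])
        if Ggvvv is not None:
            Ggvvv[o[2]] += contract("xd,xyz->dyz", t2[:, o[0], :, o[1]], S)
            Ggvooo[:, o[2], :, o[1]] -= contract("xyl,xyz->zl", t2[:, o[0], :, :], S)


def _dressed_seed_adjoint(ham, Ggvvv, Ggvooo, cholesky=None):
    """t1 gradient from the accumulated seed-integral gradients.

    Adjoint of the r1-dressing of the triples seeds; the four-virtual
    contraction optionally runs through Cholesky factors of the dressed
    integrals instead of the stored vvvv block.
    """
    no, n = ham.n_occ, ham.n_orb
    g = ham.g
    o, v = slice(0, no), slice(no, n)
    # Ggvvv layout: [k][d, b, c] for dg_vvvo[b, d, c, k]
    Gvvvo = Ggvvv.transpose(2, 1, 3, 0)  # (b, d, c, k)
    v1 = -contract("bdck,mdck->bm", Gvvvo, g[o, v, v, o])
    v1 -= contract("bdck,bdmk->cm", Gvvvo, g[v, v, o, o])
    if cholesky is None:
        v1 += contract("bdck,bdce->ek", Gvvvo, g[v, v, v, v])
    else:
        for LJ in cholesky:
            X = contract("bdck,bd->ck", Gvvvo, LJ[v, v])
            v1 += contract("ck,ce->ek", X, LJ[v, v])
    v1 -= contract("cklj,mklj->cm", Ggvooo, g[o, o, o, o])
    v1 += contract("cklj,celj->ek", Ggvooo, g[v, v, o, o])
    v1 += contract("cklj,ckle->ej", Ggvooo, g[v, o, o, v])
    return v1


def _loop1_gradients_adjoint(ham, Gdf, Gooov, Govoo):
    no = ham.n_occ
    g_ovov = ham.g[:no, no:, :no, no:]
    v1 = 2.0 * contract("kc,kcle->el", Gdf, g_ovov) - contract(
        "kc,kelc->el", Gdf, g_ovov
    )
    v1 += contract("kjlc,kelc->ej", Gooov, g_ovov)
    v1 += contract("kclj,kcle->ej", Govoo, g_ovov)
    return v1


# ---------------------------------------------------------------------------
# the transforms
# ---------------------------------------------------------------------------


def jacobian_transform_right(
    ham: T1Hamiltonian,
    amps: Amplitudes,
    inter: JacobianIntermediates | None,
    v: ExcitationVector,
    omega: float = 0.0,
    core_occ=None,
    triples: bool = True,
) -> ExcitationVector:
    """Apply the CC3 Jacobian J(omega) to a right trial vector."""
    if v.side != "right":
        raise ValueError("expected a right-side trial vector")
    no, nv = ham.n_occ, ham.n_virt
    if v.x1.shape != (nv, no):
        raise ValueError("trial vector dimensions do not match the Hamiltonian")
    r1, r2 = v.x1, v.x2
    dg_vovo, dF = dressing_direction_blocks(ham, r1)
    cache = inter.ccsd_cache if inter is not None else None
    s1, s2 = _ccsd_linearized(ham, amps.t2, r2, dg_vovo, dF, r1, cache=cache)
    if triples and no >= 2:
        ints = ReorderedIntegrals.from_ham(ham)
        d = DressedDirections(ham, r1)
        s2x = np.zeros_like(s2)
        if inter is not None:
            s2x += inter.r1_coupling(r1)
        # loop 1: rebuild tau3, contract with r1-dressed coupling slices
        if inter is None:
            # slow path without preparation: vvvo channel done in the loop
            dg_vvov = -contract("bm,mckd->bckd", r1, ints.g_ovov)
        for ijk in occupied_triples(no, core_occ):
            denom = triples_denominator(ham.eps, ijk, no)
            blk = build_t3_block(ham, amps.t2, ijk, denom, ints=ints)
            _couple_block(blk.W, ijk, ints, None, s2x, f_ov=d.f_ov,
                          g_ooov=d.g_ooov, g_ovoo=d.g_ovoo, vvov=False)
            if inter is None:
                _couple_vvov_dressed(blk.W, ijk, dg_vvov, s2x)
        # loop 2: response triples blocks, contracted with ground integrals
        dints = d.seeds_integrals()
        sx1 = np.zeros_like(s1)
        for ijk in occupied_triples(no, core_occ):
            denom = triples_denominator(ham.eps, ijk, no)
            b1 = build_t3_block(None, r2, ijk, denom, ints=ints, omega=omega)
            b2 = build_t3_block(None, amps.t2, ijk, denom, ints=dints, omega=omega)
            _couple_block(b1.W + b2.W, ijk, ints, sx1, s2x)
        s1 = s1 + sx1
        s2 = s2 + s2x + s2x.transpose(2, 3, 0, 1)
    out = ExcitationVector(s1, s2, side="right", omega=omega)
    if core_occ:
        out = cvs_project(out, core_occ)
    return out


def _couple_vvov_dressed(W, ijk, dg_vvov, om2x):
    """vvvo-type coupling contracted directly with r1-dressed integrals.

    Slow path used when no preparation intermediates are supplied; the
    two-path equivalence with the precomputed route is tested.
    """
    for (o1, o2, o3), axperm in _block_orderings(ijk):
        Wp = np.transpose(W, axperm)
        sl = dg_vvov[:, :, o3, :]
        om2x[:, o1, :, o2] += 2.0 * contract("acd,bcd->ab", Wp, sl)
        om2x[:, o1, :, o2] -= contract("acd,bdc->ab", Wp, sl)
    for (o1, o2, o3), axperm in _block_orderings(ijk):
        Wp = np.transpose(W, axperm)
        om2x[:, o2, :, o3] -= contract(
            "acd,bdc->ab", Wp, dg_vvov[:, :, o1, :]
        )


def jacobian_transform_left(
    ham: T1Hamiltonian,
    amps: Amplitudes,
    inter: JacobianIntermediates | None,
    v: ExcitationVector,
    omega: float = 0.0,
    core_occ=None,
    cholesky=None,
    triples: bool = True,
) -> ExcitationVector:
    """Apply the transpose Jacobian J(omega)^T to a left trial vector."""
    if v.side != "left":
        raise ValueError("expected a left-side trial vector")
    no, nv = ham.n_occ, ham.n_virt
    u1, u2 = v.x1, v.x2
    v1, v2 = _ccsd_linearized_adjoint(ham, amps.t2, u1, u2)
    if triples and no >= 2:
        ints = ReorderedIntegrals.from_ham(ham)
        U2 = 2.0 * u2
        if inter is not None:
            v1 = v1 + inter.r1_coupling_adjoint(u2)
        # loop 1 adjoint: rebuild tau3, accumulate coupling-slice gradients
        Gdf = np.zeros((no, nv))
        Gooov = np.zeros((no, no, no, nv))
        Govoo = np.zeros((no, nv, no, no))
        for ijk in occupied_triples(no, core_occ):
            denom = triples_denominator(ham.eps, ijk, no)
            blk = build_t3_block(ham, amps.t2, ijk, denom, ints=ints)
            for (o1, o2, o3), axperm in _block_orderings(ijk):
                Wp = np.transpose(blk.W, axperm)
                Gdf[o3] += contract("abc,ab->c", Wp, U2[:, o1, :, o2])
                Gdf[o2] -= contract("abc,ab->c", Wp, U2[:, o1, :, o3])
                Gooov[o2, :, o3, :] += -2.0 * contract("abc,abj->jc", Wp, U2[:, o1])
                Govoo[o2, :, o3, :] += contract("abc,abj->cj", Wp, U2[:, o1])
                Govoo[o1, :, o2, :] += contract("abc,abj->cj", Wp, U2[:, o3])
        v1 = v1 + _loop1_gradients_adjoint(ham, Gdf, Gooov, Govoo)
        # loop 2 adjoint: left triples blocks through the seed adjoints
        v2g = np.zeros((nv, no, nv, no))
        Ggvvv = np.zeros((no, nv, nv, nv))
        Ggvooo = np.zeros((nv, no, no, no))
        for ijk in occupied_triples(no, core_occ):
            denom = triples_denominator(ham.eps, ijk, no)
            L3 = _couple_block_adjoint(ijk, ints, u1, U2, omega, denom.eps3)
            _w_adjoint_block(L3, ijk, amps.t2, ints, v2g, Ggvvv, Ggvooo)
        v1 = v1 + _dressed_seed_adjoint(ham, Ggvvv, Ggvooo, cholesky=cholesky)
        v2 = v2 + 0.5 * (v2g + v2g.transpose(2, 3, 0, 1))
    out = ExcitationVector(v1, v2, side="left", omega=omega)
    if core_occ:
        out = cvs_project(out, core_occ)
    return out


# ---------------------------------------------------------------------------
# eta vector and multipliers
# ---------------------------------------------------------------------------


def eta_vector(ham: T1Hamiltonian, amps: Amplitudes) -> EtaVector:
    """Gradient of the energy w.r.t. the amplitudes (full-sum pairing).

    The doubles part is the spin-adapted integral combination
    ``2 g_iajb - g_ibja``; the singles part flows through the adjoint of the
    T1 dressing of the reference and correlation energies.
    """
    no, n = ham.n_occ, ham.n_orb
    g_ovov = ham.g[:no, no:, :no, no:]
    eta2 = 2.0 * g_ovov - g_ovov.transpose(0, 3, 2, 1)
    eta2 = np.ascontiguousarray(eta2.transpose(1, 0, 3, 2))
    Gh = np.zeros((n, n))
    Gh[:no, :no] = 2.0 * np.eye(no)
    Gg = np.zeros((n,) * 4)
    for i in range(no):
        for j in range(no):
            Gg[i, i, j, j] += 2.0
            Gg[i, j, j, i] -= 1.0
    Gg[:no, no:, :no, no:] += 2.0 * contract("aibj->iajb", amps.t2)
    Gg[:no, no:, :no, no:] -= contract("aibj->ibja", amps.t2)
    eta1 = _dressing_adjoint_vo(ham, Gh, Gg)
    return EtaVector(eta1, eta2)


def solve_multipliers(
    ham: T1Hamiltonian,
    amps: Amplitudes,
    inter: JacobianIntermediates | None = None,
    conv: float = 1e-8,
    max_iter: int = 100,
) -> MultiplierVector:
    """Ground-state Lagrange multipliers from eta + lambda . J = 0.

    Preconditioned (orbital-energy-difference) linear iterations driven by
    the transpose Jacobian transformation at omega = 0, DIIS accelerated.
    """
    no, nv = ham.n_occ, ham.n_virt
    if inter is None:
        inter = prepare_jacobian_intermediates(ham, amps)
    eta = eta_vector(ham, amps)
    eo, ev = ham.eps[:no], ham.eps[no:]
    d1 = ev[:, None] - eo[None, :]
    d2 = d1[:, :, None, None] + d1[None, None, :, :]
    l1 = -eta.eta1 / d1
    l2 = -eta.eta2 / d2
    diis = DIIS()
    for it in range(max_iter):
        res = jacobian_transform_left(
            ham, amps, inter, ExcitationVector(l1, l2, side="left")
        )
        rho1 = eta.eta1 + res.x1
        rho2 = eta.eta2 + res.x2
        err = max(np.abs(rho1).max(), np.abs(rho2).max())
        if err < conv:
            return MultiplierVector(l1, l2)
        step1, step2 = -rho1 / d1, -rho2 / d2
        z = diis.update(pack(l1 + step1, l2 + step2), pack(step1, step2))
        l1, l2 = unpack(z, nv, no)
    raise RuntimeError(f"multiplier equations did not converge ({err:.2e})")


# ---------------------------------------------------------------------------
# CVS projection
# ---------------------------------------------------------------------------


def cvs_project(v: ExcitationVector, core_occ) -> ExcitationVector:
    """Zero every amplitude whose occupied indices contain no core orbital."""
    core = sorted(set(core_occ))
    no = v.x1.shape[1]
    if not core:
        raise ValueError("core_occ must be non-empty")
    if any(c < 0 or c >= no for c in core):
        raise IndexError("core orbital index outside the occupied range")
    mask1 = np.zeros(no, bool)
    mask1[core] = True
    x1 = np.where(mask1[None, :], v.x1, 0.0)
    m2 = mask1[None, :, None, None] | mask1[None, None, None, :]
    x2 = np.where(m2, v.x2, 0.0)
    return ExcitationVector(x1, x2, v.side, v.ref_weight, v.omega)


# ---------------------------------------------------------------------------
# Davidson eigensolver
# ---------------------------------------------------------------------------


def davidson_solve(
    transform,
    diag: np.ndarray,
    guesses,
    n_roots: int = 1,
    conv: float = 1e-4,
    max_space: int = 60,
    max_iter: int = 200,
    target: float | None = None,
):
    """Non-Hermitian Davidson with subspace collapse.

    ``transform`` maps a flat vector to a flat vector; ``diag`` is the
    preconditioner diagonal (orbital-energy differences).  Roots are homed by
    maximum overlap with the current Ritz vectors when ``target`` is given,
    otherwise the lowest eigenvalues are followed.  Returns
    ``(values, vectors, iterations, residual_norms)``.
    """
    dim = diag.size
    max_space = min(max_space, dim)
    V = []
    W = []
    for gss in guesses:
        _orthonormalize_into(V, gss)
    if not V:
        raise ValueError("no linearly independent start guesses")
    its = 0
    while its < max_iter:
        while len(W) < len(V):
            W.append(transform(V[len(W)]))
        its += 1
        Vm = np.array(V).T
        Wm = np.array(W).T
        H = Vm.T @ Wm
        vals, vecs = np.linalg.eig(H)
        order = np.argsort(vals.real)
        vals, vecs = vals[order].real, vecs[:, order].real
        if target is not None:
            sel = np.argsort(np.abs(vals - target))[:n_roots]
            sel = sel[np.argsort(vals[sel])]
        else:
            sel = np.arange(min(n_roots, len(vals)))
        ritz_vals = vals[sel]
        ritz_vecs = Vm @ vecs[:, sel]
        residuals = Wm @ vecs[:, sel] - ritz_vecs * ritz_vals[None, :]
        norms = np.linalg.norm(residuals, axis=0)
        if np.all(norms < conv):
            return ritz_vals, [ritz_vecs[:, m] for m in range(len(sel))], its, norms
        if len(V) >= max_space:
            # collapse onto the current Ritz vectors, then keep expanding
            V, W = [], []
            for m in range(len(sel)):
                _orthonormalize_into(V, ritz_vecs[:, m])
        added = False
        room = max_space - len(V)
        for m in range(len(sel)):
            if norms[m] < conv or room <= 0:
                continue
            precond = diag - ritz_vals[m]
            precond = np.where(np.abs(precond) < 1e-6, 1e-6, precond)
            if _orthonormalize_into(V, residuals[:, m] / precond):
                added = True
                room -= 1
        if not added:
            # subspace exhausted without new directions: accept if the
            # remaining residual is only slightly above the threshold
            if np.all(norms < 10 * conv):
                return ritz_vals, [ritz_vecs[:, m] for m in range(len(sel))], its, norms
            raise RuntimeError(
                f"Davidson stagnated at residuals {norms} (conv {conv})"
            )
    raise RuntimeError("Davidson did not converge")


def _orthonormalize_into(V, x, tol=1e-11):
    nx = np.linalg.norm(x)
    if nx <= 0.0:
        return False
    y = x / nx
    for _ in range(3):
        for b in V:
            y -= (b @ y) * b
        nrm = np.linalg.norm(y)
        if nrm < tol:
            return False
        y /= nrm
    V.append(y)
    return True


# ---------------------------------------------------------------------------
# excited-state driver (self-consistent omega folding)
# ---------------------------------------------------------------------------


def _flatten(x1, x2):
    """Packed symmetric coordinates (the Davidson working representation)."""
    return pack(x1, x2)


def _unflatten(z, nv, no):
    return unpack(z, nv, no)


def _jacobian_diag(ham):
    no, nv = ham.n_occ, ham.n_virt
    eo, ev = ham.eps[:no], ham.eps[no:]
    d1 = ev[:, None] - eo[None, :]
    d2 = d1[:, :, None, None] + d1[None, None, :, :]
    return pack(d1, d2)


def singles_guesses(ham, n_roots, core_occ=None):
    """Unit singles vectors on the lowest orbital-energy differences.

    If more roots are requested than singles exist, unit doubles on the
    lowest pair energy differences supplement the guess set.
    """
    no, nv = ham.n_occ, ham.n_virt
    eo, ev = ham.eps[:no], ham.eps[no:]
    d1 = (ev[:, None] - eo[None, :]).copy()
    if core_occ:
        mask = np.ones(no, bool)
        mask[list(core_occ)] = False
        d1[:, mask] = np.inf
    order = np.argsort(d1.ravel())
    out = []
    for idx in order[: min(n_roots, nv * no)]:
        x1 = np.zeros(nv * no)
        x1[idx] = 1.0
        out.append((x1.reshape(nv, no), np.zeros((nv, no, nv, no))))
    if len(out) < n_roots:
        d2 = d1[:, :, None, None] + d1[None, None, :, :]
        for idx in np.argsort(d2.ravel())[: n_roots - len(out)]:
            x2 = np.zeros((nv * no) ** 2)
            x2[idx] = 1.0
            x2 = x2.reshape(nv, no, nv, no)
            out.append((np.zeros((nv, no)), 0.5 * (x2 + x2.transpose(2, 3, 0, 1))))
    return out


def solve_excited_states(
    ham: T1Hamiltonian,
    amps: Amplitudes,
    inter: JacobianIntermediates,
    n_roots: int,
    side: str = "right",
    conv: float = 1e-4,
    core_occ=None,
    guesses=None,
    omega_tol: float | None = None,
    max_cycles: int = 50,
    buffer_roots: int = 2,
    fixed_omegas=None,
) -> EigenSolution:
    """Solve for EOM-CC3 eigenvectors with self-consistent energy folding.

    Because the folded triples carry the excitation energy in their
    denominators, each root m solves the nonlinear problem
    ``J(omega_m) x = omega_m x``.  Roots are obtained sequentially: an inner
    Davidson solve at fixed omega alternates with an omega update until the
    fixed point is reached (tolerance ``omega_tol``, default ``conv/10``).
    With ``fixed_omegas`` (used for left states) the folding energies are
    frozen at the supplied values so that left and right eigenpairs match.
    """
    no, nv = ham.n_occ, ham.n_virt
    omega_tol = conv * 0.1 if omega_tol is None else omega_tol
    diag = _jacobian_diag(ham)
    if core_occ:
        # push non-core components of the preconditioner/guesses away
        proj = cvs_project(
            ExcitationVector(np.ones((nv, no)), np.ones((nv, no, nv, no))), core_occ
        )
        mask = _flatten(proj.x1, proj.x2) == 0.0
    else:
        mask = None

    def make_op(omega):
        def op(z):
            x1, x2 = _unflatten(z, nv, no)
            vec = ExcitationVector(x1, x2, side=side)
            if core_occ:
                vec = cvs_project(vec, core_occ)
            if side == "right":
                res = jacobian_transform_right(
                    ham, amps, inter, vec, omega=omega, core_occ=core_occ
                )
            else:
                res = jacobian_transform_left(
                    ham, amps, inter, vec, omega=omega, core_occ=core_occ
                )
            out = _flatten(res.x1, res.x2)
            if mask is not None:
                out[mask] = 0.0
            return out

        return op

    n_seek = max(1, min(n_roots + buffer_roots, diag.size))
    if guesses == "ccsd":
        # restart from the singles/doubles (CCSD-level) eigenvectors
        def op0(z):
            x1, x2 = _unflatten(z, nv, no)
            vec = ExcitationVector(x1, x2, side=side)
            if core_occ:
                vec = cvs_project(vec, core_occ)
            fn = jacobian_transform_right if side == "right" else jacobian_transform_left
            res = fn(ham, amps, inter, vec, omega=0.0, core_occ=core_occ, triples=False)
            out = _flatten(res.x1, res.x2)
            if mask is not None:
                out[mask] = 0.0
            return out

        seeds = [_flatten(x1, x2) for (x1, x2) in singles_guesses(ham, n_seek, core_occ=core_occ)]
        if mask is not None:
            for s_ in seeds:
                s_[mask] = 0.0
        _, vecs0c, *_ = davidson_solve(op0, diag, seeds, n_roots=n_seek, conv=1e-4)
        guesses = [(x1, x2) for x1, x2 in (_unflatten(z, nv, no) for z in vecs0c)]
    if guesses is None:
        guesses = singles_guesses(ham, n_seek, core_occ=core_occ)
    flat_guesses = [_flatten(x1, x2) for (x1, x2) in guesses]
    if mask is not None:
        for gss in flat_guesses:
            gss[mask] = 0.0

    # initial spectrum at omega = 0 to seed the per-root folding
    vals0, vecs0, *_ = davidson_solve(
        make_op(0.0), diag, flat_guesses, n_roots=n_seek, conv=max(conv, 1e-3)
    )
    n_seek = min(n_seek, len(vals0))
    roots = []
    for m in range(n_seek):
        omega = float(vals0[m]) if fixed_omegas is None else float(fixed_omegas[m])
        x = vecs0[m]
        n_it = 0
        for cycle in range(max_cycles):
            op = make_op(omega)
            vals, vecs, its, norms = davidson_solve(
                op, diag, [x] + flat_guesses, n_roots=1, conv=conv, target=omega
            )
            n_it += its
            x = vecs[0]
            if fixed_omegas is not None:
                resnorm = norms[0]
                break
            if abs(vals[0] - omega) < omega_tol:
                omega = float(vals[0])
                resnorm = norms[0]
                break
            omega = float(vals[0])
        else:
            raise RuntimeError(f"omega self-consistency not reached for root {m}")
        x1, x2 = _unflatten(x, nv, no)
        # tie-break bookkeeping: energy then singles weight
        roots.append((omega, ExcitationVector(x1, x2, side=side, omega=omega),
                      n_it, resnorm))
    roots.sort(key=lambda r: (round(r[0], 10), -float(np.sum(r[1].x1 ** 2))))
    # deduplicate collapsed roots by vector overlap
    uniq = []
    for r in roots:
        dup = False
        for q in uniq:
            ov = abs(_flatten(r[1].x1, r[1].x2) @ _flatten(q[1].x1, q[1].x2))
            nr = np.linalg.norm(_flatten(r[1].x1, r[1].x2))
            nq = np.linalg.norm(_flatten(q[1].x1, q[1].x2))
            if ov > 0.98 * nr * nq and abs(r[0] - q[0]) < 1e-6:
                dup = True
                break
        if not dup:
            uniq.append(r)
    uniq = uniq[:n_roots]
    return EigenSolution(
        omegas=np.array([r[0] for r in uniq]),
        vectors=[r[1] for r in uniq],
        iterations=[r[2] for r in uniq],
        residual_norms=[r[3] for r in uniq],
    )


def solve_left_states(
    ham, amps, inter, right: EigenSolution, conv: float = 1e-4, core_occ=None
) -> EigenSolution:
    """Left eigenvectors at the energies of the converged right states."""
    return solve_excited_states(
        ham,
        amps,
        inter,
        n_roots=len(right.omegas),
        side="left",
        conv=conv,
        core_occ=core_occ,
        fixed_omegas=right.omegas,
        buffer_roots=0,
    )


# ---------------------------------------------------------------------------
# biorthonormality with the folded triples sector
# ---------------------------------------------------------------------------


def excitation_overlap(
    ham: T1Hamiltonian,
    amps: Amplitudes,
    left: ExcitationVector,
    right: ExcitationVector,
    omega_left: float,
    omega_right: float,
    include_triples: bool = True,
) -> float:
    """<L, R> including the folded triples sector.

    The singles/doubles part is the full-sum pairing; the triples part pairs
    the folded left and response triples tensors, evaluated blockwise.
    """
    s = float(np.sum(left.x1 * right.x1) + np.sum(left.x2 * right.x2))
    no, nv = ham.n_occ, ham.n_virt
    if include_triples and no >= 2:
        ints = ReorderedIntegrals.from_ham(ham)
        d = DressedDirections(ham, right.x1)
        dints = d.seeds_integrals()
        U2 = 2.0 * left.x2
        ev = ham.eps[no:]
        blocks = list(occupied_triples(no)) + [(i, i, i) for i in range(no)]
        for ijk in blocks:
            i, j, k = ijk
            eps3 = (
                ev[:, None, None] + ev[None, :, None] + ev[None, None, :]
                - (ham.eps[i] + ham.eps[j] + ham.eps[k])
            )
            denom = DenominatorBlock(ijk=ijk, eps3=eps3)
            L3 = _couple_block_adjoint(
                ijk, ints, left.x1, U2, omega_left, eps3, all_perms=True
            ) / 6.0
            b1 = build_t3_block(None, right.x2, ijk, denom, ints=ints, omega=omega_right)
            b2 = build_t3_block(None, amps.t2, ijk, denom, ints=dints, omega=omega_right)
            R3 = b1.W + b2.W
            for (_, _, _), axperm in _block_orderings(ijk):
                s += float(
                    np.sum(np.transpose(L3, axperm) * np.transpose(R3, axperm))
                )
    return s
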