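"""EOM densities, oscillator strengths and broadened spectra.

Density matrices are assembled in the T1-dressed frame from the frozen
working equations and transformed back with the dressing matrices,
``D = A^T D^ B``.  Triples enter through folded tensors that are never
stored whole: contributions whose occupied indices coincide between the
left and right triples run in the restricted occupied triples loop, while
the occupied-occupied block pairs triples with one mismatched occupied
index and therefore needs an additional triple loop over the *virtual*
indices, holding (no, no, no) blocks for one virtual triple at a time.
One pair of mixed terms (occupied and virtual indices both mismatched) is
factorized through a doubles-sized intermediate in two blocked sweeps.

Two ground-state density variants exist:

* ``variant="eom"`` -- the biorthogonal expectation-value form
  <HF|(1 + Lambda) e^{-T} E_pq e^{T}|HF>, used for spectra;
* ``variant="response"`` -- the exact derivative of the CC3 energy.  It
  differs from the EOM form by one Lambda3-T2-T2 ov term and by the frame
  of the Lambda3-tau3 oo/vv blocks (they derive from the bare-Fock
  commutator and enter undressed); finite-field derivatives reproduce it
  with clean O(alpha^2) convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _equations as eq
from .contractions import contract
from .eom import (
    DressedDirections,
    ExcitationVector,
    MultiplierVector,
    _couple_block_adjoint,
    excitation_overlap,
)
from .ground import (
    Amplitudes,
    DenominatorBlock,
    ReorderedIntegrals,
    _PERMS3,
    _block_orderings,
    build_t3_block,
)
from .integrals import T1Hamiltonian

__all__ = [
    "DensityMatrix",
    "PropertyOperator",
    "SpectrumLine",
    "Spectrum",
    "ground_state_density",
    "right_transition_density",
    "left_transition_density",
    "transition_strength",
    "oscillator_strength",
    "lorentzian_spectrum",
    "HARTREE_TO_EV",
]

#: CODATA conversion pinned at the reporting boundary
HARTREE_TO_EV = 27.211386


@dataclass
class DensityMatrix:
    D: np.ndarray
    kind: str  # ground | right_transition | left_transition
    state_index: int = 0

    def trace(self) -> float:
        return float(np.trace(self.D))

    def expectation(self, A: np.ndarray) -> float:
        return float(np.sum(self.D * A))


@dataclass
class PropertyOperator:
    """Three Cartesian one-electron matrices in the MO basis (a.u.)."""

    components: np.ndarray  # (3, n, n)

    def __post_init__(self):
        a = np.asarray(self.components, float)
        if a.ndim != 3 or a.shape[0] != 3:
            raise ValueError("expected dipole components of shape (3, n, n)")
        self.components = a


@dataclass
class SpectrumLine:
    omega_ev: float
    f: float
    label: str = ""


@dataclass
class Spectrum:
    grid_ev: np.ndarray
    intensity: np.ndarray
    lines: list


# ---------------------------------------------------------------------------
# blocked triples helpers
# ---------------------------------------------------------------------------


def _sorted_triples(n):
    for i in range(n):
        for j in range(i + 1):
            for k in range(j + 1):
                yield (i, j, k)


def _eps3_occ(eps, no, ijk):
    ev = eps[no:]
    i, j, k = ijk
    return (
        ev[:, None, None] + ev[None, :, None] + ev[None, None, :]
        - (eps[i] + eps[j] + eps[k])
    )


def _eps3_virt(eps, no, abc):
    eo = eps[:no]
    ev = eps[no:]
    a, b, c = abc
    return (
        ev[a] + ev[b] + ev[c]
        - (eo[:, None, None] + eo[None, :, None] + eo[None, None, :])
    )


def _w_v_seeds(t2, g, no, va, vb, vc, g_dress=None):
    """Triples seeds for a fixed virtual triple over the occupied cube."""
    if g_dress is None:
        gv1 = g[no + vb, no:, no + vc, :no]  # (d, k)
        gv2 = g[no + vc, :no, :no, :no]  # (k, l, j)
    else:
        g_vvvo, g_vooo = g_dress
        gv1 = g_vvvo[vb, :, vc, :]
        gv2 = g_vooo[vc]
    s = contract("idj,dk->ijk", t2[va], gv1)
    s = s - contract("il,klj->ijk", t2[va, :, vb, :], gv2)
    return s


class _TriplesWork:
    """Blocked access to the folded triples tensors of a density evaluation."""

    def __init__(self, ham, amps, l1, l2, omega_l=0.0, r: ExcitationVector | None = None,
                 omega_r=0.0):
        self.ham, self.amps = ham, amps
        self.no, self.nv = ham.n_occ, ham.n_virt
        self.ints = ReorderedIntegrals.from_ham(ham)
        self.l1, self.l2, self.omega_l = l1, l2, omega_l
        self.U2 = 2.0 * l2
        self.r, self.omega_r = r, omega_r
        if r is not None:
            self.d = DressedDirections(ham, r.x1)
            self.dints = self.d.seeds_integrals()
        else:
            self.d = self.dints = None

    # occupied-blocked tensors -------------------------------------------------

    def l3_occ(self, ijk):
        eps3 = _eps3_occ(self.ham.eps, self.no, ijk)
        return _couple_block_adjoint(
            ijk, self.ints, self.l1, self.U2, self.omega_l, eps3, all_perms=True
        ) / 6.0

    def _t3_occ(self, ijk, response):
        denom = DenominatorBlock(ijk=ijk, eps3=_eps3_occ(self.ham.eps, self.no, ijk))
        if not response:
            return build_t3_block(self.ham, self.amps.t2, ijk, denom, ints=self.ints).W
        b1 = build_t3_block(None, self.r.x2, ijk, denom, ints=self.ints,
                            omega=self.omega_r)
        b2 = build_t3_block(None, self.amps.t2, ijk, denom, ints=self.dints,
                            omega=self.omega_r)
        return b1.W + b2.W

    def t3_occ(self, ijk):
        return self._t3_occ(ijk, False)

    def r3_occ(self, ijk):
        return self._t3_occ(ijk, True)

    # virtual-blocked tensors --------------------------------------------------

    def _t3_virt(self, abc, response):
        no, g = self.no, self.ham.g
        t2 = self.amps.t2
        W = None
        for perm in _PERMS3:
            v = tuple(abc[p] for p in perm)
            inv = tuple(int(x) for x in np.argsort(perm))
            if not response:
                s = _w_v_seeds(t2, g, no, *v)
            else:
                s = _w_v_seeds(self.r.x2, g, no, *v)
                s = s + _w_v_seeds(
                    t2, g, no, *v, g_dress=(self.d.g_vvvo, self.d.g_vooo)
                )
            W = np.transpose(s, inv) if W is None else W + np.transpose(s, inv)
        omega = 0.0 if not response else self.omega_r
        return -W / (_eps3_virt(self.ham.eps, self.no, abc) - omega)

    def t3_virt(self, abc):
        return self._t3_virt(abc, False)

    def r3_virt(self, abc):
        return self._t3_virt(abc, True)

    def l3_virt(self, abc):
        no, n = self.no, self.ham.n_orb
        ops = {"g": self.ham.g, "F": self.ham.fock}
        G = np.zeros((no, no, no))
        for perm in _PERMS3:
            v = tuple(abc[p] for p in perm)
            inv = tuple(int(x) for x in np.argsort(perm))
            G += np.transpose(_g3raw_v_slice(self.l1, self.U2, ops, v, no, n), inv)
        return -(G / 6.0) / (_eps3_virt(self.ham.eps, self.no, abc) - self.omega_l)


def _g3raw_v_slice(u1, U2, ops, v, no, n):
    """Raw coupling-adjoint slice at fixed virtual block coordinates ``v``."""
    out = np.zeros((no, no, no))
    for coef, spec, names in eq.COUPLING1:
        out += coef * _adj_slice(spec, u1, ops[names[1]], v, no, n, singles=True)
    for coef, spec, names in eq.COUPLING2:
        # U2 already carries the pair-symmetrization factor of two
        out += coef * _adj_slice(spec, U2, ops[names[1]], v, no, n, singles=False)
    return out


def _adj_slice(spec, u, op, v, no, n, singles):
    """Slice of ``einsum('out,gspec->t3spec', u, op)`` at fixed virtuals.

    Letters fixed by the virtual block substitute into both operands; any
    remaining virtual letter of the output is contracted with the integral.
    """
    ins, outspec = spec.split("->")
    t3spec, gspec = ins.split(",")
    fixed = dict(zip(t3spec[0::2], v))
    uidx, uspec = [], ""
    for ch in outspec:
        if ch in fixed:
            uidx.append(fixed[ch])  # u carries block-coordinate virtual axes
        else:
            uidx.append(slice(None))
            uspec += ch
    usl = u[tuple(uidx)]
    oidx, opspec = [], ""
    for ch in gspec:
        if ch in fixed:
            oidx.append(no + fixed[ch])
        else:
            oidx.append(slice(0, no) if ch in "ijklm" else slice(no, n))
            opspec += ch
    return contract(f"{uspec},{opspec}->{t3spec[1::2]}", usl, op[tuple(oidx)])


# ---------------------------------------------------------------------------
# density assembly
# ---------------------------------------------------------------------------


def _undress(ham: T1Hamiltonian, Dhat: np.ndarray, t1: np.ndarray) -> np.ndarray:
    no, n = ham.n_occ, ham.n_orb
    A = np.eye(n)
    A[no:, :no] -= t1
    B = np.eye(n)
    B[:no, no:] += t1.T
    return A.T @ Dhat @ B


def _lambda_density_parts(work: _TriplesWork):
    """Dressed-frame density of a left state (Lambda or L_m), in three parts.

    Returns ``(Dhat, Dtrip, Dov_l3)``: the singles/doubles part, the
    lambda3.tau3 oo/vv part (frame chosen by the caller) and the EOM-only
    lambda3.t2.t2 ov term.
    """
    ham, amps = work.ham, work.amps
    no, n = work.no, ham.n_orb
    l1, l2, t2 = work.l1, work.l2, amps.t2
    Dhat = np.zeros((n, n))
    Dtrip = np.zeros((n, n))
    Dov_l3 = np.zeros((n, n))

    Dhat[no:, :no] = l1
    Dhat[:no, :no] += -2.0 * contract("cjdk,cidk->ij", l2, t2)
    Dhat[no:, no:] += 2.0 * contract("akcl,bkcl->ab", l2, t2)
    Dhat[:no, no:] += 2.0 * contract("ck,aick->ia", l1, t2) - contract(
        "ck,akci->ia", l1, t2
    )
    if no < 2:
        return Dhat, Dtrip, Dov_l3

    # occupied-blocked loop
    for ijk in _sorted_triples(no):
        T3 = work.t3_occ(ijk)
        L3 = work.l3_occ(ijk)
        for (o1, o2, o3), axperm in _block_orderings(ijk):
            T3p = np.transpose(T3, axperm)
            L3p = np.transpose(L3, axperm)
            if not (o1 == o2 == o3):
                # l2 . tau3 -> ov (zero for i = j = k blocks by construction)
                Dhat[o1, no:] += 2.0 * contract("cd,acd->a", l2[:, o2, :, o3], T3p)
                Dhat[o2, no:] -= 2.0 * contract("cd,acd->a", l2[:, o1, :, o3], T3p)
            # vv block: 3 l3 . tau3 over shared occupied indices
            Dtrip[no:, no:] += 3.0 * contract("acd,bcd->ab", L3p, T3p)
            # EOM-only ov term: -6 l3[ckdlem] t2[akdl] t2[ciem]
            X = contract("cde,ad->cea", L3p, t2[:, o1, :, o2])
            Dov_l3[:no, no:] += -6.0 * contract("cea,cie->ia", X, t2[:, :, :, o3])
    # virtual-blocked loop: oo block needs one mismatched occupied index
    for abc in _sorted_triples(work.nv):
        T3v = work.t3_virt(abc)
        L3v = work.l3_virt(abc)
        for (_, _, _), axperm in _block_orderings(abc):
            Dtrip[:no, :no] += -3.0 * contract(
                "jkl,ikl->ij", np.transpose(L3v, axperm), np.transpose(T3v, axperm)
            )
    return Dhat, Dtrip, Dov_l3


def ground_state_density(
    ham: T1Hamiltonian,
    amps: Amplitudes,
    multipliers: MultiplierVector,
    variant: str = "eom",
) -> DensityMatrix:
    """CC3 ground-state one-particle density D^{00}.

    ``variant="eom"`` is the biorthogonal expectation value (used in the
    transition-density reuse); ``variant="response"`` is the exact energy
    derivative validated by finite-field differentiation.  Both trace to the
    electron count.
    """
    no = ham.n_occ
    work = _TriplesWork(ham, amps, multipliers.lambda1, multipliers.lambda2)
    Dhat, Dtrip, Dov_l3 = _lambda_density_parts(work)
    Dhat[:no, :no] += 2.0 * np.eye(no)
    if variant == "eom":
        D = _undress(ham, Dhat + Dtrip + Dov_l3, amps.t1)
    elif variant == "response":
        # the bare-Fock commutator terms enter in the undressed frame
        D = _undress(ham, Dhat, amps.t1) + Dtrip
    else:
        raise ValueError(f"unknown density variant {variant!r}")
    return DensityMatrix(D=D, kind="ground")


def right_transition_density(
    ham: T1Hamiltonian,
    amps: Amplitudes,
    L_m: ExcitationVector,
    omega: float,
    state_index: int = 0,
) -> DensityMatrix:
    """Right transition density D^{m0} from the left eigenvector of state m.

    Identical algorithm to the ground-state density with L_m in place of
    Lambda (and no reference contribution, since excited left vectors carry
    zero reference weight).
    """
    work = _TriplesWork(ham, amps, L_m.x1, L_m.x2, omega_l=omega)
    Dhat, Dtrip, Dov_l3 = _lambda_density_parts(work)
    D = _undress(ham, Dhat + Dtrip + Dov_l3, amps.t1)
    return DensityMatrix(D=D, kind="right_transition", state_index=state_index)


def left_transition_density(
    ham: T1Hamiltonian,
    amps: Amplitudes,
    multipliers: MultiplierVector,
    R_m: ExcitationVector,
    D00: DensityMatrix,
    omega: float,
    ref_weight: float | None = None,
    state_index: int = 0,
) -> DensityMatrix:
    """Left transition density D~^{0m}.

    Needs tau3, Lambda3 and the response triples R3 (roughly twice the cost
    of tau3); the reference-weight contribution reuses the ground-state
    density.
    """
    no, nv = ham.n_occ, ham.n_virt
    n = ham.n_orb
    l1, l2 = multipliers.lambda1, multipliers.lambda2
    t2 = amps.t2
    r1, r2 = R_m.x1, R_m.x2
    if ref_weight is None:
        ref_weight = R_m.ref_weight
    work = _TriplesWork(ham, amps, l1, l2, omega_l=0.0, r=R_m, omega_r=omega)

    Dhat = np.zeros((n, n))
    # reference part and the singles/doubles terms of the frozen list
    Dhat[:no, no:] += 2.0 * r1.T
    Dhat[:no, :no] += -contract("cj,ci->ij", l1, r1)
    Dhat[:no, :no] += 2.0 * float(np.sum(l1 * r1)) * np.eye(no)
    Dhat[:no, :no] += -2.0 * contract("cjdk,cidk->ij", l2, r2)
    Dhat[:no, :no] += 2.0 * float(np.sum(l2 * r2)) * np.eye(no)
    Dhat[no:, no:] += contract("ak,bk->ab", l1, r1)
    Dhat[no:, no:] += 2.0 * contract("akcl,bkcl->ab", l2, r2)
    Dhat[:no, no:] += 2.0 * contract("ck,aick->ia", l1, r2) - contract(
        "ck,akci->ia", l1, r2
    )
    Dhat[:no, no:] += (
        -2.0 * contract("ckdl,ci,akdl->ia", l2, r1, t2)
        - 2.0 * contract("ckdl,ak,cidl->ia", l2, r1, t2)
        + 4.0 * contract("ckdl,ck,aidl->ia", l2, r1, t2)
        - 2.0 * contract("ckdl,ck,aldi->ia", l2, r1, t2)
    )
    Dhat[no:, :no] += 2.0 * contract("aick,ck->ai", l2, r1)

    if no >= 2:
        trace_l3r3 = 0.0
        M = np.zeros((nv, no, nv, no))  # sum_ck l3[ckdlem] r1[ck] intermediate
        for ijk in _sorted_triples(no):
            L3 = work.l3_occ(ijk)
            R3 = work.r3_occ(ijk)
            for (o1, o2, o3), axperm in _block_orderings(ijk):
                L3p = np.transpose(L3, axperm)
                R3p = np.transpose(R3, axperm)
                if not (o1 == o2 == o3):
                    # l2 . R3 -> ov
                    Dhat[o1, no:] += 2.0 * contract("cd,acd->a", l2[:, o2, :, o3], R3p)
                    Dhat[o2, no:] -= 2.0 * contract("cd,acd->a", l2[:, o1, :, o3], R3p)
                    # l3 . R2 -> vo
                    Dhat[no:, o1] += 3.0 * contract("acd,cd->a", L3p, r2[:, o2, :, o3])
                # vv l3.r3 and the trace term
                Dhat[no:, no:] += 3.0 * contract("acd,bcd->ab", L3p, R3p)
                trace_l3r3 += float(np.sum(L3p * R3p))
                # vv l3.r1.t2: 6 l3[akcldm] r1[cl] t2[bkdm]
                Dhat[no:, no:] += 6.0 * contract(
                    "acd,c,bd->ab", L3p, r1[:, o2], t2[:, o1, :, o3]
                )
                T3p = np.transpose(work.t3_occ(ijk), axperm)
                # ov l3.r2.t2 terms
                Y = contract("cde,ae->cda", L3p, t2[:, o1, :, o3])
                Dhat[:no, no:] += -6.0 * contract("cda,cid->ia", Y, r2[:, :, :, o2])
                Y = contract("cde,ad->cea", L3p, r2[:, o1, :, o2])
                Dhat[:no, no:] += -6.0 * contract("cea,cie->ia", Y, t2[:, :, :, o3])
                z = contract("cde,cd->e", L3p, r2[:, o1, :, o2])
                Dhat[:no, no:] += 6.0 * contract("e,aie->ia", z, t2[:, :, :, o3])
                Dhat[:no, no:] += -3.0 * contract("e,aei->ia", z, t2[:, o3])
                # ov l3.r1.t3 with matching occupied/virtual structure
                P = contract("cde,ade->ca", L3p, T3p)
                Dhat[:no, no:] += -3.0 * contract("ca,ci->ia", P, r1)
                # doubles-sized intermediate for the doubly-mismatched terms
                M[:, o2, :, o3] += contract("cde,c->de", L3p, r1[:, o1])
        Dhat[:no, :no] += 2.0 * trace_l3r3 * np.eye(no)
        # second sweep: contract the intermediate with tau3 blocks
        for ijk in _sorted_triples(no):
            T3 = work.t3_occ(ijk)
            for (p1, p2, p3), axperm in _block_orderings(ijk):
                T3p = np.transpose(T3, axperm)
                Dhat[p1, no:] += 6.0 * contract("ade,de->a", T3p, M[:, p2, :, p3])
                Dhat[p2, no:] += -6.0 * contract("ade,de->a", T3p, M[:, p1, :, p3])
        # virtual-blocked loop: oo l3.r3 and oo l3.r1.t2
        for abc in _sorted_triples(nv):
            L3v = work.l3_virt(abc)
            R3v = work.r3_virt(abc)
            T3v = work.t3_virt(abc)
            for (v1, v2, v3), axperm in _block_orderings(abc):
                L3vp = np.transpose(L3v, axperm)
                R3vp = np.transpose(R3v, axperm)
                Dhat[:no, :no] += -3.0 * contract("jkl,ikl->ij", L3vp, R3vp)
                Dhat[:no, :no] += -6.0 * contract(
                    "jkl,k,il->ij", L3vp, r1[v2], t2[v1, :, v3, :]
                )
                # ov term -3 l3[ckdlem] r1[ak] tau3[cidlem]: one mismatched
                # occupied index, shared virtuals
                T3vp = np.transpose(T3v, axperm)
                Dhat[:no, no:] += -3.0 * contract("klm,ak,ilm->ia", L3vp, r1, T3vp)
    D = _undress(ham, Dhat, amps.t1)
    if ref_weight:
        D = D + ref_weight * D00.D
    return DensityMatrix(D=D, kind="left_transition", state_index=state_index)


# ---------------------------------------------------------------------------
# transition moments and spectra
# ---------------------------------------------------------------------------


def transition_strength(Dm0: DensityMatrix, D0m: DensityMatrix,
                        A: PropertyOperator) -> float:
    """Biorthogonal product sum_q Tr(D~^{0m} A_q) Tr(D^{m0} A_q)."""
    s = 0.0
    for q in range(3):
        s += D0m.expectation(A.components[q]) * Dm0.expectation(A.components[q])
    return s


def oscillator_strength(
    omega: float, Dm0: DensityMatrix, D0m: DensityMatrix, A: PropertyOperator,
    label: str = "",
) -> SpectrumLine:
    """Length-gauge EOM oscillator strength f = 2/3 omega S (omega in Hartree).

    A negative value usually signals mismatched left/right roots and is
    reported with a warning rather than an error.
    """
    s = transition_strength(Dm0, D0m, A)
    f = (2.0 / 3.0) * omega * s
    if f < 0:
        import warnings

        warnings.warn(
            f"negative oscillator strength {f:.3e}; check the root pairing"
        )
    return SpectrumLine(omega_ev=omega * HARTREE_TO_EV, f=f, label=label)


def lorentzian_spectrum(
    lines, width: float = 0.5, shift: float = 0.0, grid=None, margin: float = 3.0,
    npoints: int = 2000,
) -> Spectrum:
    """Area-normalized Lorentzian broadening of a stick spectrum.

    ``sigma(w) = sum_m f_m * (Gamma/2pi) / ((w - w_m - shift)^2 + (Gamma/2)^2)``
    with FWHM ``Gamma = width`` (eV); the integral over each line equals its
    oscillator strength and the peak height is ``2 f / (pi Gamma)``.
    ``shift`` rigidly displaces the lines (used to align spectra from
    different models).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    lines = list(lines)
    if grid is None:
        if not lines:
            return Spectrum(np.zeros(0), np.zeros(0), [])
        lo = min(l.omega_ev for l in lines) + shift - margin * width
        hi = max(l.omega_ev for l in lines) + shift + margin * width
        grid = np.linspace(lo, hi, npoints)
    grid = np.asarray(grid, float)
    sigma = np.zeros_like(grid)
    half = 0.5 * width
    for line in lines:
        x = grid - line.omega_ev - shift
        sigma += line.f * (half / np.pi) / (x * x + half * half)
    return Spectrum(grid_ev=grid, intensity=sigma, lines=lines)
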