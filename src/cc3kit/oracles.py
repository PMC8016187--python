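"""Independent brute-force references and synthetic input generation.

Two layers of oracle live here:

1. :class:`DeterminantSpace` -- exact arithmetic in the full determinant basis
   (fixed particle number, S_z = 0).  Singlet excitation operators ``E_pq``,
   the Hamiltonian, cluster operators and similarity transforms are realized
   as explicit (sparse-structured) matrices, so coupled-cluster residuals,
   Jacobians, multipliers and densities can be evaluated with no recourse to
   spin-adapted tensor algebra.  This is the ultimate correctness reference
   for every contraction formula in the package, and it also provides
   :func:`fci_solve`.

2. :func:`dense_cc3_reference` (defined in :mod:`cc3kit.dense`) -- an
   independently coded, unblocked tensor implementation holding the full
   triples tensor in memory; re-exported here as the equivalence oracle for
   the blocked production path.

The determinant engine exploits the alpha/beta string factorization: a basis
state is a pair of occupation strings, and every spin-summed one-body operator
acts as ``A (x) 1 + 1 (x) A`` with a small string-space matrix ``A``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from pathlib import Path

import numpy as np

from .contractions import contract
from .integrals import MOSystem

from .contractions import FlopCounter, count_flops  # re-export: instrumented layer

__all__ = [
    "DeterminantSpace",
    "FCISolution",
    "fci_solve",
    "det_cc3_solve",
    "det_cc3_residual",
    "synthetic_mosystem",
    "finite_difference_directional",
    "load_fixture",
    "fixture_names",
    "fixture_metadata",
    "dense_cc3_reference",
    "count_flops",
    "FlopCounter",
]


# ---------------------------------------------------------------------------
# Determinant space
# ---------------------------------------------------------------------------


def _popcount_below(mask: int, p: int) -> int:
    return bin(mask & ((1 << p) - 1)).count("1")


class DeterminantSpace:
    """Full determinant basis (N_alpha = N_beta = n_occ) over n_orb spatial orbitals.

    Basis states are indexed ``i_alpha * n_strings + i_beta`` where the string
    lists enumerate all ``C(n_orb, n_occ)`` occupation bitmasks in a fixed
    order.  The closed-shell reference (lowest ``n_occ`` orbitals doubly
    occupied) sits at :attr:`hf_index`.
    """

    def __init__(self, n_orb: int, n_occ: int):
        if not 0 < n_occ <= n_orb:
            raise ValueError("need 0 < n_occ <= n_orb")
        self.n_orb = n_orb
        self.n_occ = n_occ
        self.strings = [sum(1 << p for p in occ) for occ in combinations(range(n_orb), n_occ)]
        self.index = {s: i for i, s in enumerate(self.strings)}
        self.ns = len(self.strings)
        self.dim = self.ns * self.ns
        hf = (1 << n_occ) - 1
        self.hf_string = self.index[hf]
        self.hf_index = self.hf_string * self.ns + self.hf_string
        # string-space matrices of a^dagger_p a_q (one spin channel)
        self._A = np.zeros((n_orb, n_orb, self.ns, self.ns))
        for q in range(n_orb):
            for p in range(n_orb):
                M = self._A[p, q]
                for si, s in enumerate(self.strings):
                    if not (s >> q) & 1:
                        continue
                    s1 = s & ~(1 << q)
                    phase = (-1) ** _popcount_below(s1, q)
                    if (s1 >> p) & 1:
                        continue
                    s2 = s1 | (1 << p)
                    phase *= (-1) ** _popcount_below(s1, p)
                    M[self.index[s2], si] += phase
        # excitation rank (number of electrons in virtual orbitals)
        virt_mask = ~hf
        string_rank = np.array([bin(s & virt_mask).count("1") for s in self.strings])
        self.rank = (string_rank[:, None] + string_rank[None, :]).reshape(self.dim)

    # -- elementary operators -------------------------------------------------

    def hf_vector(self, dtype=float) -> np.ndarray:
        v = np.zeros(self.dim, dtype)
        v[self.hf_index] = 1.0
        return v

    def apply_E(self, p: int, q: int, vec: np.ndarray) -> np.ndarray:
        """Apply the singlet excitation operator E_pq = sum_sigma a+_{p sigma} a_{q sigma}."""
        V = vec.reshape(self.ns, self.ns)
        A = self._A[p, q]
        return (A @ V + V @ A.T).ravel()

    def one_body(self, o: np.ndarray) -> np.ndarray:
        """Dense matrix of sum_pq o_pq E_pq."""
        G = np.einsum("pq,pqij->ij", o, self._A)
        return self._kron_pair(G)

    def _kron_pair(self, G: np.ndarray) -> np.ndarray:
        eye = np.eye(self.ns, dtype=G.dtype)
        return (np.kron(G, eye) + np.kron(eye, G)).reshape(self.dim, self.dim)

    def build_hamiltonian(self, h: np.ndarray, g: np.ndarray) -> np.ndarray:
        """Dense matrix of sum h_pq E_pq + 1/2 sum g_pqrs (E_pq E_rs - d_qr E_ps).

        ``g`` must have at least the pair-swap symmetry g_pqrs = g_rspq
        (chemists' notation); this holds for bare and for T1-dressed integrals.
        """
        n = self.n_orb
        A = self._A.reshape(n * n, self.ns, self.ns)
        B = np.einsum("xy,yij->xij", g.reshape(n * n, n * n), A)  # B_pq = sum_rs g_pqrs A_rs
        # same-spin two-electron part: 1/2 sum_pq A_pq B_pq - 1/2 sum_ps (sum_q g_pqqs) A_ps
        G = np.einsum("pq,pqij->ij", h, self._A).astype(np.result_type(h, g))
        G += 0.5 * np.einsum("xij,xjk->ik", A, B)
        G -= 0.5 * np.einsum("pqqs,psij->ij", g, self._A)
        H = self._kron_pair(G)
        # opposite-spin part: sum_pq A_pq (x) B_pq (uses the pair-swap symmetry)
        cross = np.einsum("xij,xkl->ikjl", A, B).reshape(self.dim, self.dim)
        return H + cross

    # -- amplitude-space <-> state maps ---------------------------------------

    def singles_kets(self) -> np.ndarray:
        """Matrix (dim, nv*no) of E_ai |HF>, column order a-major then i."""
        no, nv = self.n_occ, self.n_orb - self.n_occ
        hf = self.hf_vector()
        cols = [self.apply_E(no + a, i, hf) for a in range(nv) for i in range(no)]
        return np.array(cols).T

    def pair_list(self):
        """Ordered list of doubles pairs (ai) >= (bj) in flattened (a, i) order."""
        no, nv = self.n_occ, self.n_orb - self.n_occ
        singles = [(a, i) for a in range(nv) for i in range(no)]
        pairs = []
        for x, (a, i) in enumerate(singles):
            for (b, j) in singles[: x + 1]:
                pairs.append((a, i, b, j))
        return pairs

    def doubles_kets(self) -> np.ndarray:
        """Matrix (dim, npairs) of E_ai E_bj |HF> for (ai) >= (bj)."""
        no = self.n_occ
        hf = self.hf_vector()
        singles = {}
        nv = self.n_orb - no
        for a in range(nv):
            for i in range(no):
                singles[(a, i)] = self.apply_E(no + a, i, hf)
        cols = []
        for (a, i, b, j) in self.pair_list():
            cols.append(self.apply_E(no + a, i, singles[(b, j)]))
        return np.array(cols).T

    def apply_T2(self, t2: np.ndarray, vec: np.ndarray) -> np.ndarray:
        """Apply T2 = 1/2 sum t_aibj E_ai E_bj to a state vector."""
        no, nv = self.n_occ, t2.shape[0]
        out = np.zeros_like(vec)
        for b in range(nv):
            for j in range(no):
                w = self.apply_E(no + b, j, vec)
                for a in range(nv):
                    for i in range(no):
                        out = out + 0.5 * t2[a, i, b, j] * self.apply_E(no + a, i, w)
        return out

    def apply_T3(self, t3: np.ndarray, vec: np.ndarray) -> np.ndarray:
        """Apply T3 = 1/6 sum t_aibjck E_ai E_bj E_ck to a state vector."""
        no, nv = self.n_occ, t3.shape[0]
        ns1 = nv * no
        w1 = np.array([self.apply_E(no + b, j, vec) for b in range(nv) for j in range(no)])
        w2 = np.array([self.apply_E(no + b, j, w) for b in range(nv) for j in range(no)
                       for w in w1])
        x = t3.reshape(ns1, ns1 * ns1) @ w2
        out = np.zeros_like(vec)
        for a in range(nv):
            for i in range(no):
                out = out + self.apply_E(no + a, i, x[a * no + i])
        return out / 6.0

    def apply_T1(self, t1: np.ndarray, vec: np.ndarray) -> np.ndarray:
        no, nv = t1.shape[1], t1.shape[0]
        V = vec.reshape(self.ns, self.ns)
        G = np.einsum("ai,aixy->xy", t1, self._A[no:, :no].astype(t1.dtype))
        return (G @ V + V @ G.T).ravel()

    def exp_T_on(self, vec: np.ndarray, t1=None, t2=None, t3=None, sign: float = 1.0) -> np.ndarray:
        """Apply exp(sign * (T1 + T2 + T3)) to ``vec`` (the series terminates)."""
        out = vec.copy()
        term = vec.copy()
        for k in range(1, 4 * self.n_occ + 3):
            nxt = np.zeros_like(term)
            if t1 is not None:
                nxt = nxt + self.apply_T1(t1, term)
            if t2 is not None:
                nxt = nxt + self.apply_T2(t2, term)
            if t3 is not None:
                nxt = nxt + self.apply_T3(t3, term)
            term = sign * nxt / k
            if not np.any(term):
                break
            out = out + term
        return out

    def project_rank(self, vec: np.ndarray, r: int) -> np.ndarray:
        out = np.zeros_like(vec)
        mask = self.rank == r
        out[mask] = vec[mask]
        return out

    def energy_denominators(self, eps: np.ndarray) -> np.ndarray:
        """Per-determinant sum of occupied-spinorbital energies minus the HF value."""
        string_e = np.array(
            [sum(eps[p] for p in range(self.n_orb) if (s >> p) & 1) for s in self.strings]
        )
        tot = (string_e[:, None] + string_e[None, :]).reshape(self.dim)
        return tot - tot[self.hf_index]

    # -- covariant / biorthonormal extraction ---------------------------------

    def covariant_singles(self, vec: np.ndarray) -> np.ndarray:
        """Omega_ai = <HF| E_ia |vec> as an (nv, no) array."""
        no, nv = self.n_occ, self.n_orb - self.n_occ
        K = self._cached_singles_kets()
        return (K.T @ vec).reshape(nv, no)

    def covariant_doubles(self, vec: np.ndarray) -> np.ndarray:
        """Omega_aibj = <HF| E_ia E_jb |vec> as a full symmetric (nv,no,nv,no) array."""
        no, nv = self.n_occ, self.n_orb - self.n_occ
        K = self._cached_doubles_kets()
        packed = K.T @ vec
        out = np.zeros((nv, no, nv, no), dtype=vec.dtype)
        for val, (a, i, b, j) in zip(packed, self.pair_list()):
            out[a, i, b, j] = val
            out[b, j, a, i] = val
        return out

    def biorthonormal_doubles(self, vec: np.ndarray) -> np.ndarray:
        """The unique symmetric tensor x with (1/2) sum x_aibj E_ai E_bj |HF> = P2 vec."""
        no, nv = self.n_occ, self.n_orb - self.n_occ
        pinv = self._cached_doubles_pinv()
        packed = pinv @ self.project_rank(vec, 2)
        out = np.zeros((nv, no, nv, no), dtype=vec.dtype)
        for val, (a, i, b, j) in zip(packed, self.pair_list()):
            out[a, i, b, j] = val
            out[b, j, a, i] = val
        return out

    def biorthonormal_singles(self, vec: np.ndarray) -> np.ndarray:
        return 0.5 * self.covariant_singles(vec)

    def biorth_bra_state(self, ref: float = 0.0, l1=None, l2=None) -> np.ndarray:
        """Bra vector <L| with <L| M(x)|HF> = ref*x0 + sum l1.x1 + sum_full l2.x2."""
        b = ref * self.hf_vector()
        if l1 is not None:
            K1 = self._cached_singles_kets()
            b = b + 0.5 * (K1 @ l1.ravel())
        if l2 is not None:
            pinv = self._cached_doubles_pinv()
            w = np.array([1.0 if (a, i) == (b_, j) else 2.0 for (a, i, b_, j) in self.pair_list()])
            packed = np.array([l2[a, i, b_, j] for (a, i, b_, j) in self.pair_list()])
            b = b + (w * packed) @ pinv
        return b

    def _cached_singles_kets(self):
        if not hasattr(self, "_K1"):
            self._K1 = self.singles_kets()
        return self._K1

    def _cached_doubles_kets(self):
        if not hasattr(self, "_K2"):
            self._K2 = self.doubles_kets()
        return self._K2

    def _cached_doubles_pinv(self):
        # weights: the map t2 -> T2|HF> in packed (ai)>=(bj) coordinates carries
        # weight 1 off the pair diagonal and 1/2 on it.
        if not hasattr(self, "_P2inv"):
            K = self._cached_doubles_kets()
            w = np.array([0.5 if (a, i) == (b, j) else 1.0 for (a, i, b, j) in self.pair_list()])
            Kw = K * w
            self._P2inv = np.linalg.pinv(Kw, rcond=1e-12)
        return self._P2inv


@lru_cache(maxsize=8)
def det_space(n_orb: int, n_occ: int) -> DeterminantSpace:
    """Memoized :class:`DeterminantSpace` constructor."""
    return DeterminantSpace(n_orb, n_occ)


# ---------------------------------------------------------------------------
# Determinant-space CC3 (the equation-level reference)
# ---------------------------------------------------------------------------


def det_cc3_triples(space: DeterminantSpace, H: np.ndarray, t2: np.ndarray,
                    eps: np.ndarray, omega: float = 0.0) -> np.ndarray:
    """Folded triples vector: -(eps3 - omega)^{-1} P3 [H-tilde, T2] |HF>.

    ``H`` is the dressed Hamiltonian matrix; the denominators use the bare
    orbital energies ``eps`` (canonical partitioning).
    """
    hf = space.hf_vector(dtype=np.result_type(H, t2))
    w3 = space.project_rank(H @ space.apply_T2(t2, hf) - space.apply_T2(t2, H @ hf), 3)
    denom = space.energy_denominators(eps) - omega
    v3 = np.zeros_like(w3)
    mask = space.rank == 3
    v3[mask] = -w3[mask] / denom[mask]
    return v3


def det_cc3_residual(space: DeterminantSpace, ham, t2: np.ndarray, triples: bool = True):
    """CC3 energy and linked residual from determinant arithmetic.

    ``ham`` is a :class:`~cc3kit.integrals.T1Hamiltonian`; the T1 dependence
    enters entirely through the dressed integrals.  Returns
    ``(energy, omega1, omega2, v3)`` with the residual in the biorthonormal
    (amplitude-space) convention: at t = 0, ``omega1 = F_ai`` and
    ``omega2 = g_aibj``.
    """
    H = space.build_hamiltonian(ham.h, ham.g)
    hf = space.hf_vector(dtype=np.result_type(H, t2))
    psi = space.exp_T_on(hf, t2=t2)
    r_state = H @ psi
    energy = r_state[space.hf_index] + ham.e_nuc
    v3 = None
    if triples:
        v3 = det_cc3_triples(space, H, t2, ham.eps)
        r_state = r_state + H @ v3
    r_state = space.exp_T_on(r_state, t2=t2, sign=-1.0)
    om1 = space.biorthonormal_singles(r_state)
    om2 = space.biorthonormal_doubles(r_state)
    return energy, om1, om2, v3


def det_cc3_solve(
    sys: MOSystem,
    conv: float = 1e-12,
    max_iter: int = 300,
    noncanonical: bool = False,
):
    """Solve the CC3 amplitude equations entirely in determinant space.

    With ``noncanonical=True`` the triples zeroth-order operator is the full
    bare Fock matrix of ``sys`` (its off-diagonal blocks couple triples
    determinants; a dense linear solve in the triples sector replaces the
    orbital-energy denominators).  This is the reference path for
    finite-field checks of the ground-state density, where the perturbed
    Fock matrix is no longer diagonal.

    Returns ``(energy, t1, t2)``.
    """
    from ._packing import DIIS, pack, unpack
    from .integrals import t1_transform

    space = det_space(sys.n_orb, sys.n_occ)
    no, nv = sys.n_occ, sys.n_virt
    eo, ev = sys.eps[:no], sys.eps[no:]
    d1 = ev[:, None] - eo[None, :]
    d2 = d1[:, :, None, None] + d1[None, None, :, :]
    t1 = np.zeros((nv, no))
    t2 = np.zeros((nv, no, nv, no))
    hf = space.hf_vector()
    mask3 = space.rank == 3
    if noncanonical:
        Fdet = space.one_body(sys.fock)
        e0f = 2.0 * np.sum(np.diag(sys.fock)[:no])
        F3 = Fdet[np.ix_(mask3, mask3)] - e0f * np.eye(int(mask3.sum()))
    diis = DIIS()
    err = np.inf
    for it in range(max_iter):
        ham = t1_transform(sys, t1)
        H = space.build_hamiltonian(ham.h, ham.g)
        psi = space.exp_T_on(hf, t2=t2)
        w3 = space.project_rank(H @ space.apply_T2(t2, hf) - space.apply_T2(t2, H @ hf), 3)
        v3 = np.zeros_like(w3)
        if no >= 2 and np.any(mask3):
            if noncanonical:
                v3[mask3] = np.linalg.solve(F3, -w3[mask3])
            else:
                den = space.energy_denominators(sys.eps)
                v3[mask3] = -w3[mask3] / den[mask3]
        r_state = H @ psi + H @ v3
        energy = r_state[space.hf_index] + sys.e_nuc
        r_state = space.exp_T_on(r_state, t2=t2, sign=-1.0)
        om1 = space.biorthonormal_singles(r_state)
        om2 = space.biorthonormal_doubles(r_state)
        err = max(np.abs(om1).max(), np.abs(om2).max())
        if err < conv:
            if not np.iscomplexobj(energy):
                energy = float(energy)
            return energy, t1, t2
        z = diis.update(pack(t1 - om1 / d1, t2 - om2 / d2), pack(-om1 / d1, -om2 / d2))
        t1, t2 = unpack(z, nv, no)
    raise RuntimeError(f"determinant-space CC3 did not converge ({err:.2e})")


# ---------------------------------------------------------------------------
# FCI
# ---------------------------------------------------------------------------


@dataclass
class FCISolution:
    energies: np.ndarray  # total energies incl. nuclear repulsion, ascending
    vectors: np.ndarray  # columns are CI vectors in the determinant basis
    space: DeterminantSpace

    def excitation_energies(self, n: int | None = None) -> np.ndarray:
        de = self.energies[1:] - self.energies[0]
        return de if n is None else de[:n]

    def swap_parity(self, m: int) -> float:
        """Alpha/beta exchange parity of state m: +1 for singlets (and other
        even-spin states), -1 for triplets.  Exact spin label for systems with
        at most two unpaired electrons."""
        ns = self.space.ns
        V = self.vectors[:, m].reshape(ns, ns)
        return float(np.sum(V * V.T))

    def singlet_excitations(self, n: int | None = None) -> np.ndarray:
        out = [
            self.energies[m] - self.energies[0]
            for m in range(1, len(self.energies))
            if self.swap_parity(m) > 0.0
        ]
        return np.array(out if n is None else out[:n])

    def transition_strength(self, dipole: np.ndarray, m: int) -> float:
        """sum_q |<0| A_q |m>|^2 for the Cartesian dipole components."""
        s = 0.0
        for q in range(dipole.shape[0]):
            Aop = self.space.one_body(dipole[q])
            s += float(self.vectors[:, 0] @ (Aop @ self.vectors[:, m])) ** 2
        return s

    def oscillator_strength(self, dipole: np.ndarray, m: int) -> float:
        omega = self.energies[m] - self.energies[0]
        return (2.0 / 3.0) * omega * self.transition_strength(dipole, m)


def fci_solve(sys: MOSystem, n_states: int | None = None, max_dim: int = 20000) -> FCISolution:
    """Dense full CI in the S_z = 0 determinant basis (tiny systems only)."""
    space = det_space(sys.n_orb, sys.n_occ)
    if space.dim > max_dim:
        raise ValueError(
            f"determinant space of dimension {space.dim} exceeds the oracle limit {max_dim}"
        )
    H = space.build_hamiltonian(sys.h, sys.eri)
    vals, vecs = np.linalg.eigh(H)
    if n_states is not None:
        vals, vecs = vals[:n_states], vecs[:, :n_states]
    return FCISolution(energies=vals + sys.e_nuc, vectors=vecs, space=space)


# ---------------------------------------------------------------------------
# Synthetic systems
# ---------------------------------------------------------------------------


def synthetic_mosystem(
    n_occ: int,
    n_virt: int,
    seed: int = 0,
    interaction_scale: float = 0.1,
    gap: float = 1.0,
    dipole: bool = True,
) -> MOSystem:
    """Random canonical closed-shell model Hamiltonian.

    The ERI tensor is assembled as ``sum_J L^J L^J`` from ``3 * n_orb`` seeded
    Gaussian symmetric factors scaled by ``interaction_scale / sqrt(n_factors)``
    (guaranteed positive semidefinite with the full 8-fold symmetry, and with
    a norm that is stable under basis-size changes).  The Fock matrix is
    diagonal by construction with a spectral gap >= 0.2 Hartree between the
    occupied and virtual blocks, and the one-electron part is back-solved so
    that the requested orbital energies are exactly the Fock eigenvalues.  A
    small ``interaction_scale`` keeps the perturbative structure needed for
    the amplitude iterations to converge.
    """
    if n_occ < 1 or n_virt < 1:
        raise ValueError("need n_occ >= 1 and n_virt >= 1")
    rng = np.random.default_rng(seed)
    n = n_occ + n_virt
    n_fac = 3 * n
    L = rng.standard_normal((n_fac, n, n))
    L = (L + L.transpose(0, 2, 1)) / 2.0
    L *= interaction_scale / np.sqrt(n_fac)
    eri = contract("Jpq,Jrs->pqrs", L, L)

    eps = np.concatenate(
        [
            -gap - np.sort(rng.uniform(0.0, 1.0, n_occ))[::-1],
            0.2 + np.sort(rng.uniform(0.0, 1.0, n_virt)),
        ]
    )
    o = slice(0, n_occ)
    h = np.diag(eps) - 2.0 * contract("pqii->pq", eri[:, :, o, o]) + contract(
        "piiq->pq", eri[:, o, o, :]
    )
    dip = None
    if dipole:
        dip = rng.standard_normal((3, n, n))
        dip = (dip + dip.transpose(0, 2, 1)) / 2.0
    return MOSystem.from_integrals(
        h, eri, n_electrons=2 * n_occ, e_nuc=0.0, dipole=dip, check=True
    )


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------

_FIXTURE_DIR = Path(__file__).parent / "fixtures"


def fixture_names():
    return sorted(p.stem for p in _FIXTURE_DIR.glob("*.fcidump"))


def fixture_metadata(name: str) -> dict:
    import json

    return json.loads((_FIXTURE_DIR / f"{name}.json").read_text())


def load_fixture(name: str, frozen=None) -> MOSystem:
    """Load a packaged tiny-molecule FCIDUMP fixture (with dipole matrices).

    Available fixtures: H2 in a minimal and a split-valence basis, He, and
    H4/H6 hydrogen chains (s-function bases; geometry and provenance in the
    JSON sidecars).
    """
    from .integrals import read_fcidump

    path = _FIXTURE_DIR / f"{name}.fcidump"
    if not path.exists():
        raise FileNotFoundError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    sys = read_fcidump(path, frozen=frozen)
    meta = fixture_metadata(name)
    if "dipole_mo" in meta and not frozen:
        sys.dipole = np.array(meta["dipole_mo"])
    return sys


# ---------------------------------------------------------------------------
# Finite differences
# ---------------------------------------------------------------------------


def finite_difference_directional(fn, x0: np.ndarray, direction: np.ndarray, eps_list):
    """Central-difference directional derivatives with observed-order estimate.

    Returns ``(derivative, order)`` where ``derivative`` uses the smallest
    step and ``order`` is the median log2 error-reduction rate between
    consecutive steps (Richardson-style check; exact 2.0 for smooth ``fn``).
    """
    eps_list = sorted(eps_list, reverse=True)
    if any(e <= 0 for e in eps_list):
        raise ValueError("steps must be positive")
    if min(eps_list) < 1e-7:
        raise ValueError("steps below 1e-7 lose precision in double arithmetic")
    ests = []
    for e in eps_list:
        ests.append((fn(x0 + e * direction) - fn(x0 - e * direction)) / (2 * e))
    if len(ests) < 3:
        return ests[-1], np.nan
    # err(e) ~ C e^p: consecutive differences satisfy
    # |est_k - est_{k+1}| / |est_{k+1} - est_{k+2}| = r^p  for e_{k+1} = e_k / r
    orders = []
    for k in range(len(ests) - 2):
        d1 = np.linalg.norm(np.atleast_1d(ests[k] - ests[k + 1]))
        d2 = np.linalg.norm(np.atleast_1d(ests[k + 1] - ests[k + 2]))
        r1 = eps_list[k] / eps_list[k + 1]
        r2 = eps_list[k + 1] / eps_list[k + 2]
        if d2 > 0 and d1 > 0 and abs(r1 - r2) < 1e-12:
            orders.append(np.log(d1 / d2) / np.log(r1))
    order = float(np.median(orders)) if orders else np.nan
    return ests[-1], order


def dense_cc3_reference(sys: MOSystem, conv: float = 1e-11, triples: bool = True):
    """Unblocked dense CC3 equivalence oracle (see :mod:`cc3kit.dense`)."""
    from .dense import DenseCC3Reference

    return DenseCC3Reference(sys, conv=conv, triples=triples)
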