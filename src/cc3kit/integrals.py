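"""Canonical-MO Hamiltonians: FCIDUMP I/O, Cholesky ERI factors, T1 dressing.

Conventions used throughout the package
---------------------------------------
* Spatial orbitals, 0-based, occupied block first (``0 .. n_occ-1``) followed by
  the virtual block (``n_occ .. n_orb-1``).  FCIDUMP I/O converts from the
  1-based convention at the boundary.
* Two-electron integrals are stored in chemists' notation ``(pq|rs)`` as a full
  4-index array ``eri[p, q, r, s]`` with 8-fold permutational symmetry.
* All energies in Hartree.

The T1 similarity transform ``exp(-T1) H exp(T1)`` acts as a biorthogonal
orbital rotation: creation operators are dressed with ``A = 1 - t1`` and
annihilation operators with ``B = 1 + t1^T`` (t1 embedded in the virtual-row /
occupied-column block).  Dressed integrals therefore lose the within-pair
``(pq|rs) -> (qp|rs)`` symmetry but keep the pair swap ``(pq|rs) -> (rs|pq)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .contractions import contract

__all__ = [
    "MOSystem",
    "CholeskyVectors",
    "T1Hamiltonian",
    "read_fcidump",
    "write_fcidump",
    "cholesky_decompose",
    "t1_transform",
    "partition_fock",
    "hf_energy",
    "load_dipole_h5",
    "save_dipole_h5",
]

CANONICAL_TOL = 1e-8


class FCIDumpError(ValueError):
    """Malformed FCIDUMP content."""


@dataclass
class MOSystem:
    """Canonical-MO Hamiltonian for a closed-shell reference.

    Attributes
    ----------
    n_occ, n_virt:
        Number of active occupied / virtual spatial orbitals.
    n_electrons:
        Total number of electrons including frozen-core ones.
    eps:
        Orbital energies (Hartree), length ``n_occ + n_virt``.  These define
        the zeroth-order (Moller-Plesset-like) partitioning and the triples
        denominators.
    h, eri:
        One-electron integrals and chemists'-notation ``(pq|rs)`` two-electron
        integrals over active orbitals; frozen-core contributions are folded
        into ``h`` and ``e_nuc`` at construction.
    fock:
        Fock matrix.  Off-diagonal elements inside the occupied-occupied and
        virtual-virtual blocks must vanish to ``canonical_tol`` (the
        perturbation orders of the triples treatment assume a canonical
        basis); violations raise unless ``check=False``.
    dipole:
        Optional ``(3, n, n)`` array of Cartesian dipole matrices (a.u.).
    core_occ:
        Occupied orbital indices designated as core for CVS runs.
    """

    n_occ: int
    n_virt: int
    n_electrons: int
    eps: np.ndarray
    h: np.ndarray
    eri: np.ndarray
    fock: np.ndarray
    e_nuc: float = 0.0
    dipole: np.ndarray | None = None
    core_occ: list[int] = field(default_factory=list)
    frozen: list[int] = field(default_factory=list)

    @property
    def n_orb(self) -> int:
        return self.n_occ + self.n_virt

    @classmethod
    def from_integrals(
        cls,
        h: np.ndarray,
        eri: np.ndarray,
        n_electrons: int,
        e_nuc: float = 0.0,
        frozen: list[int] | None = None,
        dipole: np.ndarray | None = None,
        core_occ: list[int] | None = None,
        check: bool = True,
        canonical_tol: float = CANONICAL_TOL,
    ) -> "MOSystem":
        """Build an :class:`MOSystem`, folding frozen-core orbitals into ``h``.

        Orbitals are assumed energy-ordered so that the occupied space is the
        first ``n_electrons // 2`` orbitals (before freezing).
        """
        h = np.asarray(h, float)
        eri = np.asarray(eri, float)
        frozen = sorted(frozen or [])
        if n_electrons % 2:
            raise ValueError("closed-shell reference requires an even electron count")
        n_occ_total = n_electrons // 2
        if any(f >= n_occ_total for f in frozen):
            raise ValueError("frozen orbitals must be occupied")

        if frozen:
            fz = np.array(frozen, int)
            e_nuc = e_nuc + 2.0 * h[fz, fz].sum()
            e_nuc += 2.0 * contract("ffgg->", eri[np.ix_(fz, fz, fz, fz)]).item()
            e_nuc -= contract("fggf->", eri[np.ix_(fz, fz, fz, fz)]).item()
            h = h + 2.0 * contract("pqff->pq", eri[:, :, fz, :][:, :, :, fz])
            h = h - contract("pffq->pq", eri[:, fz, :, :][:, :, fz, :])
            keep = [p for p in range(h.shape[0]) if p not in frozen]
            h = h[np.ix_(keep, keep)]
            eri = eri[np.ix_(keep, keep, keep, keep)]

        n_occ = n_occ_total - len(frozen)
        n_orb = h.shape[0]
        n_virt = n_orb - n_occ
        o = slice(0, n_occ)
        fock = h + 2.0 * contract("pqii->pq", eri[:, :, o, o]) - contract("piiq->pq", eri[:, o, o, :])
        if check:
            off = fock - np.diag(np.diag(fock))
            err = max(
                np.abs(off[o, o]).max(initial=0.0),
                np.abs(off[n_occ:, n_occ:]).max(initial=0.0),
            )
            if err > canonical_tol:
                raise ValueError(
                    f"non-canonical reference: |off-diagonal Fock| = {err:.3e} "
                    f"exceeds {canonical_tol:.1e} in the occ-occ/virt-virt blocks"
                )
        return cls(
            n_occ=n_occ,
            n_virt=n_virt,
            n_electrons=n_electrons,
            eps=np.diag(fock).copy(),
            h=h,
            eri=eri,
            fock=fock,
            e_nuc=float(e_nuc),
            dipole=None if dipole is None else np.asarray(dipole, float),
            core_occ=list(core_occ or []),
            frozen=frozen,
        )

    def with_perturbation(self, A: np.ndarray, alpha: float) -> "MOSystem":
        """Return a copy with ``alpha * A`` added to the one-electron part.

        The orbital-energy vector ``eps`` (the zeroth-order partitioning) is
        left untouched; the perturbation lives entirely in the fluctuation
        potential.  Used by finite-field checks of densities.
        """
        h = self.h + alpha * np.asarray(A, float)
        o = slice(0, self.n_occ)
        fock = h + 2.0 * contract("pqii->pq", self.eri[:, :, o, o]) - contract(
            "piiq->pq", self.eri[:, o, o, :]
        )
        return replace(self, h=h, fock=fock)


@dataclass
class CholeskyVectors:
    """Incomplete pivoted Cholesky factors of the ERI pair matrix.

    ``vectors[J]`` is a square ``(n, n)`` factor ``L^J_pq`` with
    ``sum_J L^J_pq L^J_rs ~= (pq|rs)`` to ``threshold``.
    """

    vectors: np.ndarray  # (n_vec, n, n)
    threshold: float

    def reconstruct(self) -> np.ndarray:
        n = self.vectors.shape[1]
        if len(self.vectors) == 0:
            return np.zeros((n, n, n, n))
        return contract("Jpq,Jrs->pqrs", self.vectors, self.vectors)


@dataclass
class T1Hamiltonian:
    """T1-dressed Hamiltonian in the MO basis.

    ``g`` is the dressed two-electron integral set (the fluctuation potential
    ``U``), ``fock`` the dressed Fock matrix.  With ``t1 = 0`` every quantity
    equals the corresponding :class:`MOSystem` one.
    """

    n_occ: int
    n_virt: int
    h: np.ndarray
    g: np.ndarray
    fock: np.ndarray
    eps: np.ndarray  # bare orbital energies defining the denominators
    e_nuc: float

    @property
    def n_orb(self) -> int:
        return self.n_occ + self.n_virt

    @property
    def f_oo(self) -> np.ndarray:
        return self.fock[: self.n_occ, : self.n_occ]

    @property
    def f_vv(self) -> np.ndarray:
        return self.fock[self.n_occ :, self.n_occ :]

    @property
    def f_ov(self) -> np.ndarray:
        return self.fock[: self.n_occ, self.n_occ :]

    @property
    def f_vo(self) -> np.ndarray:
        return self.fock[self.n_occ :, : self.n_occ]

    def reference_energy(self) -> float:
        """<HF| dressed H |HF> + nuclear repulsion."""
        o = slice(0, self.n_occ)
        e = 2.0 * np.trace(self.h[o, o])
        e += 2.0 * contract("iijj->", self.g[o, o, o, o]).item()
        e -= contract("ijji->", self.g[o, o, o, o]).item()
        return e + self.e_nuc


def t1_transform(sys: MOSystem, t1: np.ndarray) -> T1Hamiltonian:
    """Dress the Hamiltonian of ``sys`` with singles amplitudes ``t1 (nv, no)``."""
    no, nv, n = sys.n_occ, sys.n_virt, sys.n_orb
    t1 = np.asarray(t1)
    if t1.shape != (nv, no):
        raise ValueError(f"t1 must have shape ({nv}, {no}), got {t1.shape}")
    A = np.eye(n, dtype=t1.dtype)
    A[no:, :no] -= t1
    B = np.eye(n, dtype=t1.dtype)
    B[:no, no:] += t1.T

    h = A @ sys.h @ B.T
    g = contract("pt,qu,tuvw->pqvw", A, B, sys.eri.astype(t1.dtype, copy=False))
    g = contract("rv,sw,pqvw->pqrs", A, B, g)
    o = slice(0, no)
    fock = h + 2.0 * contract("pqii->pq", g[:, :, o, o]) - contract("piiq->pq", g[:, o, o, :])
    return T1Hamiltonian(
        n_occ=no, n_virt=nv, h=h, g=g, fock=fock, eps=sys.eps.copy(), e_nuc=sys.e_nuc
    )


def partition_fock(ham: T1Hamiltonian):
    """Split the dressed Hamiltonian into Fock blocks and the fluctuation potential.

    Returns ``(F_oo, F_vv, F_ov, F_vo, U)`` where ``U`` is the dressed
    two-electron integral set.
    """
    return ham.f_oo, ham.f_vv, ham.f_ov, ham.f_vo, ham.g


def hf_energy(sys: MOSystem) -> float:
    o = slice(0, sys.n_occ)
    e = 2.0 * np.trace(sys.h[o, o])
    e += 2.0 * contract("iijj->", sys.eri[o, o, o, o]).item()
    e -= contract("ijji->", sys.eri[o, o, o, o]).item()
    return e + sys.e_nuc


# ---------------------------------------------------------------------------
# Cholesky decomposition of the ERI pair matrix
# ---------------------------------------------------------------------------


def cholesky_decompose(eri: np.ndarray, threshold: float = 1e-8) -> CholeskyVectors:
    """Pivoted incomplete Cholesky factorization of ``(pq|rs)``.

    The ERI array is viewed as a positive semidefinite matrix over composite
    pair indices ``(pq), (rs)``; factors are accumulated until the largest
    remaining diagonal element drops to ``threshold``.
    """
    n = eri.shape[0]
    M = np.asarray(eri, float).reshape(n * n, n * n)
    diag = np.diag(M).copy()
    if diag.min() < -10.0 * threshold:
        raise ValueError(
            f"pair matrix has negative diagonal {diag.min():.3e}; ERI not positive semidefinite"
        )
    vecs: list[np.ndarray] = []
    Ls: list[np.ndarray] = []
    while True:
        p = int(np.argmax(diag))
        dmax = diag[p]
        if dmax <= threshold:
            break
        col = M[:, p].copy()
        for L in Ls:
            col -= L * L[p]
        L = col / np.sqrt(dmax)
        Ls.append(L)
        diag -= L * L
        if diag.min() < -10.0 * threshold:
            raise ValueError("negative residual diagonal; ERI not positive semidefinite")
        np.maximum(diag, 0.0, out=diag)
        if len(Ls) >= n * n:
            break
    if Ls:
        vectors = np.array([L.reshape(n, n) for L in Ls])
    else:
        vectors = np.zeros((0, n, n))
    return CholeskyVectors(vectors=vectors, threshold=threshold)


# ---------------------------------------------------------------------------
# FCIDUMP I/O (Molpro dialect)
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"&FCI(.*?)(?:&END|/)", re.S | re.I)


def _parse_header(text: str) -> dict:
    m = _HEADER_RE.search(text)
    if not m:
        raise FCIDumpError("missing &FCI ... &END header")
    body = m.group(1)
    out = {}
    for key, val in re.findall(r"([A-Za-z0-9_]+)\s*=\s*([^=]*?)(?=,?\s*[A-Za-z0-9_]+\s*=|$)", body, re.S):
        out[key.upper()] = val.strip().rstrip(",")
    for key in ("NORB", "NELEC"):
        if key not in out:
            raise FCIDumpError(f"FCIDUMP header lacks required key {key}")
        try:
            out[key] = int(out[key])
        except ValueError as exc:
            raise FCIDumpError(f"FCIDUMP header key {key} is not an integer: {out[key]!r}") from exc
    return out, m.end()


def read_fcidump(
    path,
    frozen: list[int] | None = None,
    check: bool = True,
    canonical_tol: float = CANONICAL_TOL,
) -> MOSystem:
    """Read a Molpro-dialect FCIDUMP file into an :class:`MOSystem`.

    Indices are converted to the internal 0-based convention and the
    8-fold-reduced integral records are expanded to full symmetric storage.
    The occupied/virtual split follows from ``NELEC`` and the ``frozen`` list.
    """
    text = open(path).read()
    header, pos = _parse_header(text)
    norb, nelec = header["NORB"], header["NELEC"]
    h = np.zeros((norb, norb))
    eri = np.zeros((norb, norb, norb, norb))
    e_nuc = 0.0
    for line in text[pos:].splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise FCIDumpError(f"malformed integral record: {line!r}")
        val = float(parts[0].replace("D", "E").replace("d", "e"))
        i, j, k, l = (int(x) for x in parts[1:])
        for idx in (i, j, k, l):
            if idx < 0 or idx > norb:
                raise FCIDumpError(f"orbital index {idx} outside 1..NORB={norb}: {line!r}")
        if i == 0:
            e_nuc = val
        elif k == 0:
            i, j = i - 1, j - 1
            h[i, j] = h[j, i] = val
        else:
            i, j, k, l = i - 1, j - 1, k - 1, l - 1
            for (p, q, r, s) in (
                (i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
                (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i),
            ):
                eri[p, q, r, s] = val
    return MOSystem.from_integrals(
        h, eri, n_electrons=nelec, e_nuc=e_nuc, frozen=frozen, check=check,
        canonical_tol=canonical_tol,
    )


def write_fcidump(path, h: np.ndarray, eri: np.ndarray, n_electrons: int,
                  e_nuc: float = 0.0, tol: float = 0.0) -> None:
    """Write integrals in the Molpro FCIDUMP dialect (8-fold reduced records)."""
    norb = h.shape[0]
    with open(path, "w") as f:
        f.write(f"&FCI NORB={norb},NELEC={n_electrons},MS2=0,\n")
        f.write("  ORBSYM=" + ",".join(["1"] * norb) + ",\n  ISYM=1,\n&END\n")

        def pair_iter():
            for i in range(norb):
                for j in range(i + 1):
                    yield i, j

        pairs = list(pair_iter())
        for a, (i, j) in enumerate(pairs):
            for (k, l) in pairs[: a + 1]:
                v = eri[i, j, k, l]
                if abs(v) > tol:
                    f.write(f"{v:23.16E} {i+1:4d} {j+1:4d} {k+1:4d} {l+1:4d}\n")
        for i in range(norb):
            for j in range(i + 1):
                if abs(h[i, j]) > tol:
                    f.write(f"{h[i, j]:23.16E} {i+1:4d} {j+1:4d} {0:4d} {0:4d}\n")
        f.write(f"{e_nuc:23.16E} {0:4d} {0:4d} {0:4d} {0:4d}\n")


# ---------------------------------------------------------------------------
# Dipole-operator container (HDF5)
# ---------------------------------------------------------------------------


def save_dipole_h5(path, dipole: np.ndarray) -> None:
    """Store MO-basis dipole matrices in datasets ``dipole_x/y/z``."""
    import h5py

    with h5py.File(path, "w") as f:
        for axis, name in enumerate(("dipole_x", "dipole_y", "dipole_z")):
            f.create_dataset(name, data=np.asarray(dipole)[axis])


def load_dipole_h5(path) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as f:
        return np.array([f["dipole_x"][()], f["dipole_y"][()], f["dipole_z"][()]])
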