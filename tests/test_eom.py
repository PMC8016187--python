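"""EOM-CC3: transforms, intermediates, eigensolver, multipliers, CVS."""

import numpy as np
import pytest

from cc3kit import dense
from cc3kit._packing import n_packed, pack, unpack
from cc3kit.eom import (
    ExcitationVector,
    cvs_project,
    davidson_solve,
    eta_vector,
    excitation_overlap,
    jacobian_transform_left,
    jacobian_transform_right,
    prepare_jacobian_intermediates,
    solve_excited_states,
    solve_left_states,
    solve_multipliers,
)
from cc3kit.ground import Amplitudes, cc3_residual
from cc3kit.integrals import t1_transform
from cc3kit.oracles import (
    fci_solve,
    finite_difference_directional,
    load_fixture,
    synthetic_mosystem,
)
from conftest import random_doubles


class TestIntermediates:
    def test_zero_doubles_gives_zero_intermediates(self, tiny):
        zero = Amplitudes.zeros(tiny.sys.n_virt, tiny.sys.n_occ)
        ham = t1_transform(tiny.sys, zero.t1)
        inter = prepare_jacobian_intermediates(ham, zero)
        assert np.abs(inter.Z).max() == 0.0

    def test_two_path_equivalence(self, medium, rng):
        """The precomputed route equals recomputing inside the transform."""
        nv, no = medium.sys.n_virt, medium.sys.n_occ
        v = ExcitationVector(rng.standard_normal((nv, no)), random_doubles(rng, nv, no))
        fast = jacobian_transform_right(medium.ham, medium.amps, medium.inter, v, omega=0.1)
        slow = jacobian_transform_right(medium.ham, medium.amps, None, v, omega=0.1)
        assert np.abs(fast.x1 - slow.x1).max() < 1e-12
        assert np.abs(fast.x2 - slow.x2).max() < 1e-12

    def test_deterministic_rebuild(self, medium):
        a = prepare_jacobian_intermediates(medium.ham, medium.amps)
        b = prepare_jacobian_intermediates(medium.ham, medium.amps)
        assert np.array_equal(a.Z, b.Z)


class TestRightTransform:
    def test_eigen_relation(self, medium):
        sol = medium.right(2)
        for m in range(2):
            v = sol.vectors[m]
            out = jacobian_transform_right(
                medium.ham, medium.amps, medium.inter, v, omega=sol.omegas[m]
            )
            r = pack(out.x1 - sol.omegas[m] * v.x1, out.x2 - sol.omegas[m] * v.x2)
            assert np.linalg.norm(r) < 1e-7

    def test_matches_dense_oracle(self, rng):
        sys = synthetic_mosystem(2, 3, seed=5, interaction_scale=0.4)
        t1 = 0.1 * rng.standard_normal((3, 2))
        t2 = random_doubles(rng, 3, 2, 0.1)
        ham = t1_transform(sys, t1)
        amps = Amplitudes(t1, t2)
        inter = prepare_jacobian_intermediates(ham, amps)
        r1 = rng.standard_normal((3, 2))
        r2 = random_doubles(rng, 3, 2)
        out = jacobian_transform_right(ham, amps, inter, ExcitationVector(r1, r2), omega=0.3)
        d1, d2 = dense.dense_jacobian_transform(ham, t2, r1, r2, omega=0.3)
        assert np.abs(out.x1 - d1).max() < 1e-11
        assert np.abs(out.x2 - d2).max() < 1e-11

    def test_finite_difference_consistency(self, tiny, rng):
        """J.v at omega=0 is the directional derivative of the residual."""
        nv, no = tiny.sys.n_virt, tiny.sys.n_occ
        r1 = rng.standard_normal((nv, no))
        r2 = random_doubles(rng, nv, no)
        out = jacobian_transform_right(
            tiny.ham, tiny.amps, tiny.inter, ExcitationVector(r1, r2)
        )

        def f(z):
            x1, x2 = unpack(z, nv, no)
            ham = t1_transform(tiny.sys, x1)
            res = cc3_residual(ham, Amplitudes(x1, x2))
            return pack(res.omega1, res.omega2)

        z0 = pack(tiny.amps.t1, tiny.amps.t2)
        d = pack(r1, r2)
        deriv, order = finite_difference_directional(f, z0, d, [4e-4, 2e-4, 1e-4, 5e-5])
        assert abs(order - 2.0) < 0.2
        assert np.abs(deriv - pack(out.x1, out.x2)).max() < 1e-6


class TestLeftTransform:
    def test_adjoint_identity(self, medium, rng):
        nv, no = medium.sys.n_virt, medium.sys.n_occ
        for _ in range(20):
            r1 = rng.standard_normal((nv, no))
            r2 = random_doubles(rng, nv, no)
            u1 = rng.standard_normal((nv, no))
            u2 = random_doubles(rng, nv, no)
            jr = jacobian_transform_right(
                medium.ham, medium.amps, medium.inter, ExcitationVector(r1, r2), omega=0.2
            )
            jl = jacobian_transform_left(
                medium.ham, medium.amps, medium.inter,
                ExcitationVector(u1, u2, side="left"), omega=0.2,
            )
            lhs = np.sum(u1 * jr.x1) + np.sum(u2 * jr.x2)
            rhs = np.sum(jl.x1 * r1) + np.sum(jl.x2 * r2)
            scale = np.linalg.norm(pack(u1, u2)) * np.linalg.norm(pack(r1, r2))
            assert abs(lhs - rhs) <= 1e-11 * scale

    def test_left_eigen_relation(self, medium):
        right = medium.right(2)
        left = medium.left(2)
        for m in range(2):
            v = left.vectors[m]
            out = jacobian_transform_left(
                medium.ham, medium.amps, medium.inter, v, omega=left.omegas[m]
            )
            r = pack(out.x1 - left.omegas[m] * v.x1, out.x2 - left.omegas[m] * v.x2)
            assert np.linalg.norm(r) < 1e-7

    def test_matches_dense_transpose(self, rng):
        sys = synthetic_mosystem(2, 3, seed=5, interaction_scale=0.4)
        t1 = 0.1 * rng.standard_normal((3, 2))
        t2 = random_doubles(rng, 3, 2, 0.1)
        ham = t1_transform(sys, t1)
        amps = Amplitudes(t1, t2)
        inter = prepare_jacobian_intermediates(ham, amps)
        ref = dense.DenseCC3Reference.__new__(dense.DenseCC3Reference)
        ref.sys, ref.triples, ref.t1, ref.t2, ref.ham = sys, True, t1, t2, ham
        J = ref.jacobian_matrix(0.25)
        u1 = rng.standard_normal((3, 2))
        u2 = random_doubles(rng, 3, 2)
        out = jacobian_transform_left(
            ham, amps, inter, ExcitationVector(u1, u2, side="left"), omega=0.25
        )
        # adjoint w.r.t. the full-sum pairing in packed coordinates
        from cc3kit._packing import pack_weights

        w = pack_weights(3, 2)
        ref_vec = J.T @ (w * pack(u1, u2)) / w
        assert np.abs(pack(out.x1, out.x2) - ref_vec).max() < 1e-11

    def test_cholesky_contraction_path_equivalent(self, medium, rng):
        """The four-virtual contraction through Cholesky factors matches."""
        from cc3kit.integrals import cholesky_decompose

        nv, no = medium.sys.n_virt, medium.sys.n_occ
        # dressed Cholesky factors: L~J = A LJ B^T
        ch = cholesky_decompose(medium.sys.eri, threshold=1e-12)
        n = medium.sys.n_orb
        A = np.eye(n); A[no:, :no] -= medium.amps.t1
        B = np.eye(n); B[:no, no:] += medium.amps.t1.T
        dressed = np.array([A @ L @ B.T for L in ch.vectors])
        u1 = rng.standard_normal((nv, no))
        u2 = random_doubles(rng, nv, no)
        a = jacobian_transform_left(
            medium.ham, medium.amps, medium.inter,
            ExcitationVector(u1, u2, side="left"),
        )
        b = jacobian_transform_left(
            medium.ham, medium.amps, medium.inter,
            ExcitationVector(u1, u2, side="left"), cholesky=dressed,
        )
        assert np.abs(a.x1 - b.x1).max() < 1e-9
        assert np.abs(a.x2 - b.x2).max() < 1e-12


class TestEta:
    def test_two_electron_system_reduces_to_doubles_only_path(self, h2dz):
        """With two electrons the triples vanish and eta is the plain
        singles/doubles energy gradient."""
        eta = eta_vector(h2dz.ham, h2dz.amps)
        de1, de2 = dense.dense_eta(h2dz.ham, h2dz.amps.t2)
        assert np.abs(eta.eta1 - de1).max() < 1e-12
        assert np.abs(eta.eta2 - de2).max() < 1e-12

    def test_finite_difference_of_energy(self, tiny, rng):
        from cc3kit.ground import cc3_energy

        nv, no = tiny.sys.n_virt, tiny.sys.n_occ
        eta = eta_vector(tiny.ham, tiny.amps)
        r1 = rng.standard_normal((nv, no))
        r2 = random_doubles(rng, nv, no)

        def f(z):
            x1, x2 = unpack(z, nv, no)
            return np.array([cc3_energy(t1_transform(tiny.sys, x1), x2)])

        z0 = pack(tiny.amps.t1, tiny.amps.t2)
        deriv, order = finite_difference_directional(
            f, z0, pack(r1, r2), [4e-4, 2e-4, 1e-4]
        )
        ref = np.sum(eta.eta1 * r1) + np.sum(eta.eta2 * r2)
        assert abs(deriv[0] - ref) < 1e-7

    def test_fock_only_hamiltonian(self):
        """With U = 0 and t = 0 the gradient has no two-electron content."""
        sys = synthetic_mosystem(2, 3, seed=2, interaction_scale=0.0)
        ham = t1_transform(sys, np.zeros((3, 2)))
        eta = eta_vector(ham, Amplitudes.zeros(3, 2))
        assert np.abs(eta.eta1).max() < 1e-12  # F_ov = 0 for canonical ref
        assert np.abs(eta.eta2).max() < 1e-14


class TestMultipliers:
    def test_defining_equation(self, medium):
        lam = medium.lam
        eta = eta_vector(medium.ham, medium.amps)
        res = jacobian_transform_left(
            medium.ham, medium.amps, medium.inter,
            ExcitationVector(lam.lambda1, lam.lambda2, side="left"),
        )
        assert np.abs(eta.eta1 + res.x1).max() < 1e-9
        assert np.abs(eta.eta2 + res.x2).max() < 1e-9

    def test_matches_dense_linear_solve(self, tiny):
        ref = dense.dense_cc3_reference(tiny.sys)
        dl1, dl2 = ref.multipliers()
        lam = tiny.lam
        assert np.abs(lam.lambda1 - dl1).max() < 1e-9
        assert np.abs(lam.lambda2 - dl2).max() < 1e-9

    def test_two_electron_expectation_matches_fci(self, h2):
        """The Lambda-state dipole expectation equals the FCI value."""
        from cc3kit.densities import ground_state_density

        D = ground_state_density(h2.ham, h2.amps, h2.lam)
        fci = fci_solve(h2.sys)
        for q in range(3):
            Aop = h2.sys.dipole[q]
            ref = float(
                fci.vectors[:, 0] @ (fci.space.one_body(Aop) @ fci.vectors[:, 0])
            )
            assert abs(D.expectation(Aop) - ref) < 1e-8


class TestDavidson:
    def test_diagonal_operator(self):
        diag = np.array([3.0, 1.0, 2.0, 5.0, 0.5, 4.0])
        guesses = [np.eye(6)[i] for i in np.argsort(diag)[:3]]
        vals, vecs, its, norms = davidson_solve(
            lambda z: diag * z, diag, guesses, n_roots=3, conv=1e-10
        )
        assert np.abs(vals - np.array([0.5, 1.0, 2.0])).max() < 1e-12

    def test_left_right_spectral_agreement(self, medium):
        right = medium.right(3)
        left = medium.left(3)
        assert np.abs(right.omegas - left.omegas).max() < 1e-8

    def test_eigenvalues_match_dense_oracle(self, tiny):
        sol = solve_excited_states(
            tiny.ham, tiny.amps, tiny.inter, n_roots=3, conv=1e-9
        )
        ref = dense.dense_cc3_reference(tiny.sys)
        dvals = ref.eigenvalues(4)
        for w in sol.omegas:
            assert min(abs(dvals - w)) < 1e-8

    def test_ccsd_restart_reaches_same_roots(self, tiny):
        a = solve_excited_states(tiny.ham, tiny.amps, tiny.inter, n_roots=2, conv=1e-8)
        b = solve_excited_states(
            tiny.ham, tiny.amps, tiny.inter, n_roots=2, conv=1e-8, guesses="ccsd"
        )
        assert np.abs(a.omegas - b.omegas).max() < 1e-7


class TestBiorthonormality:
    def test_overlap_matrix_is_identity(self, medium):
        right = medium.right(3)
        left = medium.left(3)
        n = 3
        S = np.zeros((n, n))
        for m in range(n):
            for k in range(n):
                S[m, k] = excitation_overlap(
                    medium.ham, medium.amps, left.vectors[m], right.vectors[k],
                    left.omegas[m], right.omegas[k],
                )
        S = S / np.diag(S)[:, None]
        assert np.abs(S - np.eye(n)).max() < 1e-8


class TestCVS:
    def test_projector_idempotent(self, medium, rng):
        nv, no = medium.sys.n_virt, medium.sys.n_occ
        v = ExcitationVector(rng.standard_normal((nv, no)), random_doubles(rng, nv, no))
        p1 = cvs_project(v, [0])
        p2 = cvs_project(p1, [0])
        assert np.abs(p1.x1 - p2.x1).max() == 0.0
        assert np.abs(p1.x2 - p2.x2).max() == 0.0

    def test_valence_components_annihilated(self, medium, rng):
        nv, no = medium.sys.n_virt, medium.sys.n_occ
        x1 = rng.standard_normal((nv, no))
        x1[:, 0] = 0.0
        x2 = random_doubles(rng, nv, no)
        x2[:, 0, :, :] = 0.0
        x2[:, :, :, 0] = 0.0
        p = cvs_project(ExcitationVector(x1, x2), [0])
        assert np.abs(p.x1).max() == 0.0 and np.abs(p.x2).max() == 0.0

    def test_core_index_out_of_range(self, medium):
        v = ExcitationVector(
            np.zeros((medium.sys.n_virt, medium.sys.n_occ)),
            np.zeros((medium.sys.n_virt, medium.sys.n_occ) * 2),
        )
        with pytest.raises(IndexError):
            cvs_project(v, [medium.sys.n_occ])

    def test_cvs_eigenvalues_match_projected_dense_jacobian(self, medium):
        core = [0]
        inter = prepare_jacobian_intermediates(medium.ham, medium.amps, core_occ=core)
        sol = solve_excited_states(
            medium.ham, medium.amps, inter, n_roots=2, conv=1e-9, core_occ=core
        )
        nv, no = medium.sys.n_virt, medium.sys.n_occ
        pv = cvs_project(
            ExcitationVector(np.ones((nv, no)), np.ones((nv, no, nv, no))), core
        )
        keep = pack(pv.x1, pv.x2) != 0.0
        dim = n_packed(nv, no)
        for w in sol.omegas:
            J = np.empty((dim, dim))
            for q in range(dim):
                e = np.zeros(dim)
                e[q] = 1.0
                r1, r2 = unpack(e, nv, no)
                s1, s2 = dense.dense_jacobian_transform(
                    medium.ham, medium.amps.t2, r1, r2, omega=w, cvs_core=core
                )
                J[:, q] = pack(s1, s2)
            ev = np.sort(np.linalg.eigvals(J[np.ix_(keep, keep)]).real)
            assert min(abs(ev - w)) < 1e-8

    def test_loop_cycling_reduces_trip_count(self):
        from cc3kit.ground import occupied_triples

        no = 6
        full = len(list(occupied_triples(no)))
        cvs = len(list(occupied_triples(no, [0])))
        # one core orbital: O(n_occ^2) trips instead of O(n_occ^3)
        assert cvs < full
        assert cvs <= no * (no + 1) // 2 + 1


class TestTwoElectronExactness:
    def test_eom_equals_fci_singlets(self, h2dz):
        sol = h2dz.right(3)
        fci = fci_solve(h2dz.sys)
        ex = fci.singlet_excitations()
        for w in sol.omegas:
            assert min(abs(ex - w)) < 1e-8
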