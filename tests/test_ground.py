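"""Blocked CC3 ground state: triples blocks, residuals, solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cc3kit import dense
from cc3kit.ground import (
    Amplitudes,
    ReorderedIntegrals,
    TriplesBlock,
    biorthonormal_residual,
    build_t3_block,
    cc3_residual,
    ccsd_residual,
    contravariant_triples,
    covariant_residual,
    load_checkpoint,
    save_checkpoint,
    solve_ground_state,
    triples_denominator,
)
from cc3kit.integrals import t1_transform
from cc3kit.oracles import (
    det_cc3_residual,
    det_space,
    fci_solve,
    load_fixture,
    synthetic_mosystem,
)
from conftest import random_doubles


class TestTriplesDenominator:
    def test_direct_sum(self):
        eps = np.array([-1.0, -0.5, 0.3, 0.7])
        blk = triples_denominator(eps, (1, 1, 1), no=2, on_degenerate="warn")
        # entry (a,b,c) = (0,0,0): 3*0.3 - 3*(-0.5)
        assert abs(blk.eps3[0, 0, 0] - (3 * 0.3 + 3 * 0.5)) < 1e-14

    def test_degenerate_limit_flagged(self):
        eps = np.zeros(4)
        with pytest.raises(ZeroDivisionError):
            triples_denominator(eps, (1, 0, 0), no=2)
        with pytest.warns(UserWarning, match="degenerate"):
            blk = triples_denominator(eps, (1, 0, 0), no=2, on_degenerate="warn")
        assert np.abs(blk.eps3).max() == 0.0

    def test_elementwise_oracle(self, rng):
        eps = rng.standard_normal(7)
        no = 3
        blk = triples_denominator(eps, (2, 1, 0), no=no, on_degenerate="warn")
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    ref = eps[no + a] + eps[no + b] + eps[no + c] - eps[2] - eps[1] - eps[0]
                    assert abs(blk.eps3[a, b, c] - ref) < 1e-14


class TestTriplesBlocks:
    def test_zero_doubles_gives_zero_block(self, tiny):
        ham = tiny.ham
        blk = build_t3_block(
            ham, np.zeros_like(tiny.amps.t2), (1, 0, 0),
            triples_denominator(ham.eps, (1, 0, 0), no=2),
        )
        assert np.abs(blk.W).max() == 0.0

    def test_blocks_match_full_tensor_oracle(self, rng):
        sys = synthetic_mosystem(2, 3, seed=3, interaction_scale=0.4)
        t1 = 0.1 * rng.standard_normal((3, 2))
        t2 = random_doubles(rng, 3, 2, 0.1)
        ham = t1_transform(sys, t1)
        full = dense.dense_tau3(ham, t2)
        ints = ReorderedIntegrals.from_ham(ham)
        for ijk in [(1, 0, 0), (1, 1, 0)]:
            blk = build_t3_block(ham, t2, ijk, triples_denominator(ham.eps, ijk, 2), ints=ints)
            i, j, k = ijk
            assert np.abs(blk.W - full[:, i, :, j, :, k]).max() < 1e-13

    def test_linearity_in_doubles(self, tiny, rng):
        ham = tiny.ham
        t2 = random_doubles(rng, 3, 2)
        d = triples_denominator(ham.eps, (1, 0, 0), no=2)
        b1 = build_t3_block(ham, t2, (1, 0, 0), d)
        b2 = build_t3_block(ham, 2.5 * t2, (1, 0, 0), d)
        assert np.abs(b2.W - 2.5 * b1.W).max() < 1e-12

    def test_unsorted_triple_rejected(self, tiny):
        with pytest.raises(ValueError, match="i >= j >= k"):
            build_t3_block(tiny.ham, tiny.amps.t2, (0, 1, 0), None)


class TestContravariantTriples:
    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 100))
    def test_linear_map(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((3, 3, 3))
        a = contravariant_triples(TriplesBlock((1, 0, 0), W)).W
        b = contravariant_triples(TriplesBlock((1, 0, 0), 3.0 * W)).W
        assert np.abs(b - 3.0 * a).max() < 1e-12

    def test_coefficients_sum_to_zero_on_constant_tensor(self):
        W = np.ones((4, 4, 4))
        out = contravariant_triples(TriplesBlock((1, 0, 0), W)).W
        assert np.abs(out).max() < 1e-14

    def test_pipeline_equivalence_of_residual_conventions(self, tiny):
        """Covariant projection and its back-transform invert each other."""
        res = cc3_residual(tiny.ham, tiny.amps)
        cov = covariant_residual(res)
        back = biorthonormal_residual(cov)
        assert np.abs(back.omega1 - res.omega1).max() < 1e-14
        assert np.abs(back.omega2 - res.omega2).max() < 1e-14
        assert cov.variance == "covariant"
        # the covariant doubles keep the pair-exchange symmetry
        assert np.abs(cov.omega2 - cov.omega2.transpose(2, 3, 0, 1)).max() < 1e-12


class TestCCSDResidual:
    def test_zero_amplitude_limit(self, tiny):
        sys = tiny.sys
        no, nv = sys.n_occ, sys.n_virt
        ham = t1_transform(sys, np.zeros((nv, no)))
        res = ccsd_residual(ham, Amplitudes.zeros(nv, no))
        assert np.abs(res.omega1 - sys.fock[no:, :no]).max() < 1e-14
        assert np.abs(res.omega2 - sys.eri[no:, :no, no:, :no]).max() < 1e-14

    def test_fixed_point_on_two_electron_fixture(self, h2dz):
        """At converged amplitudes of a 2-electron system, CCSD is stationary."""
        res = ccsd_residual(h2dz.ham, h2dz.amps)
        assert res.max_norm() < 1e-9

    def test_matches_determinant_oracle(self, rng):
        sys = synthetic_mosystem(3, 3, seed=5, interaction_scale=0.4)
        sp = det_space(sys.n_orb, sys.n_occ)
        t1 = 0.1 * rng.standard_normal((3, 3))
        t2 = random_doubles(rng, 3, 3, 0.1)
        ham = t1_transform(sys, t1)
        _, o1, o2, _ = det_cc3_residual(sp, ham, t2, triples=False)
        res = ccsd_residual(ham, Amplitudes(t1, t2))
        assert np.abs(res.omega1 - o1).max() < 1e-12
        assert np.abs(res.omega2 - o2).max() < 1e-12


class TestCC3Residual:
    def test_two_electron_limit_equals_ccsd(self, h2dz, rng):
        t2 = random_doubles(rng, 3, 1, 0.1)
        amps = Amplitudes(0.1 * rng.standard_normal((3, 1)), t2)
        ham = t1_transform(h2dz.sys, amps.t1)
        a = cc3_residual(ham, amps)
        b = ccsd_residual(ham, amps)
        assert np.abs(a.omega1 - b.omega1).max() == 0.0
        assert np.abs(a.omega2 - b.omega2).max() == 0.0

    def test_matches_full_tensor_oracle(self, rng):
        sys = synthetic_mosystem(3, 4, seed=2, interaction_scale=0.4)
        t1 = 0.1 * rng.standard_normal((4, 3))
        t2 = random_doubles(rng, 4, 3, 0.1)
        ham = t1_transform(sys, t1)
        res = cc3_residual(ham, Amplitudes(t1, t2))
        d1, d2 = dense.dense_residual(ham, t2)
        assert np.abs(res.omega1 - d1).max() < 1e-12
        assert np.abs(res.omega2 - d2).max() < 1e-12

    def test_matches_determinant_oracle_with_triples(self, rng):
        sys = synthetic_mosystem(3, 3, seed=8, interaction_scale=0.4)
        sp = det_space(sys.n_orb, sys.n_occ)
        t1 = 0.1 * rng.standard_normal((3, 3))
        t2 = random_doubles(rng, 3, 3, 0.1)
        ham = t1_transform(sys, t1)
        _, o1, o2, _ = det_cc3_residual(sp, ham, t2, triples=True)
        res = cc3_residual(ham, Amplitudes(t1, t2))
        assert np.abs(res.omega1 - o1).max() < 1e-12
        assert np.abs(res.omega2 - o2).max() < 1e-12

    def test_fixed_point_at_convergence(self, medium):
        assert cc3_residual(medium.ham, medium.amps).max_norm() < 1e-10


class TestGroundSolver:
    def test_h2_equals_fci(self, h2):
        fci = fci_solve(h2.sys)
        assert abs(h2.energy - fci.energies[0]) < 1e-9

    def test_no_fluctuation_potential_no_correlation(self):
        sys = synthetic_mosystem(2, 3, seed=1, interaction_scale=0.0)
        from cc3kit.integrals import hf_energy

        amps, energy, _ = solve_ground_state(sys, conv=1e-10)
        assert abs(energy - hf_energy(sys)) < 1e-10
        assert np.abs(amps.t2).max() < 1e-10

    def test_matches_dense_reference(self, medium):
        ref = dense.dense_cc3_reference(medium.sys)
        assert abs(medium.energy - ref.energy) < 1e-10

    def test_energy_invariant_under_degenerate_occupied_rotation(self):
        """Rotating two degenerate occupied orbitals leaves E unchanged."""
        sys = synthetic_mosystem(2, 3, seed=21, interaction_scale=0.3)
        # force occupied degeneracy, then recompute the one-electron part
        eps = sys.eps.copy()
        eps[1] = eps[0]
        from cc3kit.contractions import contract
        from cc3kit.integrals import MOSystem

        no = 2
        o = slice(0, no)
        h = np.diag(eps) - 2.0 * contract("pqii->pq", sys.eri[:, :, o, o]) + contract(
            "piiq->pq", sys.eri[:, o, o, :]
        )
        base = MOSystem.from_integrals(h, sys.eri, n_electrons=4)
        th = 0.37
        U = np.eye(sys.n_orb)
        U[:2, :2] = [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        h2_ = U.T @ base.h @ U
        eri2 = np.einsum("pi,qj,rk,sl,pqrs->ijkl", U, U, U, U, base.eri, optimize=True)
        rot = MOSystem.from_integrals(h2_, eri2, n_electrons=4)
        _, e1, _ = solve_ground_state(base, conv=1e-10)
        _, e2, _ = solve_ground_state(rot, conv=1e-10)
        assert abs(e1 - e2) < 1e-9

    def test_nonconvergence_reports_history(self):
        sys = synthetic_mosystem(2, 3, seed=1, interaction_scale=0.4)
        with pytest.raises(RuntimeError, match="residual history"):
            solve_ground_state(sys, conv=1e-14, max_iter=2)

    def test_checkpoint_roundtrip(self, tiny, tmp_path):
        p = tmp_path / "chk.h5"
        save_checkpoint(p, tiny.amps, tiny.energy)
        back = load_checkpoint(p)
        assert np.abs(back.t1 - tiny.amps.t1).max() == 0.0
        assert np.abs(back.t2 - tiny.amps.t2).max() == 0.0


class TestPackingProperties:
    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_pack_unpack_roundtrip(self, seed):
        from cc3kit._packing import pack, unpack

        rng = np.random.default_rng(seed)
        nv, no = int(rng.integers(1, 5)), int(rng.integers(1, 4))
        x1 = rng.standard_normal((nv, no))
        x2 = rng.standard_normal((nv, no, nv, no))
        x2 = x2 + x2.transpose(2, 3, 0, 1)
        y1, y2 = unpack(pack(x1, x2), nv, no)
        assert np.abs(y1 - x1).max() == 0.0
        assert np.abs(y2 - x2).max() < 1e-15

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_full_dot_matches_unrestricted_sum(self, seed):
        from cc3kit._packing import full_dot, pack

        rng = np.random.default_rng(seed)
        nv, no = 3, 2
        a1 = rng.standard_normal((nv, no))
        a2 = rng.standard_normal((nv, no, nv, no))
        a2 = a2 + a2.transpose(2, 3, 0, 1)
        b1 = rng.standard_normal((nv, no))
        b2 = rng.standard_normal((nv, no, nv, no))
        b2 = b2 + b2.transpose(2, 3, 0, 1)
        ref = float(np.sum(a1 * b1) + np.sum(a2 * b2))
        assert abs(full_dot(pack(a1, a2), pack(b1, b2), nv, no) - ref) < 1e-12
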