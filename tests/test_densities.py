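"""Densities, transition moments and spectra."""

import numpy as np
import pytest

from cc3kit.densities import (
    DensityMatrix,
    PropertyOperator,
    SpectrumLine,
    ground_state_density,
    left_transition_density,
    lorentzian_spectrum,
    oscillator_strength,
    right_transition_density,
    transition_strength,
)
from cc3kit.eom import ExcitationVector, MultiplierVector, excitation_overlap
from cc3kit.ground import Amplitudes
from cc3kit.integrals import t1_transform
from cc3kit.oracles import det_cc3_solve, fci_solve, synthetic_mosystem


def biorthonormal_pair(solved, m):
    """Normalized (L_m, R_m with reference weight) for state m."""
    right = solved.right(m + 1)
    left = solved.left(m + 1)
    w = right.omegas[m]
    L, R = left.vectors[m], right.vectors[m]
    s = excitation_overlap(solved.ham, solved.amps, L, R, w, w)
    R = ExcitationVector(R.x1 / s, R.x2 / s, "right")
    lam_vec = ExcitationVector(solved.lam.lambda1, solved.lam.lambda2, side="left")
    R.ref_weight = -excitation_overlap(solved.ham, solved.amps, lam_vec, R, 0.0, w)
    return w, L, R


class TestGroundStateDensity:
    def test_hartree_fock_limit(self, tiny):
        """With t = lambda = 0 the density is twice the occupied identity."""
        nv, no = tiny.sys.n_virt, tiny.sys.n_occ
        ham = t1_transform(tiny.sys, np.zeros((nv, no)))
        D = ground_state_density(
            ham, Amplitudes.zeros(nv, no),
            MultiplierVector(np.zeros((nv, no)), np.zeros((nv, no, nv, no))),
        )
        ref = np.diag([2.0] * no + [0.0] * nv)
        assert np.abs(D.D - ref).max() < 1e-14

    @pytest.mark.parametrize("variant", ["eom", "response"])
    def test_trace_equals_electron_count(self, medium, variant):
        D = ground_state_density(medium.ham, medium.amps, medium.lam, variant=variant)
        assert abs(D.trace() - medium.sys.n_electrons) < 1e-8

    def test_finite_field_derivative(self, tiny):
        """Tr(D A) equals dE/dalpha with O(alpha^2) error decay."""
        rng = np.random.default_rng(5)
        n = tiny.sys.n_orb
        Aop = rng.standard_normal((n, n))
        Aop = (Aop + Aop.T) / 2
        D = ground_state_density(tiny.ham, tiny.amps, tiny.lam, variant="response")
        analytic = D.expectation(Aop)
        errs = []
        for alpha in (2e-3, 1e-3, 5e-4):
            Ep, *_ = det_cc3_solve(
                tiny.sys.with_perturbation(Aop, alpha), conv=1e-13, noncanonical=True
            )
            Em, *_ = det_cc3_solve(
                tiny.sys.with_perturbation(Aop, -alpha), conv=1e-13, noncanonical=True
            )
            errs.append((Ep - Em) / (2 * alpha) - analytic)
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        assert all(abs(r - 4.0) < 0.3 for r in ratios), (errs, ratios)


class TestTransitionDensities:
    def test_two_electron_strengths_match_fci(self, h2dz):
        A = PropertyOperator(h2dz.sys.dipole)
        fci = fci_solve(h2dz.sys)
        D00 = ground_state_density(h2dz.ham, h2dz.amps, h2dz.lam)
        fci_ex = fci.excitation_energies()
        for m in range(2):
            w, L, R = biorthonormal_pair(h2dz, m)
            Dm0 = right_transition_density(h2dz.ham, h2dz.amps, L, w)
            D0m = left_transition_density(h2dz.ham, h2dz.amps, h2dz.lam, R, D00, w)
            S = transition_strength(Dm0, D0m, A)
            k = int(np.argmin(np.abs(fci_ex - w))) + 1
            assert abs(S - fci.transition_strength(h2dz.sys.dipole, k)) < 1e-8

    def test_biorthogonal_rescaling_invariance(self, tiny):
        w, L, R = biorthonormal_pair(tiny, 0)
        A = PropertyOperator(tiny.sys.dipole)
        D00 = ground_state_density(tiny.ham, tiny.amps, tiny.lam)
        c = 1.7
        Lc = ExcitationVector(c * L.x1, c * L.x2, "left")
        Rc = ExcitationVector(R.x1 / c, R.x2 / c, "right", ref_weight=R.ref_weight / c)
        Dm0 = right_transition_density(tiny.ham, tiny.amps, L, w)
        Dm0c = right_transition_density(tiny.ham, tiny.amps, Lc, w)
        assert np.abs(Dm0c.D - c * Dm0.D).max() < 1e-10
        D0m = left_transition_density(tiny.ham, tiny.amps, tiny.lam, R, D00, w)
        D0mc = left_transition_density(tiny.ham, tiny.amps, tiny.lam, Rc, D00, w)
        s = transition_strength(Dm0, D0m, A)
        sc = transition_strength(Dm0c, D0mc, A)
        assert abs(s - sc) < 1e-9 * max(1.0, abs(s))

    def test_null_excitation_block(self, tiny):
        """With R = 0 only the reference weight times D00 survives."""
        D00 = ground_state_density(tiny.ham, tiny.amps, tiny.lam)
        nv, no = tiny.sys.n_virt, tiny.sys.n_occ
        R0 = ExcitationVector(
            np.zeros((nv, no)), np.zeros((nv, no, nv, no)), "right", ref_weight=0.6
        )
        D = left_transition_density(tiny.ham, tiny.amps, tiny.lam, R0, D00, 0.3)
        assert np.abs(D.D - 0.6 * D00.D).max() < 1e-12


class TestOscillatorStrength:
    def test_null_operator(self, tiny):
        n = tiny.sys.n_orb
        A = PropertyOperator(np.zeros((3, n, n)))
        D = DensityMatrix(np.ones((n, n)), "right_transition")
        line = oscillator_strength(0.5, D, D, A)
        assert line.f == 0.0
        assert abs(line.omega_ev - 0.5 * 27.211386) < 1e-10

    def test_negative_value_warns_not_raises(self, tiny):
        n = tiny.sys.n_orb
        A = PropertyOperator(np.tile(np.eye(n), (3, 1, 1)))
        Dp = DensityMatrix(np.eye(n), "right_transition")
        Dm = DensityMatrix(-np.eye(n), "left_transition")
        with pytest.warns(UserWarning, match="negative"):
            line = oscillator_strength(0.5, Dp, Dm, A)
        assert line.f < 0


class TestLorentzianSpectrum:
    def test_single_line_peak_and_width(self):
        line = SpectrumLine(omega_ev=10.0, f=0.5)
        spec = lorentzian_spectrum([line], width=0.5, shift=0.25, npoints=40001)
        imax = int(np.argmax(spec.intensity))
        assert abs(spec.grid_ev[imax] - 10.25) < 1e-3
        peak = spec.intensity[imax]
        assert abs(peak - 2 * 0.5 / (np.pi * 0.5)) < 1e-3
        half = peak / 2
        above = spec.grid_ev[spec.intensity >= half]
        assert abs((above[-1] - above[0]) - 0.5) < 2e-3  # FWHM = width

    def test_area_normalization(self):
        lines = [SpectrumLine(5.0, 0.3), SpectrumLine(6.0, 0.7)]
        grid = np.linspace(-495.0, 505.0, 400001)
        spec = lorentzian_spectrum(lines, width=0.4, grid=grid)
        integral = np.trapezoid(spec.intensity, grid)
        assert abs(integral - 1.0) < 1e-3

    def test_linearity(self):
        l1 = SpectrumLine(5.0, 0.3)
        l2 = SpectrumLine(5.2, 0.6)
        grid = np.linspace(3, 7, 101)
        a = lorentzian_spectrum([l1], width=0.5, grid=grid).intensity
        b = lorentzian_spectrum([l2], width=0.5, grid=grid).intensity
        ab = lorentzian_spectrum([l1, l2], width=0.5, grid=grid).intensity
        assert np.abs(ab - a - b).max() < 1e-12

    def test_empty_line_list(self):
        spec = lorentzian_spectrum([], width=0.5)
        assert spec.grid_ev.size == 0

    def test_width_must_be_positive(self):
        with pytest.raises(ValueError):
            lorentzian_spectrum([], width=0.0)
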