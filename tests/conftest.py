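"""Shared fixtures: converged CC3 states on tiny systems, built once."""

import numpy as np
import pytest

from cc3kit import (
    Amplitudes,
    prepare_jacobian_intermediates,
    solve_excited_states,
    solve_ground_state,
    solve_left_states,
    solve_multipliers,
    synthetic_mosystem,
    t1_transform,
)
from cc3kit.oracles import load_fixture


class SolvedSystem:
    """Converged ground state (and lazily, excited states) of one system."""

    def __init__(self, sys, conv=1e-10):
        self.sys = sys
        self.amps, self.energy, self.info = solve_ground_state(sys, conv=conv)
        self.ham = t1_transform(sys, self.amps.t1)
        self._inter = None
        self._lam = None
        self._right = {}
        self._left = {}

    @property
    def inter(self):
        if self._inter is None:
            self._inter = prepare_jacobian_intermediates(self.ham, self.amps)
        return self._inter

    @property
    def lam(self):
        if self._lam is None:
            self._lam = solve_multipliers(self.ham, self.amps, self.inter, conv=1e-10)
        return self._lam

    def right(self, n_roots, conv=1e-9):
        key = (n_roots, conv)
        if key not in self._right:
            self._right[key] = solve_excited_states(
                self.ham, self.amps, self.inter, n_roots=n_roots, conv=conv
            )
        return self._right[key]

    def left(self, n_roots, conv=1e-9):
        key = (n_roots, conv)
        if key not in self._left:
            self._left[key] = solve_left_states(
                self.ham, self.amps, self.inter, self.right(n_roots, conv), conv=conv
            )
        return self._left[key]


@pytest.fixture(scope="session")
def h2():
    return SolvedSystem(load_fixture("h2_sto3g"), conv=1e-11)


@pytest.fixture(scope="session")
def h2dz():
    return SolvedSystem(load_fixture("h2_631g"), conv=1e-11)


@pytest.fixture(scope="session")
def he():
    return SolvedSystem(load_fixture("he_631g"), conv=1e-11)


@pytest.fixture(scope="session")
def tiny():
    """2 occupied / 3 virtual synthetic system with converged CC3."""
    return SolvedSystem(synthetic_mosystem(2, 3, seed=13, interaction_scale=0.4))


@pytest.fixture(scope="session")
def medium():
    """3 occupied / 4 virtual synthetic system with converged CC3."""
    return SolvedSystem(synthetic_mosystem(3, 4, seed=11, interaction_scale=0.3))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_doubles(rng, nv, no, scale=1.0):
    x = scale * rng.standard_normal((nv, no, nv, no))
    return x + x.transpose(2, 3, 0, 1)
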