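"""Neuron kernels: coupling term, pulse invariants, model equivalences."""

import math

import numpy as np
import pytest

from pcnnseg import (DEFAULT_KERNEL, LatticeState, ModelParams, StepSchedule,
                     neighborhood_sum, pcnn_iterate, spcnn_iterate,
                     varstep_iterate)
from pcnnseg.dynamics import ST_FLOOR


class TestNeighborhoodSum:
    def test_zero_field(self):
        assert np.all(neighborhood_sum(np.zeros((5, 5)), DEFAULT_KERNEL) == 0)

    def test_impulse_response_mirrors_kernel(self):
        y = np.zeros((5, 5))
        y[2, 2] = 1.0
        out = neighborhood_sum(y, DEFAULT_KERNEL)
        assert out[2, 2] == 0.0  # a neuron is not its own neighbor
        assert np.array_equal(out[1:4, 1:4], DEFAULT_KERNEL[::-1, ::-1])

    def test_interior_all_ones_gives_six(self):
        # total kernel weight 6: the constant in the automatic formulas
        out = neighborhood_sum(np.ones((7, 7)), DEFAULT_KERNEL)
        assert out[3, 3] == 6.0

    def test_border_zero_padded(self):
        out = neighborhood_sum(np.ones((7, 7)), DEFAULT_KERNEL)
        assert out[0, 0] == 2.5  # two direct + one diagonal neighbor remain

    def test_rejects_bad_kernels(self):
        with pytest.raises(ValueError):
            neighborhood_sum(np.ones((3, 3)), np.ones((5, 5)))
        with pytest.raises(ValueError):
            neighborhood_sum(np.ones((3, 3)), np.ones((3, 3)))  # nonzero center


class TestClassicPcnn:
    def test_no_stimulus_no_pulse(self):
        p = ModelParams.classic_defaults()
        state = LatticeState.zeros((8, 8))
        s = np.zeros((8, 8))
        for _ in range(50):
            state = pcnn_iterate(state, s, p)
            assert not state.y.any()

    def test_decoupled_lattice_is_permutation_equivariant(self):
        p = ModelParams.classic_defaults()
        p.beta = 0.0
        p.vf = 0.0  # remove pulse coupling entirely: pixels evolve independently
        rng = np.random.default_rng(0)
        s = rng.uniform(0.1, 1.0, (6, 6))
        perm = rng.permutation(36)
        s_perm = s.ravel()[perm].reshape(6, 6)
        a = LatticeState.zeros((6, 6))
        b = LatticeState.zeros((6, 6))
        for _ in range(30):
            a = pcnn_iterate(a, s, p)
            b = pcnn_iterate(b, s_perm, p)
        assert np.array_equal(a.y.ravel()[perm], b.y.ravel())

    def test_single_neuron_fires_periodically(self):
        p = ModelParams.classic_defaults()
        s = np.array([[0.7]])
        state = LatticeState.zeros((1, 1))
        pulses = []
        for _ in range(400):
            state = pcnn_iterate(state, s, p)
            pulses.append(int(state.y[0, 0]))
        tail = pulses[200:]
        periods = [q for q in range(1, 80)
                   if all(tail[i] == tail[i + q] for i in range(len(tail) - q))]
        assert periods, "pulse train should become exactly periodic after a transient"
        assert sum(tail) > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pcnn_iterate(LatticeState.zeros((4, 4)), np.zeros((5, 5)),
                         ModelParams.classic_defaults())


class TestSpcnn:
    def test_uncoupled_constant_stimulus_matches_geometric_series(self, auto_params):
        p = ModelParams.from_dict(auto_params.to_dict())
        p.beta = 0.0
        p.ve = 1e9  # keep the threshold out of the way after the first pulse
        c = 0.37
        s = np.full((4, 4), c)
        state = LatticeState.zeros((4, 4))
        q = math.exp(-p.af)
        for n in range(1, 51):
            state = spcnn_iterate(state, s, p)
            closed = c * (1 - q ** n) / (1 - q)
            assert abs(state.u[0, 0] - closed) < 1e-10

    def test_zero_stimulus_decays_to_zero(self, auto_params):
        state = LatticeState.zeros((4, 4))
        state.u = np.full((4, 4), 2.0)
        state.e = np.full((4, 4), 10.0)
        s = np.zeros((4, 4))
        for _ in range(200):
            state = spcnn_iterate(state, s, auto_params)
        assert np.all(state.u < 1e-10)

    def test_huge_threshold_suppresses_pulse(self, auto_params, random_stimulus):
        state = LatticeState.zeros(random_stimulus.shape)
        state.e = np.full(random_stimulus.shape, 1e9)
        state = spcnn_iterate(state, random_stimulus, auto_params)
        assert not state.y.any()

    def test_pulses_always_binary(self, auto_params, random_stimulus):
        state = LatticeState.zeros(random_stimulus.shape)
        for _ in range(60):
            state = spcnn_iterate(state, random_stimulus, auto_params)
            assert set(np.unique(state.y)) <= {0.0, 1.0}
            assert np.all(state.e >= 0.0)


class TestVarstep:
    def test_st_one_reduces_to_spcnn(self, auto_params, random_stimulus):
        a = LatticeState.zeros(random_stimulus.shape)
        b = LatticeState.zeros(random_stimulus.shape)
        for _ in range(100):
            a = spcnn_iterate(a, random_stimulus, auto_params)
            b = varstep_iterate(b, random_stimulus, auto_params, 1.0)
            assert np.abs(a.u - b.u).max() < 1e-10
            assert np.abs(a.e - b.e).max() < 1e-10
            assert np.array_equal(a.y, b.y)

    @pytest.mark.parametrize("st", [0.3, 0.6, 0.9])
    def test_constant_st_matches_first_order_oracle(self, st, auto_params,
                                                    random_stimulus):
        # oracle: direct first-order iteration with decay e^{-aF*ST}
        p, s = auto_params, random_stimulus
        q, r = math.exp(-p.af * st), math.exp(-p.ae * st)
        u = np.zeros_like(s)
        e = np.zeros_like(s)
        y = np.zeros_like(s)
        state = LatticeState.zeros(s.shape)
        for _ in range(100):
            u = s * (1 + p.beta * p.vl * neighborhood_sum(y, p.kernel_w)) + q * u
            e = r * e + p.ve * y
            y = (u > e).astype(float)
            state = varstep_iterate(state, s, p, st)
            assert np.abs(state.u - u).max() < 1e-10
            assert np.abs(state.e - e).max() < 1e-10
            assert np.array_equal(state.y, y)

    def test_quiescent_history_fixed_point(self, auto_params):
        c = 1.3
        state = LatticeState.zeros((3, 3))
        state.u = np.full((3, 3), c)
        state.u_prev = np.full((3, 3), c)
        state.e = np.full((3, 3), 10.0)
        state.n = 2  # histories populated, no pulses in them
        out = varstep_iterate(state, np.zeros((3, 3)), auto_params, 0.5)
        assert np.allclose(out.u, c)  # (1+q)c - qc = c

    def test_invalid_step_rejected(self, auto_params):
        state = LatticeState.zeros((3, 3))
        for st in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                varstep_iterate(state, np.zeros((3, 3)), auto_params, st)


class TestStepSchedule:
    def test_modes_validate(self):
        with pytest.raises(ValueError):
            StepSchedule.fixed(0.0)
        with pytest.raises(ValueError):
            StepSchedule(mode="sinusoidal", w=1.0, phi=4.0)  # phi > pi/w
        with pytest.raises(ValueError):
            StepSchedule.explicit([0.5, 1.2])

    def test_sinusoidal_matches_closed_form_and_floor(self):
        sched = StepSchedule.sinusoidal(w=1.5681, phi=0.3)
        for t in range(1, 200):
            exact = 0.5 * math.sin(1.5681 * t + 0.3) + 0.5
            assert abs(sched.st_at(t) - max(exact, ST_FLOOR)) == 0.0
            assert ST_FLOOR <= sched.st_at(t) <= 1.0

    def test_explicit_sequence_indexing(self):
        sched = StepSchedule.explicit([0.2, 0.7])
        assert sched.st_at(1) == 0.2 and sched.st_at(2) == 0.7
        with pytest.raises(ValueError):
            sched.st_at(3)


def test_synchronous_firing_on_two_band_phantom(two_band):
    """All pixels of the brighter band first fire in the same iteration."""
    from pcnnseg import estimate_stats, spcnn_auto_params

    p = spcnn_auto_params(estimate_stats(two_band.image))
    state = LatticeState.zeros(two_band.image.shape)
    bright = two_band.masks[1]
    first = np.zeros(two_band.image.shape, dtype=int)
    for n in range(1, 30):
        state = spcnn_iterate(state, two_band.image, p)
        if n >= 2:
            first = np.where((state.y > 0) & (first == 0), n, first)
    times = np.unique(first[bright])
    assert len(times) == 1 and times[0] > 0


def test_translation_equivariance_on_interior(auto_params):
    """Shifting the stimulus shifts the pulses identically on the interior.

    Influence propagates at most one pixel per iteration, so after 10
    iterations a 12-pixel margin is out of reach of both the zero padding
    and the wrapped column introduced by the roll.
    """
    rng = np.random.default_rng(3)
    s = rng.uniform(0.1, 1.0, (40, 40))
    s_shift = np.roll(s, 1, axis=1)
    a = LatticeState.zeros(s.shape)
    b = LatticeState.zeros(s.shape)
    for _ in range(10):
        a = spcnn_iterate(a, s, auto_params)
        b = spcnn_iterate(b, s_shift, auto_params)
    m = 12
    assert np.array_equal(a.y[m:-m, m - 1:-m - 1], b.y[m:-m, m:-m])
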