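"""Spin-state probabilities, lifetimes, oscillation and spectrum analysis."""

import math

import numpy as np
import pytest

from radicalpair.hamiltonians import SystemSpec
from radicalpair.lindblad_dynamics import DensityOperator, initial_pair_state
from radicalpair.observables import (
    TrajectoryResult,
    aggregate_blocks,
    block_lifetimes,
    coherence_lifetime,
    envelope_lifetime,
    oscillation_frequency,
    spin_state_probabilities,
    transition_spectrum,
)
from radicalpair.spin_algebra import enumerate_subspaces


def traj(times, ps, pt1, pt2, pt3, picture="interaction", **kw):
    return TrajectoryResult(times=np.asarray(times, float), p_singlet=np.asarray(ps),
                            p_t1=np.asarray(pt1), p_t2=np.asarray(pt2),
                            p_t3=np.asarray(pt3), picture=picture, **kw)


class TestProbabilities:
    def test_initial_singlet_state(self):
        rho = initial_pair_state(2, 3)
        assert spin_state_probabilities(rho) == pytest.approx((1, 0, 0, 0))

    def test_maximally_mixed_pair(self):
        rho = DensityOperator(np.eye(4, dtype=complex) / 4, dims=(2, 1, 2, 1))
        assert spin_state_probabilities(rho) == pytest.approx((0.25,) * 4)

    def test_t0_input(self):
        t0 = np.array([0, 1, 1, 0], dtype=complex) / np.sqrt(2)
        rho = DensityOperator(np.outer(t0, t0.conj()), dims=(2, 1, 2, 1))
        p = spin_state_probabilities(rho)
        assert p[2] == pytest.approx(1.0)

    def test_interaction_picture_rejected(self):
        rho = DensityOperator(np.eye(4, dtype=complex) / 4, dims=(2, 1, 2, 1),
                              picture="interaction")
        with pytest.raises(ValueError):
            spin_state_probabilities(rho)


class TestAggregation:
    def test_single_block_identity(self):
        t = np.linspace(0, 1, 5)
        series = np.vstack([np.full(5, 0.7), np.full(5, 0.1),
                            np.full(5, 0.1), np.full(5, 0.1)])
        tr = aggregate_blocks({(0.5, 0.5): series}, {(0.5, 0.5): 1.0}, t)
        assert np.allclose(tr.p_singlet, 0.7)

    def test_n2_weights_three_quarters_one_quarter(self):
        w = enumerate_subspaces(2).weights()
        assert w[1.0] == pytest.approx(0.75)
        assert w[0.0] == pytest.approx(0.25)

    def test_weight_sum_violation_rejected(self):
        t = np.linspace(0, 1, 3)
        s = np.vstack([np.ones(3), np.zeros(3), np.zeros(3), np.zeros(3)])
        with pytest.raises(ValueError):
            aggregate_blocks({"a": s, "b": s}, {"a": 0.6, "b": 0.6}, t)

    def test_normalization_invariant_enforced(self):
        t = np.linspace(0, 1, 3)
        with pytest.raises(ValueError):
            traj(t, np.full(3, 0.5), np.zeros(3), np.zeros(3), np.zeros(3))


class TestLifetime:
    def test_exponential_envelope_crosses_at_one_over_gamma(self):
        g = 5.0
        t = np.linspace(0, 3, 3001)
        ps = 0.5 + 0.5 * np.exp(-g * t)
        pt2 = 1 - ps
        tr = traj(t, ps, np.zeros_like(t), pt2, np.zeros_like(t))
        assert coherence_lifetime(tr) == pytest.approx(1 / g, rel=0.01)

    def test_censored_when_no_decay(self):
        t = np.linspace(0, 1, 50)
        tr = traj(t, np.ones(50), np.zeros(50), np.zeros(50), np.zeros(50))
        assert coherence_lifetime(tr) == math.inf

    def test_mixture_lifetime_is_weighted_mean_of_sectors(self):
        g_fast, g_slow = 50.0, 0.5
        t = np.linspace(0, 20, 20001)
        mk = lambda g: np.vstack([0.5 + 0.5 * np.exp(-g * t),
                                  np.zeros_like(t),
                                  0.5 - 0.5 * np.exp(-g * t),
                                  np.zeros_like(t)])
        tr = aggregate_blocks({"fast": mk(g_fast), "slow": mk(g_slow)},
                              {"fast": 0.8, "slow": 0.2}, t)
        per = block_lifetimes(tr)
        assert per["fast"] == pytest.approx(1 / g_fast, rel=0.05)
        assert per["slow"] == pytest.approx(1 / g_slow, rel=0.01)
        expected = 0.8 / g_fast + 0.2 / g_slow
        assert coherence_lifetime(tr) == pytest.approx(expected, rel=0.02)

    def test_schrodinger_picture_rejected(self):
        t = np.linspace(0, 1, 4)
        tr = traj(t, np.ones(4), np.zeros(4), np.zeros(4), np.zeros(4),
                  picture="schrodinger")
        with pytest.raises(ValueError):
            coherence_lifetime(tr)

    def test_envelope_robust_to_oscillation(self):
        # beating signal: envelope decay, not the first zero crossing
        g = 2.0
        t = np.linspace(0, 4, 8001)
        osc = np.exp(-g * t) * np.cos(2 * np.pi * 5 * t)
        ps = 0.5 + osc / 2
        tr = traj(t, ps, np.zeros_like(t), 1 - ps, np.zeros_like(t))
        assert envelope_lifetime(t, ps, 1 - ps) == pytest.approx(1 / g, rel=0.1)


class TestOscillationFrequency:
    def test_recovers_synthetic_cosine(self):
        f0 = 40.0
        t = np.linspace(0, 1, 4000)
        ps = 0.5 + 0.4 * np.cos(2 * np.pi * f0 * t)
        pt2 = 1 - ps
        tr = traj(t, ps, np.zeros_like(t), pt2, np.zeros_like(t),
                  picture="schrodinger")
        assert oscillation_frequency(tr) == pytest.approx(f0, abs=1.5)

    def test_constant_series_reports_zero(self):
        t = np.linspace(0, 1, 100)
        tr = traj(t, np.full(100, 0.5), np.zeros(100), np.full(100, 0.5),
                  np.zeros(100), picture="schrodinger")
        assert oscillation_frequency(tr) == 0.0

    def test_aliasing_guard(self):
        t = np.linspace(0, 1, 64)
        ps = 0.5 + 0.4 * np.cos(2 * np.pi * 20 * t)
        tr = traj(t, ps, np.zeros_like(t), 1 - ps, np.zeros_like(t),
                  picture="schrodinger")
        with pytest.raises(ValueError):
            oscillation_frequency(tr)


class TestTransitionSpectrum:
    def test_bare_zeeman_single_line(self):
        spec = SystemSpec(mode="collective", n1=0, n2=0, lambda_h_hz=0.0)
        # no nuclei at all: use the noncollective bare radical-2 line instead
        spec = SystemSpec(mode="noncollective",
                          couplings_hz=((0, 0, 0), (0, 0, 0)))
        report = transition_spectrum(spec, radicals=(2,))
        assert report.count == 1
        assert report.frequencies_hz[0] == pytest.approx(1.3e6, rel=0.02)

    def test_single_nucleus_five_lines(self):
        spec = SystemSpec(mode="collective", n1=1, n2=1, lambda_h_hz=1e7)
        report = transition_spectrum(spec, radicals=(1,))
        assert report.count == 5

    def test_deterministic_and_sorted(self):
        spec = SystemSpec(mode="collective", n1=3, n2=3, lambda_h_hz=1e7)
        r1 = transition_spectrum(spec)
        r2 = transition_spectrum(spec)
        assert np.array_equal(r1.frequencies_hz, r2.frequencies_hz)
        assert np.all(np.diff(r1.frequencies_hz) > 0)
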