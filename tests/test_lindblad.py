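"""Master-equation assembly, propagation, pictures, pair composition."""

import numpy as np
import pytest

from radicalpair.eigenoperators import TransitionSet
from radicalpair.hamiltonians import SystemSpec, diagonalize
from radicalpair.lindblad_dynamics import (
    DensityOperator,
    build_joint_liouvillian,
    build_liouvillian,
    compose_pair_maps,
    initial_pair_state,
    pair_expectations,
    propagate,
    to_schrodinger,
)
from radicalpair.observables import pair_projectors
from radicalpair.rates_env import RateTable
from radicalpair.simulate import prepare_blocks
from radicalpair.spin_algebra import spin_half_ops


def manual_rate_table(omegas, gammas, n_thermal, gamma_d=0.0):
    return RateTable(
        omegas=np.atleast_1d(np.asarray(omegas, float)),
        gammas=np.atleast_1d(np.asarray(gammas, float)),
        n_thermal=np.atleast_1d(np.asarray(n_thermal, float)),
        gamma_d=gamma_d, temperature=300.0, dipole_moment=0.0,
    )


def two_level_ts(w0=1e6):
    s = spin_half_ops()
    return TransitionSet(
        v0=np.zeros((2, 2), dtype=complex),
        transitions=((w0, np.asarray(s.jminus) / 2),),
        radical_index=1, grouping_tol=1e-9,
    )


class TestBuildLiouvillian:
    def test_zero_rates_give_zero_generator(self):
        ts = two_level_ts()
        rt = manual_rate_table([1e6], [0.0], [0.0], gamma_d=0.0)
        l = build_liouvillian(ts, rt, dims=(2,))
        assert np.abs(l.generator).max() == 0

    def test_trace_preservation_structure(self):
        spec = SystemSpec(mode="collective", lambda_h_hz=1e7)
        b1, _, rt = prepare_blocks(spec)
        l = build_liouvillian(b1[0.5].transitions, rt, dims=(2, 2))
        # left action on the identity's dual: columns of L summed over the
        # diagonal of the output must vanish (d/dt Tr rho = 0)
        d = l.dim
        tr_vec = np.eye(d, dtype=complex).reshape(-1)
        scale = max(np.abs(l.generator).max(), 1.0)
        assert np.abs(tr_vec @ l.generator).max() < 1e-12 * scale

    def test_frequency_missing_from_table_raises(self):
        ts = two_level_ts(w0=2e6)
        rt = manual_rate_table([1e6], [0.1], [0.0])
        with pytest.raises(KeyError):
            build_liouvillian(ts, rt, dims=(2,))


class TestPropagate:
    def test_amplitude_damping_closed_form(self):
        # T -> 0: N = 0, only emission; excited population decays as e^{-gt}
        gamma = 2.0
        s = spin_half_ops()
        ts = TransitionSet(v0=np.zeros((2, 2), dtype=complex),
                           transitions=((1e6, np.asarray(s.jminus)),),
                           radical_index=1, grouping_tol=1e-9)
        rt = manual_rate_table([1e6], [gamma], [0.0])
        l = build_liouvillian(ts, rt, dims=(2,))
        rho0 = DensityOperator(np.diag([1.0, 0.0]).astype(complex), dims=(2,))
        times = np.linspace(0, 2.0, 21)
        states = propagate(l, rho0, times)
        pop = np.array([st.matrix[0, 0].real for st in states])
        assert np.abs(pop - np.exp(-gamma * times)).max() < 1e-8

    def test_pure_dephasing_preserves_populations(self):
        # V0 = Sz only: populations frozen, coherence decays at gamma_d/2
        s = spin_half_ops()
        ts = TransitionSet(v0=np.asarray(s.jz), transitions=(),
                           radical_index=1, grouping_tol=1e-9)
        rt = manual_rate_table([1.0], [0.0], [0.0], gamma_d=3.0)
        l = build_liouvillian(ts, rt, dims=(2,))
        rho0 = DensityOperator(np.full((2, 2), 0.5, dtype=complex), dims=(2,))
        times = np.linspace(0, 1.0, 11)
        states = propagate(l, rho0, times)
        for st, t in zip(states, times):
            assert st.matrix[0, 0].real == pytest.approx(0.5, abs=1e-12)
            assert st.matrix[0, 1].real == pytest.approx(
                0.5 * np.exp(-3.0 * t / 2), abs=1e-10)

    def test_zero_generator_is_identity_map(self):
        ts = two_level_ts()
        rt = manual_rate_table([1e6], [0.0], [0.0])
        l = build_liouvillian(ts, rt, dims=(2,))
        rho0 = DensityOperator(np.diag([0.7, 0.3]).astype(complex), dims=(2,))
        states = propagate(l, rho0, np.linspace(0, 5, 6))
        assert np.allclose(states[-1].matrix, rho0.matrix)

    def test_trace_and_positivity_along_trajectory(self):
        spec = SystemSpec(mode="collective", n1=1, n2=1, lambda_h_hz=1e7)
        b1, _, rt = prepare_blocks(spec)
        blk = b1[0.5]
        l = build_liouvillian(blk.transitions, rt, dims=(2, 2))
        rho0 = DensityOperator(np.eye(4, dtype=complex) / 4, dims=(2, 2))
        for st in propagate(l, rho0, np.linspace(0, 1.0, 30)):
            assert abs(np.trace(st.matrix) - 1) < 1e-10
            assert st.min_eigenvalue() > -1e-10

    def test_unitary_limit_conserves_purity(self):
        spec = SystemSpec(mode="collective", lambda_h_hz=1e7)
        b1, _, _ = prepare_blocks(spec)
        blk = b1[0.5]
        rt = manual_rate_table(blk.transitions.frequencies,
                               np.zeros(5), np.zeros(5), gamma_d=0.0)
        l = build_liouvillian(blk.transitions, rt,
                              hamiltonian=blk.hamiltonian)
        psi = np.zeros(4, dtype=complex)
        psi[0] = psi[3] = 1 / np.sqrt(2)
        rho0 = DensityOperator(np.outer(psi, psi.conj()), dims=(2, 2))
        states = propagate(l, rho0, np.linspace(0, 1e-5, 40))
        purities = [st.purity() for st in states]
        assert np.abs(np.array(purities) - 1.0).max() < 1e-8


class TestPictures:
    def test_t0_identity_and_eigenprojector_invariance(self):
        spec = SystemSpec(mode="collective", lambda_h_hz=1e7)
        b1, _, _ = prepare_blocks(spec)
        sp = b1[0.5].spectrum
        proj = np.outer(sp.vectors[:, 0], sp.vectors[:, 0].conj())
        rho = DensityOperator(proj, dims=(2, 2), picture="interaction")
        assert np.allclose(to_schrodinger(rho, sp, 0.0).matrix, proj)
        assert np.allclose(to_schrodinger(rho, sp, 1.23e-4).matrix, proj,
                           atol=1e-12)

    def test_coherence_phase_advances_by_gap(self):
        spec = SystemSpec(mode="collective", lambda_h_hz=1e7)
        b1, _, _ = prepare_blocks(spec)
        sp = b1[0.5].spectrum
        v0, v1 = sp.vectors[:, 0], sp.vectors[:, 1]
        psi = (v0 + v1) / np.sqrt(2)
        rho = DensityOperator(np.outer(psi, psi.conj()), dims=(2, 2),
                              picture="interaction")
        gap = sp.energies[1] - sp.energies[0]
        t = 3.21e-7
        rho_s = to_schrodinger(rho, sp, t).matrix
        coh = v0.conj() @ rho_s @ v1
        assert np.angle(coh * 2) == pytest.approx(gap * t - 2 * np.pi *
                                                  round((gap * t) / (2 * np.pi)),
                                                  abs=1e-9)

    def test_picture_mismatch_rejected(self):
        spec = SystemSpec(mode="collective", lambda_h_hz=1e7)
        b1, _, _ = prepare_blocks(spec)
        rho = DensityOperator(np.eye(4, dtype=complex) / 4, dims=(2, 2))
        with pytest.raises(ValueError):
            to_schrodinger(rho, b1[0.5].spectrum, 0.0)


class TestPairState:
    def test_singlet_probability_one_and_mixed_marginals(self):
        rho = initial_pair_state(3, 2)
        projs = pair_projectors(3, 2)
        assert np.trace(projs["singlet"] @ rho.matrix).real == pytest.approx(1.0)
        # electron-1 reduced state: trace out slots 1..3
        m = rho.matrix.reshape(2, 3, 2, 2, 2, 3, 2, 2)
        red = np.einsum("iabcjabc->ij", m)
        assert np.allclose(red, np.eye(2) / 2)

    def test_nuclear_marginal_maximally_mixed(self):
        rho = initial_pair_state(4, 1)
        m = rho.matrix.reshape(2, 4, 2, 1, 2, 4, 2, 1)
        red = np.einsum("iajbicjb->ac", m)
        assert np.allclose(red, np.eye(4) / 4)


class TestPairComposition:
    @pytest.fixture()
    def one_nucleus_setup(self):
        spec = SystemSpec(mode="collective", n1=1, n2=1, lambda_h_hz=1e7)
        b1, b2, rt = prepare_blocks(spec)
        l1 = build_liouvillian(b1[0.5].transitions, rt, dims=(2, 2))
        l2 = build_liouvillian(b2[0.5].transitions, rt, dims=(2, 2))
        return l1, l2, initial_pair_state(2, 2)

    def test_identity_maps_leave_state_unchanged(self):
        ts = two_level_ts()
        rt = manual_rate_table([1e6], [0.0], [0.0])
        l = build_liouvillian(ts, rt, dims=(2,))
        rho0 = initial_pair_state(1, 1)
        states = compose_pair_maps(l, l, rho0, np.linspace(0, 1, 5))
        assert np.allclose(states[-1].matrix, rho0.matrix)

    def test_matches_joint_space_oracle(self, one_nucleus_setup):
        # factorized propagation vs brute-force joint Eq.-of-motion generator
        l1, l2, rho0 = one_nucleus_setup
        times = np.linspace(0, 2.0, 20)
        composed = compose_pair_maps(l1, l2, rho0, times)
        joint = propagate(build_joint_liouvillian(l1, l2), rho0, times)
        dev = max(np.abs(a.matrix - b.matrix).max()
                  for a, b in zip(composed, joint))
        assert dev <= 1e-8

    def test_expectations_match_composed_states(self, one_nucleus_setup):
        l1, l2, rho0 = one_nucleus_setup
        times = np.linspace(0, 1.0, 15)
        projs = pair_projectors(2, 2)
        fast = pair_expectations(l1, l2, rho0, projs, times)
        states = compose_pair_maps(l1, l2, rho0, times)
        for name, p in projs.items():
            slow = [np.trace(p @ st.matrix).real for st in states]
            assert np.abs(fast[name] - slow).max() < 1e-9

    def test_one_sided_dephasing_decays_singlet_triplet_coherence(self):
        # radical 1 dephasing (V0 = Sz at rate g), radical 2 untouched:
        # the S/T0 contrast decays at exactly g/2
        s = spin_half_ops()
        g = 4.0
        ts1 = TransitionSet(v0=np.asarray(s.jz), transitions=(),
                            radical_index=1, grouping_tol=1e-9)
        ts2 = TransitionSet(v0=np.zeros((2, 2), dtype=complex), transitions=(),
                            radical_index=2, grouping_tol=1e-9)
        rt = manual_rate_table([1.0], [0.0], [0.0], gamma_d=g)
        l1 = build_liouvillian(ts1, rt, dims=(2,))
        l2 = build_liouvillian(ts2, rt, dims=(2,))
        rho0 = initial_pair_state(1, 1)
        times = np.linspace(0, 1.0, 11)
        projs = pair_projectors(1, 1)
        obs = pair_expectations(l1, l2, rho0, projs, times)
        contrast = obs["singlet"] - obs["t2"]
        assert np.abs(contrast - np.exp(-g / 2 * times)).max() < 1e-8
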