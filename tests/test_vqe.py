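"""VQE engine: reference state, MP2 screening, UCCSD and QCC ansatze,
optimization, and the sector-diagonalization oracle."""

import numpy as np
import pytest

from fmovqe.basis import build_basis
from fmovqe.integrals import compute_ao_integrals
from fmovqe.scf import rhf
from fmovqe.qubit import (jordan_wigner, mo_transform, number_operator,
                          PauliTerm, QubitHamiltonian)
from fmovqe.fci import fci_ground_energy
from fmovqe.vqe import (UCCSDAnsatz, QCCSpec, bloch_state, correlation_energy,
                        exact_ground_energy, expectation, hf_reference_state,
                        mp2_initial_amplitudes, optimize_bloch_angles,
                        qcc_state, sector_indices, select_qcc_entanglers,
                        vqe_minimize_qcc, vqe_minimize_uccsd, _apply_pauli)


class TestReferenceState:
    def test_blocked_occupation_pattern(self):
        v = hf_reference_state(4, 2)
        assert v[0b0101] == 1.0 and np.count_nonzero(v) == 1

    def test_zero_electrons_is_vacuum(self):
        v = hf_reference_state(4, 0)
        assert v[0] == 1.0 and np.count_nonzero(v) == 1

    def test_too_many_electrons_rejected(self):
        with pytest.raises(ValueError):
            hf_reference_state(2, 4)

    def test_sector_indices_count(self):
        # 4 qubits, 2 electrons, S_z=0: one alpha x one beta = 4 states
        assert len(sector_indices(4, 2)) == 4
        assert len(sector_indices(8, 4)) == 36


class TestMP2Screening:
    def test_zero_threshold_keeps_all(self, h2_mo):
        spec = mp2_initial_amplitudes(h2_mo, 2, screen_threshold=0.0)
        assert spec.n_screened_out == 0

    def test_infinite_threshold_keeps_singles_only(self, h2_mo):
        spec = mp2_initial_amplitudes(h2_mo, 2, screen_threshold=np.inf)
        assert len(spec.doubles) == 0
        assert len(spec.singles) > 0
        assert np.all(spec.t_singles == 0.0)

    def test_h2_single_surviving_double(self, h2_mo):
        """H2/STO-3G has exactly one S_z-conserving double (both electrons
        promoted), and VQE from its MP2 value reaches FCI."""
        spec = mp2_initial_amplitudes(h2_mo, 2)
        assert len(spec.doubles) == 1
        ham = jordan_wigner(h2_mo)
        res = vqe_minimize_uccsd(ham, spec, 2)
        assert res.energy == pytest.approx(fci_ground_energy(h2_mo, 2), abs=1e-7)

    def test_degenerate_denominator_rejected(self, h2_mo):
        from fmovqe.qubit import MOIntegrals
        broken = MOIntegrals(h=h2_mo.h, g=h2_mo.g, E0=h2_mo.E0,
                             eps=np.zeros_like(h2_mo.eps))
        with pytest.raises(ValueError, match="denominator"):
            mp2_initial_amplitudes(broken, 2)


class TestUCCSDAnsatz:
    def test_zero_amplitudes_return_reference(self, h2_mo):
        spec = mp2_initial_amplitudes(h2_mo, 2)
        ansatz = UCCSDAnsatz(spec, 4, 2)
        state = ansatz.state(np.zeros(spec.n_parameters))
        np.testing.assert_array_equal(state, ansatz.reference)

    def test_unitarity_and_particle_number(self, h2_mo):
        spec = mp2_initial_amplitudes(h2_mo, 2, screen_threshold=0.0)
        ansatz = UCCSDAnsatz(spec, 4, 2)
        rng_params = np.linspace(-0.4, 0.4, spec.n_parameters)
        state = ansatz.state(rng_params)
        assert abs(np.linalg.norm(state) - 1.0) < 1e-12
        N = number_operator(4).to_sparse()
        assert expectation(N, state) == pytest.approx(2.0, abs=1e-10)
        # the state never leaves the particle-number sector
        outside = np.ones(16, dtype=bool)
        outside[sector_indices(4, 2)] = False
        assert np.abs(state[outside]).max() < 1e-12

    def test_generators_are_antihermitian(self, h2_mo):
        spec = mp2_initial_amplitudes(h2_mo, 2, screen_threshold=0.0)
        for G in UCCSDAnsatz(spec, 4, 2).generators:
            assert abs(G + G.T).max() < 1e-14

    def test_single_excitation_pi_half_swaps_occupation(self):
        """At amplitude pi/2 a lone single excitation is a full Givens
        rotation moving the electron from orbital i to orbital a."""
        from fmovqe.vqe import UCCSDSpec
        spec = UCCSDSpec(singles=[(0, 1)], doubles=[],
                         t_singles=np.array([np.pi / 2]), t_doubles=np.zeros(0))
        ansatz = UCCSDAnsatz(spec, 2, 0)
        ref = np.zeros(4)
        ref[0b01] = 1.0  # electron on qubit 0
        ansatz.reference = ref
        out = ansatz.state(spec.amplitudes)
        assert abs(abs(out[0b10]) - 1.0) < 1e-10


class TestVQEMinimize:
    @pytest.mark.parametrize("basis", ["STO-3G", "6-31G"])
    def test_uccsd_exact_for_two_electrons(self, h2_geom, basis):
        st = rhf(compute_ao_integrals(build_basis(h2_geom, basis)), 2)
        mo = mo_transform(st)
        ham = jordan_wigner(mo)
        res = vqe_minimize_uccsd(ham, mp2_initial_amplitudes(mo, 2), 2)
        e_fci = exact_ground_energy(ham, 2).energy
        assert abs(res.energy - e_fci) < 1e-7
        assert res.energy >= e_fci - 1e-9  # variational bound

    def test_scalar_hamiltonian_returns_immediately(self, h_anion_scf):
        mo = mo_transform(h_anion_scf)
        ham = jordan_wigner(mo)
        spec = mp2_initial_amplitudes(mo, 2)
        assert spec.n_parameters == 0  # no virtuals
        res = vqe_minimize_uccsd(ham, spec, 2)
        assert res.n_iterations == 0
        assert res.energy == pytest.approx(h_anion_scf.energy, abs=1e-10)

    def test_variational_bound_across_fragments(self, h6_fragments):
        _, monomers, dimers = h6_fragments
        for st in list(monomers) + list(dimers.values()):
            mo = mo_transform(st)
            ham = jordan_wigner(mo)
            spec = mp2_initial_amplitudes(mo, st.n_electrons)
            res = vqe_minimize_uccsd(ham, spec, st.n_electrons)
            e_fci = exact_ground_energy(ham, st.n_electrons).energy
            assert res.energy >= e_fci - 1e-9


class TestQCC:
    def test_bloch_poles(self):
        n = 3
        np.testing.assert_allclose(bloch_state(np.zeros(n), np.zeros(n))[0], 1.0)
        all_down = bloch_state(np.full(n, np.pi), np.zeros(n))
        assert abs(abs(all_down[-1]) - 1.0) < 1e-12

    def test_single_entangler_rotation_formula(self):
        """exp(-i tau P/2)|O> = cos(tau/2)|O> - i sin(tau/2) P|O> for an
        involution P."""
        theta = np.array([0.3, 1.1])
        phi = np.array([0.2, -0.5])
        tau = 0.77
        spec = QCCSpec(theta=theta, phi=phi, entanglers=["XY"],
                       tau=np.array([tau]))
        omega = bloch_state(theta, phi)
        expected = (np.cos(tau / 2) * omega
                    - 1j * np.sin(tau / 2) * _apply_pauli("XY", omega))
        np.testing.assert_allclose(qcc_state(spec), expected, atol=1e-12)

    def test_single_qubit_entangler_rejected(self):
        with pytest.raises(ValueError, match="2 qubits"):
            QCCSpec(theta=np.zeros(2), phi=np.zeros(2),
                    entanglers=["XI"], tau=np.zeros(1))

    def test_diagonal_hamiltonian_selects_nothing(self):
        ham = QubitHamiltonian(terms=[PauliTerm("ZZ", 0.5), PauliTerm("IZ", 0.2)],
                               n_qubits=2)
        omega = bloch_state(np.array([0.4, 0.9]), np.zeros(2))
        assert select_qcc_entanglers(ham, omega) == []

    def test_top_entangler_matches_brute_force_gradient(self, h2_mo):
        """The selected leading entangler attains the maximal |dE/dtau| over
        ALL 4-qubit Pauli words (brute-force oracle)."""
        ham = jordan_wigner(h2_mo)
        theta, phi, _ = optimize_bloch_angles(ham, 2)
        omega = bloch_state(theta, phi)
        Hs = ham.to_sparse()
        Hw = Hs @ omega
        best = 0.0
        from itertools import product
        for letters in product("IXYZ", repeat=4):
            word = "".join(letters)
            nontrivial = sum(1 for c in word if c != "I")
            if nontrivial < 2:
                continue
            best = max(best, abs(np.imag(np.vdot(Hw, _apply_pauli(word, omega)))))
        chosen = select_qcc_entanglers(ham, omega, pool_size=1)
        assert chosen, "no entangler selected"
        grad = abs(np.imag(np.vdot(Hw, _apply_pauli(chosen[0], omega))))
        assert grad > 0
        assert grad == pytest.approx(best, rel=1e-9)

    def test_mean_field_at_least_rhf_quality(self, h2_scf, h2_mo):
        ham = jordan_wigner(h2_mo)
        _, _, e_mf = optimize_bloch_angles(ham, 2)
        assert e_mf <= h2_scf.energy + 1e-9

    def test_pool_nesting_monotonicity(self, h2_mo):
        """Warm-started optimization with a larger entangler pool never
        raises the optimized energy."""
        ham = jordan_wigner(h2_mo)
        theta, phi, _ = optimize_bloch_angles(ham, 2)
        omega = bloch_state(theta, phi)
        pool = select_qcc_entanglers(ham, omega)
        energies = []
        prev_tau = np.zeros(0)
        for k in range(len(pool) + 1):
            tau0 = np.concatenate([prev_tau, np.zeros(k - len(prev_tau))])
            res = vqe_minimize_qcc(ham, 2, entanglers=pool[:k], tau0=tau0)
            energies.append(res.energy)
            prev_tau = res.parameters[2 * ham.n_qubits:]
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-7)

    def test_qcc_variational_bound(self, h2_mo):
        ham = jordan_wigner(h2_mo)
        res = vqe_minimize_qcc(ham, 2)
        assert res.energy >= exact_ground_energy(ham, 2).energy - 1e-9


class TestExpectationAndOracle:
    def test_scalar_hamiltonian(self):
        ham = QubitHamiltonian(terms=[PauliTerm("II", -1.7)], n_qubits=2)
        state = np.ones(4) / 2.0
        assert expectation(ham.to_sparse(), state) == pytest.approx(-1.7)

    def test_z_eigenstate(self):
        ham = QubitHamiltonian(terms=[PauliTerm("ZI", 0.3)], n_qubits=2)
        state = np.zeros(4)
        state[0] = 1.0
        assert expectation(ham.to_sparse(), state) == pytest.approx(0.3)

    def test_empty_sector_rejected(self, h2_mo):
        ham = jordan_wigner(h2_mo)
        with pytest.raises(ValueError):
            exact_ground_energy(ham, 10)

    def test_sector_minimum_not_above_full_minimum(self, h2_mo):
        ham = jordan_wigner(h2_mo)
        e_sector = exact_ground_energy(ham, 2).energy
        w = np.linalg.eigvalsh(ham.to_sparse().toarray())
        assert e_sector >= w[0] - 1e-12


class TestCorrelationEnergy:
    def test_sign_convention(self):
        assert correlation_energy(-1.14, -1.12) == pytest.approx(-0.02)
        with pytest.raises(ValueError, match="positive"):
            correlation_energy(-1.10, -1.12)

    def test_hydride_zero(self, h_anion_scf):
        assert correlation_energy(h_anion_scf.energy, h_anion_scf.energy) == 0.0
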