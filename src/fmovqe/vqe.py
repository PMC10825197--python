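"""Statevector variational quantum eigensolver (VQE).

Two ansatze are provided:

* UCCSD — ``exp(T - T+)`` acting on the restricted HF determinant, with the
  summed generator exponentiated exactly on the statevector (Krylov
  ``expm_multiply``), so no Trotter-ordering convention enters the results.
  Initial double amplitudes come from MP2 and are screened at a threshold
  (default 1e-3); singles start at zero (Brillouin) and are never screened.
* QCC — a product of single-qubit Bloch states acted on by exponentials of
  Pauli-word entanglers, with entanglers picked by the magnitude of the
  first-order energy gradient at the optimized mean field.

The classical optimizer is SLSQP (ftol 1e-9, internal finite-difference
gradients); the whole path is deterministic.  The sector-restricted exact
diagonalization of the qubit Hamiltonian (`exact_ground_energy`) is the
oracle against which every VQE energy is measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse
import scipy.sparse.linalg
from scipy.optimize import minimize

from .qubit import (MOIntegrals, QubitHamiltonian, spin_orbital_integrals,
                    excitation_generator, pauli_word_to_masks)

__all__ = ["UCCSDSpec", "QCCSpec", "VQEResult", "hf_reference_state",
           "mp2_initial_amplitudes", "UCCSDAnsatz", "expectation",
           "vqe_minimize_uccsd", "bloch_state", "qcc_state",
           "optimize_bloch_angles", "select_qcc_entanglers",
           "vqe_minimize_qcc", "exact_ground_energy", "sector_indices",
           "correlation_energy"]


# ---------------------------------------------------------------------------
# Reference state and sector bookkeeping (blocked spin-orbital convention)
# ---------------------------------------------------------------------------

def hf_reference_state(n_qubits: int, n_electrons: int) -> np.ndarray:
    """HF computational-basis state: lowest n_electrons/2 orbitals of each
    spin block occupied (all alpha on qubits 0..m-1, beta on m..2m-1)."""
    if n_electrons > n_qubits:
        raise ValueError("more electrons than spin orbitals")
    if n_electrons % 2 != 0:
        raise ValueError("closed shell requires an even electron count")
    m = n_qubits // 2
    n_occ = n_electrons // 2
    idx = 0
    for p in range(n_occ):
        idx |= (1 << p) | (1 << (m + p))
    v = np.zeros(1 << n_qubits)
    v[idx] = 1.0
    return v


def sector_indices(n_qubits: int, n_electrons: int) -> np.ndarray:
    """Basis indices with the given particle number and S_z = 0."""
    m = n_qubits // 2
    idx = np.arange(1 << n_qubits, dtype=np.uint64)
    alpha_mask = np.uint64((1 << m) - 1)
    n_alpha = np.bitwise_count(idx & alpha_mask)
    n_beta = np.bitwise_count(idx >> np.uint64(m))
    keep = (n_alpha + n_beta == n_electrons) & (n_alpha == n_beta)
    return np.nonzero(keep)[0]


@dataclass
class ExactSolution:
    energy: float
    vector: np.ndarray
    indices: np.ndarray


def exact_ground_energy(ham: QubitHamiltonian, n_electrons: int) -> ExactSolution:
    """FCI oracle on the qubit side: lowest eigenvalue of H restricted to
    the (N, S_z = 0) determinant sector."""
    if ham.n_qubits > 20:
        raise ValueError("sector diagonalization capped at 20 qubits")
    idx = sector_indices(ham.n_qubits, n_electrons)
    if idx.size == 0:
        raise ValueError("empty particle-number sector")
    H = ham.to_sparse()
    Hsec = H[np.ix_(idx, idx)].toarray()
    if np.abs(Hsec.imag).max() > 1e-12:
        raise AssertionError("sector Hamiltonian should be real")
    Hsec = Hsec.real
    if Hsec.shape[0] <= 2000:
        w, v = np.linalg.eigh(Hsec)
        return ExactSolution(float(w[0]), v[:, 0], idx)
    w, v = scipy.sparse.linalg.eigsh(scipy.sparse.csr_matrix(Hsec), k=1, which="SA")
    return ExactSolution(float(w[0]), v[:, 0], idx)


def expectation(ham_sparse, state: np.ndarray) -> float:
    """<psi|H|psi>; the imaginary residual (numerical noise) is discarded."""
    val = np.vdot(state, ham_sparse @ state)
    if abs(val.imag) > 1e-8:
        raise ValueError(f"expectation has large imaginary part {val.imag:.3e}")
    return float(val.real)


# ---------------------------------------------------------------------------
# UCCSD
# ---------------------------------------------------------------------------

@dataclass
class UCCSDSpec:
    """Kept excitations (spin-orbital indices, blocked order) and amplitudes."""

    singles: list[tuple[int, int]]            # (i, a)
    doubles: list[tuple[int, int, int, int]]  # (i, j, a, b), i<j, a<b
    t_singles: np.ndarray
    t_doubles: np.ndarray
    screen_threshold: float = 1e-3
    n_screened_out: int = 0

    @property
    def n_parameters(self) -> int:
        return len(self.singles) + len(self.doubles)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.concatenate([np.atleast_1d(self.t_singles),
                               np.atleast_1d(self.t_doubles)])


def _spin_orbitals(m: int, n_electrons: int):
    n_occ = n_electrons // 2
    occ = list(range(n_occ)) + list(range(m, m + n_occ))
    vir = [p for p in range(2 * m) if p not in occ]
    return occ, vir


def _sz(p: int, m: int) -> int:
    return 0 if p < m else 1


def mp2_initial_amplitudes(moints: MOIntegrals, n_electrons: int,
                           screen_threshold: float = 1e-3) -> UCCSDSpec:
    """MP2 doubles t_ijab = <ij||ab> / (e_i + e_j - e_a - e_b), screened at
    ``screen_threshold``; spin-conserving singles kept with zero amplitude.

    Orbital energies come from ``moints.eps`` (canonical embedded SCF).
    """
    if moints.eps is None:
        raise ValueError("MP2 initialization needs canonical orbital energies")
    m = moints.n_orbitals
    _, g_anti = spin_orbital_integrals(moints)
    eps_so = np.concatenate([moints.eps, moints.eps])
    occ, vir = _spin_orbitals(m, n_electrons)

    singles = [(i, a) for i in occ for a in vir if _sz(i, m) == _sz(a, m)]
    doubles, amps = [], []
    n_screened = 0
    for ii, i in enumerate(occ):
        for j in occ[ii + 1:]:
            for ai, a in enumerate(vir):
                for b in vir[ai + 1:]:
                    if _sz(i, m) + _sz(j, m) != _sz(a, m) + _sz(b, m):
                        continue
                    num = g_anti[i, j, a, b]
                    den = eps_so[i] + eps_so[j] - eps_so[a] - eps_so[b]
                    if abs(den) < 1e-8:
                        raise ValueError(
                            f"vanishing MP2 denominator for ({i},{j})->({a},{b})")
                    t = num / den
                    if abs(t) < screen_threshold:
                        n_screened += 1
                        continue
                    doubles.append((i, j, a, b))
                    amps.append(t)
    return UCCSDSpec(singles=singles, doubles=doubles,
                     t_singles=np.zeros(len(singles)),
                     t_doubles=np.array(amps, dtype=float),
                     screen_threshold=screen_threshold,
                     n_screened_out=n_screened)


class UCCSDAnsatz:
    """Exact-exponential UCCSD state preparation.

    Generators G_mu = tau_mu - tau_mu+ are JW-mapped once; the summed
    generator G(t) = sum_mu t_mu G_mu is applied as expm(G) |HF> with a
    sparse Krylov exponential (no Trotterization).
    """

    def __init__(self, spec: UCCSDSpec, n_qubits: int, n_electrons: int):
        self.spec = spec
        self.n_qubits = n_qubits
        self.reference = hf_reference_state(n_qubits, n_electrons)
        excs = list(spec.singles) + list(spec.doubles)
        self.generators = [excitation_generator(exc, n_qubits) for exc in excs]

    def generator(self, params: np.ndarray) -> scipy.sparse.csr_matrix:
        G = scipy.sparse.csr_matrix((1 << self.n_qubits,) * 2)
        for t, Gmu in zip(params, self.generators):
            if t != 0.0:
                G = G + t * Gmu
        return G

    def state(self, params: np.ndarray) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        if len(params) != len(self.generators):
            raise ValueError("parameter count mismatch")
        if not len(params) or not np.any(params):
            return self.reference.copy()
        G = self.generator(params)
        return scipy.sparse.linalg.expm_multiply(G, self.reference)


@dataclass
class VQEResult:
    energy: float
    parameters: np.ndarray
    n_iterations: int
    converged: bool
    ansatz: str
    n_qubits: int = 0
    n_function_evals: int = 0


def vqe_minimize_uccsd(ham: QubitHamiltonian, spec: UCCSDSpec,
                       n_electrons: int, ftol: float = 1e-9,
                       maxiter: int = 1000) -> VQEResult:
    """SLSQP minimization of <psi(t)|H|psi(t)> over UCCSD amplitudes,
    started from the screened MP2 amplitudes."""
    ansatz = UCCSDAnsatz(spec, ham.n_qubits, n_electrons)
    Hs = ham.to_sparse().real
    x0 = spec.amplitudes
    if len(x0) == 0:
        e = expectation(Hs, ansatz.reference)
        return VQEResult(energy=e, parameters=x0, n_iterations=0,
                         converged=True, ansatz="uccsd", n_qubits=ham.n_qubits)

    def objective(x):
        return expectation(Hs, ansatz.state(x))

    res = minimize(objective, x0, method="SLSQP",
                   options={"ftol": ftol, "maxiter": maxiter})
    return VQEResult(energy=float(res.fun), parameters=res.x,
                     n_iterations=int(res.nit), converged=bool(res.success),
                     ansatz="uccsd", n_qubits=ham.n_qubits,
                     n_function_evals=int(res.nfev))


# ---------------------------------------------------------------------------
# QCC
# ---------------------------------------------------------------------------

@dataclass
class QCCSpec:
    theta: np.ndarray                 # polar Bloch angles, radians
    phi: np.ndarray                   # azimuthal Bloch angles
    entanglers: list[str]             # Pauli words
    tau: np.ndarray                   # entangler amplitudes

    def __post_init__(self):
        for w in self.entanglers:
            if sum(1 for c in w if c != "I") < 2:
                raise ValueError(f"entangler {w!r} must act on >= 2 qubits")


def bloch_state(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Product state prod_i [cos(theta_i/2)|0> + e^{i phi_i} sin(theta_i/2)|1>].

    |0> is the spin-up / unoccupied qubit state.  Qubit 0 is the least
    significant bit of the statevector index.
    """
    state = np.array([1.0 + 0.0j])
    for t, p in zip(theta, phi):
        q = np.array([np.cos(t / 2.0), np.exp(1j * p) * np.sin(t / 2.0)])
        state = np.kron(q, state)  # higher qubits are more significant bits
    return state


def _apply_pauli(word: str, state: np.ndarray) -> np.ndarray:
    x, z, conv = pauli_word_to_masks(word)
    n = len(word)
    idx = np.arange(1 << n, dtype=np.uint64)
    phases = np.where(np.bitwise_count(idx & np.uint64(z)) % 2 == 1, -1.0, 1.0)
    out = np.empty_like(state, dtype=complex)
    out[idx ^ np.uint64(x)] = conv * phases * state
    return out


def qcc_state(spec: QCCSpec) -> np.ndarray:
    """Mean-field Bloch product acted on by exp(-i tau_k P_k / 2), applied
    right-to-left (last entangler in the list acts first)."""
    state = bloch_state(spec.theta, spec.phi)
    for word, t in list(zip(spec.entanglers, spec.tau))[::-1]:
        state = np.cos(t / 2.0) * state - 1j * np.sin(t / 2.0) * _apply_pauli(word, state)
    return state


def optimize_bloch_angles(ham: QubitHamiltonian, n_electrons: int,
                          ftol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, float]:
    """Qubit mean field: minimize over all product Bloch states, starting
    from the HF occupation pattern (theta = pi on occupied qubits)."""
    n = ham.n_qubits
    m = n // 2
    n_occ = n_electrons // 2
    theta0 = np.zeros(n)
    for p in range(n_occ):
        theta0[p] = np.pi
        theta0[m + p] = np.pi
    Hs = ham.to_sparse()

    def objective(x):
        return expectation(Hs, bloch_state(x[:n], x[n:]))

    res = minimize(objective, np.concatenate([theta0, np.zeros(n)]),
                   method="SLSQP", options={"ftol": ftol, "maxiter": 1000})
    return res.x[:n].copy(), res.x[n:].copy(), float(res.fun)


def _candidate_entanglers(ham: QubitHamiltonian) -> list[str]:
    """Odd-Y words supported on the X/Y footprint of the Hamiltonian's
    off-diagonal terms (the flip set a first-order rotation can reach)."""
    n = ham.n_qubits
    candidates = set()
    for t in ham.terms:
        support = [q for q, p in enumerate(t.word) if p in ("X", "Y")]
        if len(support) < 2:
            continue
        base = ["I"] * n
        for q in support:
            base[q] = "X"
        for q in support:  # exactly one Y -> odd-Y word with nonzero gradient
            w = base.copy()
            w[q] = "Y"
            candidates.add("".join(w))
    return sorted(candidates)


def select_qcc_entanglers(ham: QubitHamiltonian, omega: np.ndarray,
                          pool_size: Optional[int] = None) -> list[str]:
    """Rank candidate Pauli words by |dE/dtau| = |Im <Omega|H P|Omega>| at
    tau = 0 and keep the top ``pool_size`` (ties broken lexicographically)."""
    if pool_size is None:
        pool_size = ham.n_qubits
    Hs = ham.to_sparse()
    Homega = Hs @ omega
    ranked = []
    for word in _candidate_entanglers(ham):
        # dE/dtau at tau=0 for exp(-i tau P/2) is Im <Omega|H P|Omega>
        grad = abs(np.imag(np.vdot(Homega, _apply_pauli(word, omega))))
        if grad > 1e-12:
            ranked.append((-grad, word))
    ranked.sort()
    return [w for _, w in ranked[:pool_size]]


def vqe_minimize_qcc(ham: QubitHamiltonian, n_electrons: int,
                     pool_size: Optional[int] = None,
                     tau0: Optional[np.ndarray] = None,
                     entanglers: Optional[list[str]] = None,
                     ftol: float = 1e-9, maxiter: int = 1000) -> VQEResult:
    """QCC pipeline: Bloch mean-field pre-optimization, gradient-ranked
    entangler selection, then joint SLSQP over (theta, phi, tau)."""
    n = ham.n_qubits
    theta, phi, e_mf = optimize_bloch_angles(ham, n_electrons)
    omega = bloch_state(theta, phi)
    if entanglers is None:
        entanglers = select_qcc_entanglers(ham, omega, pool_size)
    Hs = ham.to_sparse()
    k = len(entanglers)
    if tau0 is None:
        tau0 = np.zeros(k)

    def objective(x):
        spec = QCCSpec(theta=x[:n], phi=x[n:2 * n],
                       entanglers=entanglers, tau=x[2 * n:])
        return expectation(Hs, qcc_state(spec))

    x0 = np.concatenate([theta, phi, tau0])
    if k == 0:
        return VQEResult(energy=e_mf, parameters=x0, n_iterations=0,
                         converged=True, ansatz="qcc", n_qubits=n)
    res = minimize(objective, x0, method="SLSQP",
                   options={"ftol": ftol, "maxiter": maxiter})
    energy = float(min(res.fun, e_mf))
    return VQEResult(energy=energy, parameters=res.x, n_iterations=int(res.nit),
                     converged=bool(res.success), ansatz="qcc", n_qubits=n,
                     n_function_evals=int(res.nfev))


# ---------------------------------------------------------------------------
# Correlation energy
# ---------------------------------------------------------------------------

def correlation_energy(e_correlated: float, e_rhf: float,
                       tol: float = 1e-8) -> float:
    """E_corr = E_method - E_RHF for the same embedded fragment; should be
    non-positive up to optimizer tolerance."""
    e_corr = e_correlated - e_rhf
    if e_corr > tol:
        raise ValueError(f"correlation energy {e_corr:.3e} Ha is positive "
                         "(mismatched fragment energies?)")
    return min(e_corr, 0.0)
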