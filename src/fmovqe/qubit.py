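"""From a converged fragment SCF to a qubit Hamiltonian.

Pipeline: AO -> MO integral transformation (the embedding operator rides
inside the one-electron matrix), optional frozen-core active-space
reduction, second quantization, Jordan-Wigner (JW) mapping.

Spin-orbital convention is BLOCKED: alpha spatial orbitals occupy qubits
0..m-1 and beta orbitals qubits m..2m-1; qubit q of a computational basis
index is bit q (qubit 0 = least significant bit), with |1> = occupied.

Pauli words are stored internally in symplectic (x_mask, z_mask) form,
representing the operator X^x Z^z with an explicit complex coefficient;
Y = i X Z on each qubit.  The exported :class:`PauliTerm` uses the standard
I/X/Y/Z letters with real coefficients (the Hamiltonian is Hermitian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse

__all__ = ["MOIntegrals", "ActiveSpace", "PauliTerm", "QubitHamiltonian",
           "mo_transform", "apply_active_space", "jordan_wigner", "qubit_count",
           "spin_orbital_integrals", "pauli_word_to_masks", "pauli_sparse_matrix"]


# ---------------------------------------------------------------------------
# MO integrals and active space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MOIntegrals:
    """Spatial-orbital MO integrals of one embedded subsystem.

    h includes kinetic + own-nuclear + embedding one-electron terms;
    g is in chemists' convention (pq|rs); E0 carries intra-subsystem
    nuclear repulsion, the scalar environment term and any frozen-orbital
    folding, so that <HF|H|HF> equals the embedded RHF total energy.
    """

    h: np.ndarray
    g: np.ndarray
    E0: float
    eps: np.ndarray | None = None  # canonical orbital energies, if available

    @property
    def n_orbitals(self) -> int:
        return self.h.shape[0]


@dataclass(frozen=True)
class ActiveSpace:
    frozen: tuple[int, ...]
    active: tuple[int, ...]
    n_active_electrons: int

    def __post_init__(self):
        object.__setattr__(self, "frozen", tuple(sorted(self.frozen)))
        object.__setattr__(self, "active", tuple(sorted(self.active)))
        if set(self.frozen) & set(self.active):
            raise ValueError("frozen and active orbital sets overlap")
        if self.n_active_electrons < 0 or self.n_active_electrons % 2 != 0:
            raise ValueError("active electron count must be even and >= 0")
        if self.n_active_electrons > 2 * len(self.active):
            raise ValueError("active electrons exceed active-space capacity")

    @classmethod
    def full(cls, n_orbitals: int, n_electrons: int) -> "ActiveSpace":
        return cls(frozen=(), active=tuple(range(n_orbitals)),
                   n_active_electrons=n_electrons)

    @classmethod
    def around_homo_lumo(cls, n_orbitals: int, n_electrons: int,
                         n_active_orbitals: int) -> "ActiveSpace":
        """Pick ``n_active_orbitals`` orbitals centred on the HOMO/LUMO gap."""
        n_occ = n_electrons // 2
        lo = max(0, n_occ - (n_active_orbitals + 1) // 2)
        hi = min(n_orbitals, lo + n_active_orbitals)
        lo = hi - n_active_orbitals
        active = tuple(range(lo, hi))
        frozen = tuple(range(lo))
        return cls(frozen=frozen, active=active,
                   n_active_electrons=n_electrons - 2 * len(frozen))


def mo_transform(scf_state) -> MOIntegrals:
    """Transform a converged :class:`~fmovqe.scf.SCFState` to MO integrals."""
    C = scf_state.C
    ints = scf_state.ints
    h_ao = ints.hcore + scf_state.embedding.U
    h = C.T @ h_ao @ C
    g = np.einsum("mnls,mp,nq,lr,st->pqrt", ints.g, C, C, C, C, optimize=True)
    E0 = ints.e_nuc + scf_state.embedding.scalar
    return MOIntegrals(h=h, g=g, E0=E0, eps=scf_state.eps.copy())


def apply_active_space(moints: MOIntegrals, space: ActiveSpace) -> MOIntegrals:
    """Fold frozen orbitals into E0 and an effective one-electron matrix."""
    n = moints.n_orbitals
    if any(p < 0 or p >= n for p in space.frozen + space.active):
        raise ValueError("orbital index out of range")
    if not space.frozen and len(space.active) == n:
        return moints
    f = list(space.frozen)
    a = list(space.active)
    h, g = moints.h, moints.g
    E0 = moints.E0
    for i in f:
        E0 += 2.0 * h[i, i]
        for j in f:
            E0 += 2.0 * g[i, i, j, j] - g[i, j, j, i]
    h_eff = h.copy()
    for i in f:
        h_eff += 2.0 * g[:, :, i, i] - g[:, i, i, :]
    h_act = h_eff[np.ix_(a, a)]
    g_act = g[np.ix_(a, a, a, a)]
    eps = moints.eps[a] if moints.eps is not None else None
    return MOIntegrals(h=h_act, g=g_act, E0=E0, eps=eps)


def qubit_count(basis_name: str, n_atoms: int,
                active_space: ActiveSpace | None = None) -> int:
    """Qubits needed for a subsystem: 2 x (active spatial orbitals)."""
    from .basis import n_basis_functions
    if active_space is not None:
        return 2 * len(active_space.active)
    return 2 * n_basis_functions(basis_name, n_atoms)


# ---------------------------------------------------------------------------
# Symplectic Pauli algebra
# ---------------------------------------------------------------------------

def _mul(t1, t2):
    """Product of stored terms ((x,z), coeff): X^x Z^z ordering, Y = iXZ."""
    (x1, z1), c1 = t1
    (x2, z2), c2 = t2
    sign = -1.0 if (int(z1 & x2).bit_count() % 2) else 1.0
    return (x1 ^ x2, z1 ^ z2), c1 * c2 * sign


def _op_mul(op1: dict, op2: dict) -> dict:
    out: dict = {}
    for k1, c1 in op1.items():
        for k2, c2 in op2.items():
            k, c = _mul((k1, c1), (k2, c2))
            out[k] = out.get(k, 0.0) + c
    return {k: c for k, c in out.items() if abs(c) > 1e-16}


def _creation(q: int) -> dict:
    """JW a_q^dag = Z_{<q} (X_q - i Y_q)/2 = (Z_{<q} X_q + Z_{<q} X_q Z_q)/2."""
    zstr = (1 << q) - 1
    return {(1 << q, zstr): 0.5, (1 << q, zstr | (1 << q)): 0.5}


def _annihilation(q: int) -> dict:
    zstr = (1 << q) - 1
    return {(1 << q, zstr): 0.5, (1 << q, zstr | (1 << q)): -0.5}


def _masks_to_word(x: int, z: int, n_qubits: int) -> tuple[str, complex]:
    """Convert X^x Z^z to a standard Pauli word and the phase factor such
    that X^x Z^z = phase * word."""
    letters = []
    n_y = 0
    for q in range(n_qubits):
        xb, zb = (x >> q) & 1, (z >> q) & 1
        if xb and zb:
            letters.append("Y")
            n_y += 1
        elif xb:
            letters.append("X")
        elif zb:
            letters.append("Z")
        else:
            letters.append("I")
    # X Z = -i Y on each Y qubit
    phase = (-1j) ** n_y
    return "".join(letters), phase


def pauli_word_to_masks(word: str) -> tuple[int, int, complex]:
    """Standard word -> (x, z, c) such that word = c * X^x Z^z (Y = i X Z)."""
    x = z = 0
    n_y = 0
    for q, p in enumerate(word):
        if p == "X":
            x |= 1 << q
        elif p == "Z":
            z |= 1 << q
        elif p == "Y":
            x |= 1 << q
            z |= 1 << q
            n_y += 1
        elif p != "I":
            raise ValueError(f"bad Pauli letter {p!r}")
    return x, z, 1j ** n_y


@dataclass(frozen=True)
class PauliTerm:
    word: str          # letters over I/X/Y/Z; index 0 = qubit 0
    coeff: float       # Ha, real (Hermitian Hamiltonian)


@dataclass
class QubitHamiltonian:
    terms: list[PauliTerm]
    n_qubits: int

    def to_sparse(self) -> scipy.sparse.csr_matrix:
        return _terms_to_sparse(self.terms, self.n_qubits)

    def dump(self) -> str:
        """'coeff word' per line, lexicographic by word (diffable)."""
        lines = [f"{t.coeff:+.12e} {t.word}"
                 for t in sorted(self.terms, key=lambda t: t.word)]
        return "\n".join(lines)

    def n_terms(self) -> int:
        return len(self.terms)


def _stored_terms_to_hamiltonian(stored: dict, n_qubits: int,
                                 prune: float = 1e-12) -> QubitHamiltonian:
    terms = []
    for (x, z), c in stored.items():
        word, phase = _masks_to_word(x, z, n_qubits)
        coeff = c * phase
        if abs(coeff.imag) > 1e-10:
            raise ValueError(f"non-Hermitian term {word}: {coeff}")
        if abs(coeff.real) >= prune:
            terms.append(PauliTerm(word=word, coeff=float(coeff.real)))
    terms.sort(key=lambda t: t.word)
    return QubitHamiltonian(terms=terms, n_qubits=n_qubits)


def _terms_to_sparse(terms, n_qubits: int) -> scipy.sparse.csr_matrix:
    dim = 1 << n_qubits
    idx = np.arange(dim, dtype=np.uint64)
    rows, cols, data = [], [], []
    for t in terms:
        x, z, conv = pauli_word_to_masks(t.word)
        # X^x Z^z |i> = (-1)^{popcount(i & z)} |i ^ x>
        phases = np.where(np.bitwise_count(idx & np.uint64(z)) % 2 == 1, -1.0, 1.0)
        val = t.coeff * conv
        rows.append(idx ^ np.uint64(x))
        cols.append(idx)
        data.append(val * phases)
    if not rows:
        return scipy.sparse.csr_matrix((dim, dim), dtype=complex)
    rows = np.concatenate(rows).astype(np.int64)
    cols = np.concatenate(cols).astype(np.int64)
    data = np.concatenate(data).astype(complex)
    m = scipy.sparse.coo_matrix((data, (rows, cols)), shape=(dim, dim)).tocsr()
    return m


def stored_op_to_sparse(op: dict, n_qubits: int) -> scipy.sparse.csr_matrix:
    """Sparse matrix of a stored-form operator {(x,z): coeff}."""
    dim = 1 << n_qubits
    idx = np.arange(dim, dtype=np.uint64)
    rows, cols, data = [], [], []
    for (x, z), c in op.items():
        phases = np.where(np.bitwise_count(idx & np.uint64(z)) % 2 == 1, -1.0, 1.0)
        rows.append(idx ^ np.uint64(x))
        cols.append(idx)
        data.append(c * phases)
    if not rows:
        return scipy.sparse.csr_matrix((dim, dim), dtype=complex)
    rows = np.concatenate(rows).astype(np.int64)
    cols = np.concatenate(cols).astype(np.int64)
    data = np.concatenate(data).astype(complex)
    return scipy.sparse.coo_matrix((data, (rows, cols)), shape=(dim, dim)).tocsr()


# ---------------------------------------------------------------------------
# Second quantization + JW
# ---------------------------------------------------------------------------

def spin_orbital_integrals(moints: MOIntegrals):
    """Blocked spin-orbital integrals: h_so (2m x 2m) and antisymmetrized
    physicists' <pq||rs> (2m)^4 tensor."""
    m = moints.n_orbitals
    n_so = 2 * m
    h_so = np.zeros((n_so, n_so))
    h_so[:m, :m] = moints.h
    h_so[m:, m:] = moints.h
    # physicists <pq|rs> = chemists (pr|qs), spin delta on (p,r) and (q,s)
    g_phys = np.zeros((n_so,) * 4)
    g_sp = moints.g.transpose(0, 2, 1, 3)  # <pq|rs> spatial
    for s1 in (0, 1):
        for s2 in (0, 1):
            o1, o2 = s1 * m, s2 * m
            g_phys[o1:o1 + m, o2:o2 + m, o1:o1 + m, o2:o2 + m] = g_sp
    g_anti = g_phys - g_phys.transpose(0, 1, 3, 2)
    return h_so, g_anti


def jordan_wigner(moints: MOIntegrals, prune: float = 1e-12) -> QubitHamiltonian:
    """JW-map the second-quantized Hamiltonian of the given MO integrals.

    H = E0 + sum_pq h_pq a+_p a_q
           + 1/2 sum_{pqrs} <pq|rs> a+_p a+_q a_s a_r   (spin orbitals)
    """
    m = moints.n_orbitals
    n_qubits = 2 * m
    h, g = moints.h, moints.g
    stored: dict = {(0, 0): complex(moints.E0)}

    def add(op: dict, factor: float):
        for k, c in op.items():
            stored[k] = stored.get(k, 0.0) + factor * c

    cre = [_creation(q) for q in range(n_qubits)]
    ann = [_annihilation(q) for q in range(n_qubits)]

    # one-electron: same-spin blocks
    for p in range(m):
        for q in range(m):
            if abs(h[p, q]) < prune:
                continue
            for s in (0, 1):
                add(_op_mul(cre[p + s * m], ann[q + s * m]), h[p, q])

    # two-electron: 1/2 sum <p s1, q s2 | r s1, s s2> a+_{p s1} a+_{q s2} a_{s s2} a_{r s1}
    g_sp = g.transpose(0, 2, 1, 3)  # <pq|rs> spatial part
    for p in range(m):
        for q in range(m):
            for r in range(m):
                for s in range(m):
                    val = g_sp[p, q, r, s]
                    if abs(val) < prune:
                        continue
                    for s1 in (0, 1):
                        for s2 in (0, 1):
                            P, Q = p + s1 * m, q + s2 * m
                            R, S = r + s1 * m, s + s2 * m
                            if P == Q or R == S:
                                continue
                            op = _op_mul(_op_mul(cre[P], cre[Q]),
                                         _op_mul(ann[S], ann[R]))
                            add(op, 0.5 * val)

    return _stored_terms_to_hamiltonian(stored, n_qubits, prune=prune)


def excitation_generator(excitation, n_qubits: int) -> scipy.sparse.csr_matrix:
    """Sparse anti-Hermitian generator tau - tau^dag of a single or double
    excitation given as (i, a) or (i, j, a, b) in spin orbitals."""
    if len(excitation) == 2:
        i, a = excitation
        tau = _op_mul(_creation(a), _annihilation(i))
    elif len(excitation) == 4:
        i, j, a, b = excitation
        tau = _op_mul(_op_mul(_creation(a), _creation(b)),
                      _op_mul(_annihilation(j), _annihilation(i)))
    else:
        raise ValueError("excitation must be (i,a) or (i,j,a,b)")
    # tau - tau^dag ; dagger of stored term ((x,z), c): (X^x Z^z)^+ = Z^z X^x
    # = (-1)^{|x & z|} X^x Z^z, coefficient conjugated
    dag = {}
    for (x, z), c in tau.items():
        sign = -1.0 if (int(x & z).bit_count() % 2) else 1.0
        dag[(x, z)] = dag.get((x, z), 0.0) + sign * np.conj(c)
    gen = {k: tau.get(k, 0.0) - dag.get(k, 0.0) for k in set(tau) | set(dag)}
    gen = {k: c for k, c in gen.items() if abs(c) > 1e-16}
    mat = stored_op_to_sparse(gen, n_qubits)
    if mat.nnz and float(np.abs(mat.data.imag).max()) > 1e-14:
        raise AssertionError("excitation generator should be real")
    return scipy.sparse.csr_matrix(mat.real)


def number_operator(n_qubits: int) -> QubitHamiltonian:
    """Total particle number sum_q (I - Z_q)/2 as a Pauli-term operator."""
    terms = [PauliTerm(word="I" * n_qubits, coeff=n_qubits / 2.0)]
    for q in range(n_qubits):
        w = ["I"] * n_qubits
        w[q] = "Z"
        terms.append(PauliTerm(word="".join(w), coeff=-0.5))
    return QubitHamiltonian(terms=terms, n_qubits=n_qubits)


def pauli_sparse_matrix(word: str) -> scipy.sparse.csr_matrix:
    """Sparse matrix of a single Pauli word (coefficient 1)."""
    return _terms_to_sparse([PauliTerm(word=word, coeff=1.0)], len(word))


def commutes_with(h1: QubitHamiltonian, h2: QubitHamiltonian,
                  tol: float = 1e-10) -> bool:
    """Symbolic check that [h1, h2] = 0 on the Pauli algebra."""
    comm: dict = {}
    for t1 in h1.terms:
        x1, z1, c1conv = pauli_word_to_masks(t1.word)
        for t2 in h2.terms:
            x2, z2, c2conv = pauli_word_to_masks(t2.word)
            ca = t1.coeff * c1conv
            cb = t2.coeff * c2conv
            k_ab, c_ab = _mul(((x1, z1), ca), ((x2, z2), cb))
            k_ba, c_ba = _mul(((x2, z2), cb), ((x1, z1), ca))
            comm[k_ab] = comm.get(k_ab, 0.0) + c_ab
            comm[k_ba] = comm.get(k_ba, 0.0) - c_ba
    return all(abs(c) < tol for c in comm.values())
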