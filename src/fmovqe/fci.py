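"""Determinant-basis full configuration interaction (FCI).

Exact diagonalization of the second-quantized Hamiltonian in the basis of
Slater determinants with fixed particle number and S_z = 0, built directly
from MO integrals with the Slater-Condon rules.  This solver never touches
the Jordan-Wigner/qubit route, so it serves as the independent classical
oracle against which the qubit-sector diagonalization and the VQE energies
are checked.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .qubit import MOIntegrals, spin_orbital_integrals

__all__ = ["fci_ground_energy", "fci_matrix", "sz_zero_determinants"]


def sz_zero_determinants(n_orbitals: int, n_electrons: int) -> list[tuple[int, ...]]:
    """All determinants (sorted spin-orbital tuples, blocked alpha/beta
    convention) with n_alpha = n_beta = n_electrons/2."""
    if n_electrons % 2 != 0:
        raise ValueError("S_z = 0 requires an even electron count")
    n_each = n_electrons // 2
    if n_each > n_orbitals:
        raise ValueError("more electron pairs than spatial orbitals")
    alphas = list(combinations(range(n_orbitals), n_each))
    betas = [tuple(p + n_orbitals for p in occ) for occ in alphas]
    return [tuple(sorted(a + b)) for a in alphas for b in betas]


def _excitation(det1, det2):
    """(holes, particles) between two determinants, or None if rank > 2."""
    s1, s2 = set(det1), set(det2)
    holes = sorted(s1 - s2)
    parts = sorted(s2 - s1)
    if len(holes) > 2:
        return None
    return holes, parts


def _phase(det1, det2, holes, parts):
    """Fermionic sign aligning det2's ordering with det1's after the
    hole -> particle substitution."""
    det = list(det1)
    sign = 1
    for h, p in zip(holes, parts):
        i = det.index(h)
        det[i] = p
        # move the replaced orbital to its sorted position, counting swaps
        j = i
        while j > 0 and det[j - 1] > det[j]:
            det[j - 1], det[j] = det[j], det[j - 1]
            j -= 1
            sign = -sign
        while j < len(det) - 1 and det[j + 1] < det[j]:
            det[j + 1], det[j] = det[j], det[j + 1]
            j += 1
            sign = -sign
    assert tuple(det) == tuple(det2)
    return sign


def fci_matrix(moints: MOIntegrals, n_electrons: int) -> tuple[np.ndarray, list]:
    """Dense Hamiltonian in the S_z = 0 determinant sector."""
    h, g = spin_orbital_integrals(moints)  # g is antisymmetrized <pq||rs>
    dets = sz_zero_determinants(moints.n_orbitals, n_electrons)
    dim = len(dets)
    H = np.zeros((dim, dim))
    for I in range(dim):
        d1 = dets[I]
        occ = list(d1)
        # diagonal
        e = moints.E0 + sum(h[p, p] for p in occ)
        e += 0.5 * sum(g[p, q, p, q] for p in occ for q in occ)
        H[I, I] = e
        for J in range(I + 1, dim):
            d2 = dets[J]
            exc = _excitation(d1, d2)
            if exc is None:
                continue
            holes, parts = exc
            if len(holes) == 1:
                (i,), (a,) = holes, parts
                val = h[i, a] + sum(g[i, p, a, p] for p in occ if p != i)
            else:
                (i, j), (a, b) = holes, parts
                val = g[i, j, a, b]
            val *= _phase(d1, d2, holes, parts)
            H[I, J] = H[J, I] = val
    return H, dets


def fci_ground_energy(moints: MOIntegrals, n_electrons: int,
                      return_vector: bool = False):
    """Lowest eigenvalue (and optionally eigenvector) in the S_z = 0 sector."""
    H, dets = fci_matrix(moints, n_electrons)
    if H.shape[0] <= 1500:
        w, v = scipy.linalg.eigh(H)
        e0, v0 = float(w[0]), v[:, 0]
    else:
        w, v = scipy.sparse.linalg.eigsh(scipy.sparse.csr_matrix(H), k=1, which="SA")
        e0, v0 = float(w[0]), v[:, 0]
    if return_vector:
        return e0, v0, dets
    return e0
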