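"""Closed-form one- and two-electron integrals over contracted s Gaussians.

For s-type primitives with exponents a, b on centers A, B (p = a + b,
P = (aA + bB)/p, K = exp(-ab/p |A-B|^2)):

    overlap   (pi/p)^{3/2} K
    kinetic   ab/p (3 - 2ab/p |A-B|^2) S
    nuclear   -Z 2 pi / p K F0(p |P-C|^2)
    (ab|cd)   2 pi^{5/2} / (p q sqrt(p+q)) K_ab K_cd F0(pq/(p+q) |P-Q|^2)

with the Boys function F0(t) = erf(sqrt t) sqrt(pi/t) / 2.  Everything is in
Hartree atomic units; two-electron integrals use the chemists' convention
(mu nu | lambda sigma) with the two sides allowed to come from different
subsystems (needed for exact cross-fragment embedding potentials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .basis import BasisSet

__all__ = ["AOIntegrals", "compute_ao_integrals", "overlap", "kinetic",
           "nuclear_attraction", "eri", "nuclear_repulsion"]


def boys_f0(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    mask = t > 1e-14
    tm = t[mask]
    out[mask] = 0.5 * np.sqrt(np.pi / tm) * erf(np.sqrt(tm))
    return out


class _PairTable:
    """Primitive-pair data for all function pairs of two basis sets."""

    def __init__(self, b1: BasisSet, b2: BasisSet):
        self.n1, self.n2 = b1.n_functions, b2.n_functions
        self.p = []       # [i][j] -> (np_i*np_j,) combined exponents
        self.P = []       # Gaussian product centers
        self.cK = []      # contraction coeff product * K_ab
        self.ab_over_p = []
        self.r2 = []
        for f1 in b1.functions:
            row_p, row_P, row_cK, row_ab, row_r2 = [], [], [], [], []
            for f2 in b2.functions:
                a = f1.exponents[:, None]
                b = f2.exponents[None, :]
                p = (a + b).ravel()
                mu = (a * b / (a + b)).ravel()
                diff = f1.center - f2.center
                r2 = float(diff @ diff)
                K = np.exp(-mu * r2)
                c = (f1.coefficients[:, None] * f2.coefficients[None, :]).ravel()
                P = (a[..., None] * f1.center + b[..., None] * f2.center) / (a + b)[..., None]
                row_p.append(p)
                row_P.append(P.reshape(-1, 3))
                row_cK.append(c * K)
                row_ab.append(mu)
                row_r2.append(r2)
            self.p.append(row_p)
            self.P.append(row_P)
            self.cK.append(row_cK)
            self.ab_over_p.append(row_ab)
            self.r2.append(row_r2)


def overlap(b1: BasisSet, b2: BasisSet) -> np.ndarray:
    t = _PairTable(b1, b2)
    S = np.empty((t.n1, t.n2))
    for i in range(t.n1):
        for j in range(t.n2):
            S[i, j] = np.sum(t.cK[i][j] * (np.pi / t.p[i][j]) ** 1.5)
    return S


def kinetic(b1: BasisSet, b2: BasisSet) -> np.ndarray:
    t = _PairTable(b1, b2)
    T = np.empty((t.n1, t.n2))
    for i in range(t.n1):
        for j in range(t.n2):
            mu = t.ab_over_p[i][j]
            s = t.cK[i][j] * (np.pi / t.p[i][j]) ** 1.5
            T[i, j] = np.sum(mu * (3.0 - 2.0 * mu * t.r2[i][j]) * s)
    return T


def nuclear_attraction(b1: BasisSet, b2: BasisSet, nuclei) -> np.ndarray:
    """Potential-energy matrix -sum_A Z_A (mu| 1/|r-R_A| |nu) (negative)."""
    t = _PairTable(b1, b2)
    V = np.zeros((t.n1, t.n2))
    for i in range(t.n1):
        for j in range(t.n2):
            p = t.p[i][j]
            pref = t.cK[i][j] * 2.0 * np.pi / p
            acc = 0.0
            for Z, C in nuclei:
                d = t.P[i][j] - C
                acc += -Z * np.sum(pref * boys_f0(p * np.einsum("kx,kx->k", d, d)))
            V[i, j] = acc
    return V


def eri(b1: BasisSet, b2: BasisSet, b3: BasisSet, b4: BasisSet) -> np.ndarray:
    """Chemists' (12|34) tensor; (b1,b2) and (b3,b4) may differ."""
    t12 = _PairTable(b1, b2)
    t34 = _PairTable(b3, b4)
    same_bra = b1 is b2
    same_ket = b3 is b4
    out = np.empty((t12.n1, t12.n2, t34.n1, t34.n2))
    two_pi_52 = 2.0 * np.pi ** 2.5
    for i in range(t12.n1):
        j_range = range(i, t12.n2) if same_bra else range(t12.n2)
        for j in j_range:
            p = t12.p[i][j][:, None]
            cP = t12.cK[i][j][:, None]
            Pc = t12.P[i][j]
            for k in range(t34.n1):
                l_range = range(k, t34.n2) if same_ket else range(t34.n2)
                for l in l_range:
                    q = t34.p[k][l][None, :]
                    cQ = t34.cK[k][l][None, :]
                    d = Pc[:, None, :] - t34.P[k][l][None, :, :]
                    r2 = np.einsum("ijx,ijx->ij", d, d)
                    alpha = p * q / (p + q)
                    val = np.sum(
                        cP * cQ * two_pi_52 / (p * q * np.sqrt(p + q))
                        * boys_f0(alpha * r2)
                    )
                    out[i, j, k, l] = val
                    if same_ket:
                        out[i, j, l, k] = val
            if same_bra:
                out[j, i] = out[i, j]
    return out


def nuclear_repulsion(nuclei_a, nuclei_b=None) -> float:
    """Z_A Z_B / R sum; intra (triangular) if one set, full cross sum if two."""
    if nuclei_b is None:
        e = 0.0
        for i, (zi, ri) in enumerate(nuclei_a):
            for zj, rj in nuclei_a[i + 1:]:
                e += zi * zj / np.linalg.norm(ri - rj)
        return e
    e = 0.0
    for zi, ri in nuclei_a:
        for zj, rj in nuclei_b:
            e += zi * zj / np.linalg.norm(ri - rj)
    return e


@dataclass(frozen=True)
class AOIntegrals:
    """AO matrices of one subsystem plus its intra-subsystem nuclear repulsion."""

    basis: BasisSet
    S: np.ndarray
    T: np.ndarray
    V: np.ndarray          # own-nuclei attraction (negative definite-ish)
    g: np.ndarray          # chemists' (mu nu|lambda sigma)
    e_nuc: float

    @property
    def n_functions(self) -> int:
        return self.basis.n_functions

    @property
    def hcore(self) -> np.ndarray:
        return self.T + self.V


def compute_ao_integrals(basis: BasisSet) -> AOIntegrals:
    """All AO integrals of a subsystem in its own basis."""
    S = overlap(basis, basis)
    T = kinetic(basis, basis)
    V = nuclear_attraction(basis, basis, basis.nuclei)
    g = eri(basis, basis, basis, basis)
    e_nuc = nuclear_repulsion(basis.nuclei)
    return AOIntegrals(basis=basis, S=S, T=T, V=V, g=g, e_nuc=e_nuc)
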