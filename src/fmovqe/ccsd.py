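"""Spin-orbital coupled cluster with singles and doubles (CCSD).

Classical correlation backend and accuracy reference, implemented with the
standard one- and two-particle intermediates of the spin-orbital CCSD
equations.  Exact for two-electron systems (where it coincides with FCI),
size-extensive, and cheap at the fragment sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qubit import MOIntegrals, spin_orbital_integrals

__all__ = ["CCSDResult", "ccsd"]


class CCSDConvergenceError(RuntimeError):
    pass


@dataclass
class CCSDResult:
    e_corr: float
    e_hf: float
    n_iterations: int
    converged: bool

    @property
    def e_total(self) -> float:
        return self.e_hf + self.e_corr


def ccsd(moints: MOIntegrals, n_electrons: int,
         conv: float = 1e-10, max_iter: int = 200) -> CCSDResult:
    """Iterate the CCSD amplitude equations to convergence.

    ``moints`` may describe an embedded fragment (the embedding rides in h
    and E0); the correlation energy is measured from the corresponding
    embedded HF determinant.
    """
    h, g = spin_orbital_integrals(moints)  # g = <pq||rs>
    n_so = h.shape[0]
    if n_electrons > n_so:
        raise ValueError("more electrons than spin orbitals")
    # Blocked spin-orbital order puts occupied alpha at 0..nocc/2-1 and occupied
    # beta at m..m+nocc/2-1.  Reorder to occupied-first for slice arithmetic.
    m = n_so // 2
    n_occ_sp = n_electrons // 2
    occ = list(range(n_occ_sp)) + list(range(m, m + n_occ_sp))
    vir = [p for p in range(n_so) if p not in occ]
    order = occ + vir
    h = h[np.ix_(order, order)]
    g = g[np.ix_(order, order, order, order)]
    nocc, nvir = len(occ), len(vir)
    o, v = slice(0, nocc), slice(nocc, n_so)

    # Fock matrix in the reordered spin-orbital basis
    f = h + np.einsum("piqi->pq", g[:, o, :, o])
    e_hf_elec = np.einsum("ii->", h[o, o]) + 0.5 * np.einsum("ijij->", g[o, o, o, o])
    e_hf = float(e_hf_elec) + moints.E0

    if nvir == 0:  # complete occupation: no excitations, no correlation
        return CCSDResult(e_corr=0.0, e_hf=e_hf, n_iterations=0, converged=True)

    fo = np.diag(f)[o]
    fv = np.diag(f)[v]
    D1 = fo[:, None] - fv[None, :]
    D2 = fo[:, None, None, None] + fo[None, :, None, None] \
        - fv[None, None, :, None] - fv[None, None, None, :]
    if np.abs(D2).min() < 1e-10:
        raise CCSDConvergenceError("vanishing CCSD denominator (degenerate gap)")

    t1 = np.zeros((nocc, nvir))
    t2 = g[o, o, v, v] / D2  # MP2 start

    def energy(t1, t2):
        e = np.einsum("ia,ia->", f[o, v], t1)
        e += 0.25 * np.einsum("ijab,ijab->", g[o, o, v, v], t2)
        e += 0.5 * np.einsum("ijab,ia,jb->", g[o, o, v, v], t1, t1)
        return float(e)

    e_old = energy(t1, t2)
    diis_t, diis_e = [], []
    for it in range(1, max_iter + 1):
        tau_t = t2 + 0.5 * (np.einsum("ia,jb->ijab", t1, t1)
                            - np.einsum("ib,ja->ijab", t1, t1))
        tau = t2 + np.einsum("ia,jb->ijab", t1, t1) - np.einsum("ib,ja->ijab", t1, t1)

        Fae = f[v, v] - np.diag(np.diag(f[v, v]))
        Fae -= 0.5 * np.einsum("me,ma->ae", f[o, v], t1)
        Fae += np.einsum("mf,mafe->ae", t1, g[o, v, v, v])
        Fae -= 0.5 * np.einsum("mnaf,mnef->ae", tau_t, g[o, o, v, v])

        Fmi = f[o, o] - np.diag(np.diag(f[o, o]))
        Fmi += 0.5 * np.einsum("ie,me->mi", t1, f[o, v])
        Fmi += np.einsum("ne,mnie->mi", t1, g[o, o, o, v])
        Fmi += 0.5 * np.einsum("inef,mnef->mi", tau_t, g[o, o, v, v])

        Fme = f[o, v] + np.einsum("nf,mnef->me", t1, g[o, o, v, v])

        Wmnij = g[o, o, o, o].copy()
        Wmnij += np.einsum("je,mnie->mnij", t1, g[o, o, o, v])
        Wmnij -= np.einsum("ie,mnje->mnij", t1, g[o, o, o, v])
        Wmnij += 0.25 * np.einsum("ijef,mnef->mnij", tau, g[o, o, v, v])

        Wabef = g[v, v, v, v].copy()
        Q = np.einsum("mb,amef->abef", t1, g[v, o, v, v])
        Wabef -= Q
        Wabef += np.einsum("ma,bmef->abef", t1, g[v, o, v, v])
        Wabef += 0.25 * np.einsum("mnab,mnef->abef", tau, g[o, o, v, v])

        Wmbej = g[o, v, v, o].copy()
        Wmbej += np.einsum("jf,mbef->mbej", t1, g[o, v, v, v])
        Wmbej -= np.einsum("nb,mnej->mbej", t1, g[o, o, v, o])
        Wmbej -= np.einsum("jnfb,mnef->mbej", 0.5 * t2
                           + np.einsum("jf,nb->jnfb", t1, t1), g[o, o, v, v])

        # T1 equation
        rhs1 = f[o, v].copy()
        rhs1 += np.einsum("ie,ae->ia", t1, Fae)
        rhs1 -= np.einsum("ma,mi->ia", t1, Fmi)
        rhs1 += np.einsum("imae,me->ia", t2, Fme)
        rhs1 -= np.einsum("nf,naif->ia", t1, g[o, v, o, v])
        rhs1 -= 0.5 * np.einsum("imef,maef->ia", t2, g[o, v, v, v])
        rhs1 -= 0.5 * np.einsum("mnae,nmei->ia", t2, g[o, o, v, o])
        t1_new = rhs1 / D1

        # T2 equation
        rhs2 = g[o, o, v, v].copy()
        tmp = np.einsum("ijae,be->ijab", t2, Fae - 0.5 * np.einsum("mb,me->be", t1, Fme))
        rhs2 += tmp - tmp.transpose(0, 1, 3, 2)
        tmp = np.einsum("imab,mj->ijab", t2, Fmi + 0.5 * np.einsum("je,me->mj", t1, Fme))
        rhs2 -= tmp - tmp.transpose(1, 0, 2, 3)
        rhs2 += 0.5 * np.einsum("mnab,mnij->ijab", tau, Wmnij)
        rhs2 += 0.5 * np.einsum("ijef,abef->ijab", tau, Wabef)
        tmp = np.einsum("imae,mbej->ijab", t2, Wmbej)
        tmp -= np.einsum("ie,ma,mbej->ijab", t1, t1, g[o, v, v, o])
        tmp = tmp - tmp.transpose(0, 1, 3, 2)
        rhs2 += tmp - tmp.transpose(1, 0, 2, 3)
        tmp = np.einsum("ie,abej->ijab", t1, g[v, v, v, o])
        rhs2 += tmp - tmp.transpose(1, 0, 2, 3)
        tmp = np.einsum("ma,mbij->ijab", t1, g[o, v, o, o])
        rhs2 -= tmp - tmp.transpose(0, 1, 3, 2)
        t2_new = rhs2 / D2

        # DIIS on the concatenated amplitude vector
        t_vec = np.concatenate([t1_new.ravel(), t2_new.ravel()])
        e_vec = np.concatenate([(t1_new - t1).ravel(), (t2_new - t2).ravel()])
        diis_t.append(t_vec)
        diis_e.append(e_vec)
        if len(diis_t) > 8:
            diis_t.pop(0)
            diis_e.pop(0)
        if len(diis_t) > 1:
            k = len(diis_t)
            B = -np.ones((k + 1, k + 1))
            B[k, k] = 0.0
            for a_ in range(k):
                for b_ in range(k):
                    B[a_, b_] = diis_e[a_] @ diis_e[b_]
            rhs = np.zeros(k + 1)
            rhs[k] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:k]
                t_vec = sum(ci * ti for ci, ti in zip(c, diis_t))
            except np.linalg.LinAlgError:
                pass
        t1 = t_vec[: nocc * nvir].reshape(nocc, nvir)
        t2 = t_vec[nocc * nvir:].reshape(nocc, nocc, nvir, nvir)

        e_new = energy(t1, t2)
        d_amp = float(np.abs(e_vec).max())
        if abs(e_new - e_old) < conv and d_amp < np.sqrt(conv):
            return CCSDResult(e_corr=e_new, e_hf=e_hf, n_iterations=it, converged=True)
        e_old = e_new
    raise CCSDConvergenceError(f"CCSD not converged in {max_iter} iterations "
                               f"(last E_corr = {e_old:.10f})")
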