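"""Restricted Hartree-Fock for fragments embedded in the exact electrostatic
potential of the surrounding fragments.

Every fragment (monomer) and fragment pair (dimer) is solved by closed-shell
Roothaan SCF with DIIS.  The embedding operator of a subsystem collects the
one-electron Coulomb potential of all environment nuclei and environment
electron densities, evaluated with exact cross-fragment two-electron
integrals (no point-charge approximation), plus the scalar interaction of
the subsystem's nuclei with the environment.

The self-consistent-charge (SCC) loop iterates all monomer SCFs against
each other's densities until the monomer energies are stationary; dimers
are then solved once each in the frozen SCC-converged environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .geometry import ClusterGeometry, FragmentScheme, fragment_geometry
from .basis import BasisSet, build_basis
from .integrals import (AOIntegrals, compute_ao_integrals, eri,
                        nuclear_attraction, nuclear_repulsion)

__all__ = ["EmbeddingOperator", "SCFState", "MonomerState", "DimerState",
           "FragmentSubsystem", "rhf", "build_embedding", "scc_monomers",
           "solve_dimer", "SCFError"]


class SCFError(RuntimeError):
    def __init__(self, message, last_energy=None):
        super().__init__(message)
        self.last_energy = last_energy


@dataclass(frozen=True)
class EmbeddingOperator:
    """One-electron environment potential U and scalar nuclear/env term.

    ``U`` acts in the target subsystem's AO basis; ``scalar`` is the
    interaction energy of the target *nuclei* with environment nuclei and
    environment electron densities.  Both vanish for an empty environment.
    """

    U: np.ndarray
    scalar: float = 0.0

    @classmethod
    def empty(cls, n: int) -> "EmbeddingOperator":
        return cls(U=np.zeros((n, n)), scalar=0.0)

    @property
    def norm_inf(self) -> float:
        return float(np.abs(self.U).max()) if self.U.size else 0.0


@dataclass
class SCFState:
    """Converged closed-shell SCF solution of a (possibly embedded) subsystem."""

    ints: AOIntegrals
    embedding: EmbeddingOperator
    n_electrons: int
    C: np.ndarray            # MO coefficients (AO x MO)
    eps: np.ndarray          # orbital energies
    D: np.ndarray            # AO density, Tr(D S) = n_electrons
    energy: float            # embedded total energy (Ha)
    energy_internal: float   # embedding interaction subtracted (Ha)
    n_cycles: int
    converged: bool

    @property
    def n_orbitals(self) -> int:
        return self.ints.n_functions

    @property
    def n_occupied(self) -> int:
        return self.n_electrons // 2

    @property
    def occupations(self) -> np.ndarray:
        occ = np.zeros(self.n_orbitals)
        occ[: self.n_occupied] = 2.0
        return occ


@dataclass
class FragmentSubsystem:
    """A fragment (or fragment pair) with its basis and integrals."""

    label: str
    atom_indices: tuple[int, ...]
    geometry: ClusterGeometry
    basis: BasisSet
    ints: AOIntegrals
    n_electrons: int

    @classmethod
    def from_fragment(cls, geom: ClusterGeometry, atoms, charge: int,
                      basis_name: str, label: str) -> "FragmentSubsystem":
        sub = fragment_geometry(geom, atoms, charge)
        basis = build_basis(sub, basis_name)
        return cls(label=label, atom_indices=tuple(atoms), geometry=sub,
                   basis=basis, ints=compute_ao_integrals(basis),
                   n_electrons=sub.n_electrons)


# Monomer/dimer states carry the subsystem so downstream stages (MO
# transformation, correlation) can reuse the integrals.

@dataclass
class MonomerState(SCFState):
    subsystem: FragmentSubsystem = None
    fragment_index: int = -1


@dataclass
class DimerState(SCFState):
    subsystem: FragmentSubsystem = None
    pair: tuple[int, int] = (-1, -1)


def build_embedding(target: FragmentSubsystem,
                    environment: Sequence[tuple[FragmentSubsystem, np.ndarray]],
                    ) -> EmbeddingOperator:
    """Exact electrostatic potential of the environment in the target basis.

    environment: (subsystem, converged AO density) pairs for every fragment
    outside the target.
    """
    n = target.ints.n_functions
    U = np.zeros((n, n))
    scalar = 0.0
    for env, D_env in environment:
        # environment nuclei attraction on target electrons
        U += nuclear_attraction(target.basis, target.basis, env.basis.nuclei)
        # environment electron density Coulomb on target electrons
        g_cross = eri(target.basis, target.basis, env.basis, env.basis)
        U += np.einsum("mnls,ls->mn", g_cross, D_env)
        # target nuclei <-> environment nuclei
        scalar += nuclear_repulsion(target.basis.nuclei, env.basis.nuclei)
        # target nuclei attraction on environment electrons
        v_env = nuclear_attraction(env.basis, env.basis, target.basis.nuclei)
        scalar += float(np.einsum("ls,ls->", D_env, v_env))
    return EmbeddingOperator(U=U, scalar=scalar)


def _diis_extrapolate(fock_list, err_list):
    m = len(fock_list)
    B = -np.ones((m + 1, m + 1))
    B[m, m] = 0.0
    for i in range(m):
        for j in range(m):
            B[i, j] = np.vdot(err_list[i], err_list[j])
    rhs = np.zeros(m + 1)
    rhs[m] = -1.0
    try:
        c = np.linalg.solve(B, rhs)
    except np.linalg.LinAlgError:
        return fock_list[-1]
    F = np.zeros_like(fock_list[-1])
    for i in range(m):
        F += c[i] * fock_list[i]
    return F


def rhf(ints: AOIntegrals,
        n_electrons: int,
        embedding: Optional[EmbeddingOperator] = None,
        conv_dens: float = 1e-8,
        conv_energy: float = 1e-10,
        max_cycles: int = 200,
        diis_size: int = 8,
        ) -> SCFState:
    """Closed-shell Roothaan SCF with DIIS acceleration.

    Returns both the embedded total energy (one-electron part includes the
    embedding operator U, and the scalar environment term is added) and the
    internal energy with the embedding interaction subtracted.
    """
    if n_electrons <= 0 or n_electrons % 2 != 0:
        raise ValueError(f"need an even positive electron count, got {n_electrons}")
    n = ints.n_functions
    n_occ = n_electrons // 2
    if n_occ > n:
        raise ValueError(f"{n_electrons} electrons do not fit in {n} spatial orbitals")
    emb = embedding if embedding is not None else EmbeddingOperator.empty(n)
    S = ints.S
    hcore = ints.hcore + emb.U
    g = ints.g

    def fock(D):
        J = np.einsum("mnls,ls->mn", g, D)
        K = np.einsum("mlns,ls->mn", g, D)
        return hcore + J - 0.5 * K

    def energy_of(D, F):
        e_elec = 0.5 * float(np.einsum("mn,mn->", D, hcore + F))
        return e_elec + ints.e_nuc + emb.scalar

    # core-Hamiltonian (plus embedding) initial guess
    eps, C = scipy.linalg.eigh(hcore, S)
    Cocc = C[:, :n_occ]
    D = 2.0 * Cocc @ Cocc.T
    e_old = None
    focks, errs = [], []
    for cycle in range(1, max_cycles + 1):
        F = fock(D)
        err = F @ D @ S - S @ D @ F
        focks.append(F.copy())
        errs.append(err.ravel().copy())
        if len(focks) > diis_size:
            focks.pop(0)
            errs.pop(0)
        if len(focks) > 1:
            F_eff = _diis_extrapolate(focks, errs)
        else:
            F_eff = F
        eps, C = scipy.linalg.eigh(F_eff, S)
        Cocc = C[:, :n_occ]
        D_new = 2.0 * Cocc @ Cocc.T
        F_new = fock(D_new)
        e_new = energy_of(D_new, F_new)
        delta_d = float(np.abs(D_new - D).max())
        delta_e = np.inf if e_old is None else abs(e_new - e_old)
        D, e_old = D_new, e_new
        if delta_d < conv_dens and delta_e < conv_energy:
            e_internal = e_new - float(np.einsum("mn,mn->", D, emb.U)) - emb.scalar
            return SCFState(ints=ints, embedding=emb, n_electrons=n_electrons,
                            C=C, eps=eps, D=D, energy=e_new,
                            energy_internal=e_internal, n_cycles=cycle,
                            converged=True)
    raise SCFError(f"SCF not converged in {max_cycles} cycles "
                   f"(last E = {e_old:.10f} Ha)", last_energy=e_old)


def _as_monomer(state: SCFState, sub: FragmentSubsystem, index: int) -> MonomerState:
    return MonomerState(**{f: getattr(state, f) for f in
                           ("ints", "embedding", "n_electrons", "C", "eps", "D",
                            "energy", "energy_internal", "n_cycles", "converged")},
                        subsystem=sub, fragment_index=index)


def scc_monomers(geom: ClusterGeometry,
                 scheme: FragmentScheme,
                 basis_name: str,
                 conv: float = 1e-7,
                 max_sweeps: int = 100,
                 ) -> list[MonomerState]:
    """Self-consistent-charge loop over all monomers.

    Every monomer starts from its isolated SCF; each sweep rebuilds all
    embedding operators from the previous sweep's densities (synchronous,
    Jacobi-style update, so the fixed point is independent of fragment
    order) and re-solves every monomer.  Converged when no monomer energy
    moves by more than ``conv`` Ha between sweeps.
    """
    scheme.validate_against(geom)
    subs = [FragmentSubsystem.from_fragment(geom, atoms, charge, basis_name,
                                            label=f"frag{i}")
            for i, (atoms, charge) in enumerate(scheme.fragments)]
    states = [_as_monomer(rhf(sub.ints, sub.n_electrons), sub, i)
              for i, sub in enumerate(subs)]
    if len(subs) == 1:
        return states
    for sweep in range(1, max_sweeps + 1):
        densities = [st.D.copy() for st in states]
        new_states = []
        for i, sub in enumerate(subs):
            env = [(subs[j], densities[j]) for j in range(len(subs)) if j != i]
            emb = build_embedding(sub, env)
            new_states.append(_as_monomer(rhf(sub.ints, sub.n_electrons, emb), sub, i))
        delta = max(abs(new_states[i].energy - states[i].energy)
                    for i in range(len(subs)))
        states = new_states
        if delta < conv:
            return states
    raise SCFError(f"SCC not converged in {max_sweeps} sweeps (last delta = {delta:.3e} Ha)")


def solve_dimer(i: int, j: int,
                monomers: Sequence[MonomerState],
                geom: ClusterGeometry,
                scheme: FragmentScheme,
                basis_name: str,
                ) -> DimerState:
    """Single dimer SCF in the field of the N-2 remaining fragments, with
    environment densities frozen at their SCC-converged values."""
    if i == j:
        raise ValueError("dimer needs two distinct fragments")
    i, j = sorted((i, j))
    atoms = scheme.fragments[i][0] + scheme.fragments[j][0]
    charge = scheme.fragments[i][1] + scheme.fragments[j][1]
    sub = FragmentSubsystem.from_fragment(geom, atoms, charge, basis_name,
                                          label=f"dimer{i}-{j}")
    env = [(monomers[k].subsystem, monomers[k].D)
           for k in range(len(monomers)) if k not in (i, j)]
    emb = build_embedding(sub, env) if env else EmbeddingOperator.empty(sub.ints.n_functions)
    st = rhf(sub.ints, sub.n_electrons, emb)
    return DimerState(**{f: getattr(st, f) for f in
                         ("ints", "embedding", "n_electrons", "C", "eps", "D",
                          "energy", "energy_internal", "n_cycles", "converged")},
                      subsystem=sub, pair=(i, j))
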