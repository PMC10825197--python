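"""Two-body FMO energy assembly and the full FMO/VQE pipeline.

The FMO2 total energy combines monomer energies with pairwise corrections:

    E(FMO2-RHF)  = sum_I E_I + sum_{I>J} (E_IJ - E_I - E_J)
    E(FMO2-CC)   = E(FMO2-RHF) + sum_I Ec_I + sum_{I>J} (Ec_IJ - Ec_I - Ec_J)

Two conventions are exposed for the RHF part:

* ``"standard"`` (default) — internal fragment energies E' (embedding
  interaction subtracted) plus the density-relaxation coupling
  Tr(dD_IJ U_IJ) per pair, dD_IJ = D_IJ - (D_I + D_J).  This is the
  expression whose pair sum telescopes exactly, so FMO2 reproduces the
  whole-system RHF energy when there are only two fragments.
* ``"paper"`` — the embedded total energies are plugged in literally.
  The two agree in the non-interacting limit and at N_f = 2.

Correlation energies per fragment come from a pluggable backend: UCCSD or
QCC statevector VQE, or the classical CCSD solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .geometry import ClusterGeometry, FragmentScheme, auto_fragment_pairs
from .basis import build_basis
from .integrals import compute_ao_integrals
from .scf import (MonomerState, DimerState, rhf, scc_monomers, solve_dimer)
from .qubit import mo_transform, jordan_wigner
from .ccsd import ccsd
from . import vqe as _vqe
from .fci import fci_ground_energy

__all__ = ["FMOEnergyReport", "assemble_rhf", "assemble_corr", "fmo_total",
           "fragment_correlation", "whole_system_energy", "CORRELATION_BACKENDS"]

CORRELATION_BACKENDS = ("vqe-uccsd", "vqe-qcc", "ccsd-reference", "none")


@dataclass
class FragmentResult:
    label: str
    n_qubits: int
    n_parameters: int
    e_rhf: float            # embedded RHF total energy
    e_correlated: float     # embedded RHF + correlation
    e_corr: float
    backend: str
    converged: bool = True
    iterations: int = 0


@dataclass
class FMOEnergyReport:
    convention: str
    e_fmo1_rhf: float
    de_fmo2_rhf: float
    e_fmo2_rhf: float
    e_fmo1_corr: float
    de_fmo2_corr: float
    e_fmo2_corr: float
    e_total: float
    monomers: list[dict]
    dimers: list[dict]
    backend: str
    basis: str

    def to_json(self, indent: int = 2) -> str:
        payload = asdict(self)
        for key in ("e_fmo1_rhf", "de_fmo2_rhf", "e_fmo2_rhf", "e_fmo1_corr",
                    "de_fmo2_corr", "e_fmo2_corr", "e_total"):
            payload[key] = round(payload[key], 12)
        return json.dumps(payload, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "FMOEnergyReport":
        return cls(**json.loads(text))


def _pair_coupling(dimer: DimerState, mono_i: MonomerState,
                   mono_j: MonomerState) -> float:
    """Tr(dD_IJ U_IJ): density-relaxation correction of the standard FMO2
    expression.  Relies on the dimer AO basis being the concatenation of the
    two monomer bases (fragment I's functions first)."""
    ni = mono_i.D.shape[0]
    nj = mono_j.D.shape[0]
    D0 = np.zeros_like(dimer.D)
    D0[:ni, :ni] = mono_i.D
    D0[ni:ni + nj, ni:ni + nj] = mono_j.D
    dD = dimer.D - D0
    return float(np.einsum("mn,mn->", dD, dimer.embedding.U))


def assemble_rhf(monomers: Sequence[MonomerState],
                 dimers: dict[tuple[int, int], DimerState],
                 convention: str = "standard") -> tuple[float, float, float]:
    """FMO1/FMO2 RHF energies from converged monomer and dimer SCF states."""
    n = len(monomers)
    expected = {(i, j) for i in range(n) for j in range(i + 1, n)}
    missing = expected - {tuple(sorted(k)) for k in dimers}
    if missing:
        raise ValueError(f"missing dimers: {sorted(missing)}")
    if convention not in ("standard", "paper"):
        raise ValueError(f"unknown convention {convention!r}")
    if convention == "paper":
        e1 = sum(m.energy for m in monomers)
        de2 = sum(dimers[tuple(sorted(p))].energy
                  - monomers[p[0]].energy - monomers[p[1]].energy
                  for p in expected)
    else:
        e1 = sum(m.energy_internal for m in monomers)
        de2 = 0.0
        for i, j in expected:
            d = dimers[(i, j)]
            de2 += (d.energy_internal
                    - monomers[i].energy_internal - monomers[j].energy_internal)
            de2 += _pair_coupling(d, monomers[i], monomers[j])
    return float(e1), float(de2), float(e1 + de2)


def assemble_corr(mono_corr: Sequence[float],
                  dimer_corr: dict[tuple[int, int], float],
                  ) -> tuple[float, float, float]:
    """Correlation analogue: E1_corr, dE2_corr, E2_corr."""
    n = len(mono_corr)
    expected = {(i, j) for i in range(n) for j in range(i + 1, n)}
    missing = expected - {tuple(sorted(k)) for k in dimer_corr}
    if missing:
        raise ValueError(f"missing dimer correlation energies: {sorted(missing)}")
    e1 = float(sum(mono_corr))
    de2 = float(sum(dimer_corr[(i, j)] - mono_corr[i] - mono_corr[j]
                    for i, j in expected))
    return e1, de2, e1 + de2


def fragment_correlation(state, backend: str,
                         screen_threshold: float = 1e-3,
                         qcc_pool_size: Optional[int] = None) -> FragmentResult:
    """Correlation energy of one embedded monomer or dimer SCF solution."""
    label = state.subsystem.label if state.subsystem is not None else "system"
    if backend == "none":
        return FragmentResult(label=label, n_qubits=0, n_parameters=0,
                              e_rhf=state.energy, e_correlated=state.energy,
                              e_corr=0.0, backend=backend)
    mo = mo_transform(state)
    n_el = state.n_electrons
    if backend == "ccsd-reference":
        res = ccsd(mo, n_el)
        return FragmentResult(label=label, n_qubits=0, n_parameters=0,
                              e_rhf=state.energy, e_correlated=res.e_total,
                              e_corr=res.e_corr, backend=backend,
                              converged=res.converged, iterations=res.n_iterations)
    ham = jordan_wigner(mo)
    if backend == "vqe-uccsd":
        spec = _vqe.mp2_initial_amplitudes(mo, n_el, screen_threshold)
        res = _vqe.vqe_minimize_uccsd(ham, spec, n_el)
        n_params = spec.n_parameters
    elif backend == "vqe-qcc":
        res = _vqe.vqe_minimize_qcc(ham, n_el, pool_size=qcc_pool_size)
        n_params = len(res.parameters)
    else:
        raise ValueError(f"unknown correlation backend {backend!r} "
                         f"(choose from {CORRELATION_BACKENDS})")
    e_corr = _vqe.correlation_energy(res.energy, state.energy)
    return FragmentResult(label=label, n_qubits=ham.n_qubits,
                          n_parameters=n_params, e_rhf=state.energy,
                          e_correlated=res.energy, e_corr=e_corr,
                          backend=backend, converged=res.converged,
                          iterations=res.n_iterations)


def fmo_total(geom: ClusterGeometry,
              scheme: Optional[FragmentScheme],
              basis_name: str,
              backend: str = "vqe-uccsd",
              convention: str = "standard",
              screen_threshold: float = 1e-3,
              qcc_pool_size: Optional[int] = None,
              ) -> FMOEnergyReport:
    """Full FMO2 pipeline: SCC monomers -> dimers -> per-fragment
    correlation -> energy assembly."""
    if scheme is None:
        scheme = auto_fragment_pairs(geom)
    monomers = scc_monomers(geom, scheme, basis_name)
    n = len(monomers)
    dimers = {(i, j): solve_dimer(i, j, monomers, geom, scheme, basis_name)
              for i in range(n) for j in range(i + 1, n)}

    mono_res = [fragment_correlation(m, backend, screen_threshold, qcc_pool_size)
                for m in monomers]
    dim_res = {p: fragment_correlation(d, backend, screen_threshold, qcc_pool_size)
               for p, d in dimers.items()}

    e1_rhf, de2_rhf, e2_rhf = assemble_rhf(monomers, dimers, convention)
    e1_c, de2_c, e2_c = assemble_corr([r.e_corr for r in mono_res],
                                      {p: r.e_corr for p, r in dim_res.items()})

    mono_payload = []
    for m, r in zip(monomers, mono_res):
        mono_payload.append({
            "fragment": m.fragment_index, "atoms": list(m.subsystem.atom_indices),
            "n_electrons": m.n_electrons, "n_qubits": r.n_qubits,
            "n_params": r.n_parameters,
            "e_embedded": round(m.energy, 12),
            "e_internal": round(m.energy_internal, 12),
            "e_corr": round(r.e_corr, 12), "converged": r.converged,
        })
    dim_payload = []
    for (i, j) in sorted(dimers):
        d, r = dimers[(i, j)], dim_res[(i, j)]
        if convention == "paper":
            pair_corr = d.energy - monomers[i].energy - monomers[j].energy
        else:
            pair_corr = (d.energy_internal - monomers[i].energy_internal
                         - monomers[j].energy_internal
                         + _pair_coupling(d, monomers[i], monomers[j]))
        dim_payload.append({
            "pair": [i, j], "n_qubits": r.n_qubits, "n_params": r.n_parameters,
            "e_embedded": round(d.energy, 12),
            "e_internal": round(d.energy_internal, 12),
            "pair_correction_rhf": round(pair_corr, 12),
            "e_corr": round(r.e_corr, 12), "converged": r.converged,
        })
    return FMOEnergyReport(
        convention=convention,
        e_fmo1_rhf=e1_rhf, de_fmo2_rhf=de2_rhf, e_fmo2_rhf=e2_rhf,
        e_fmo1_corr=e1_c, de_fmo2_corr=de2_c, e_fmo2_corr=e2_c,
        e_total=e2_rhf + e2_c,
        monomers=mono_payload, dimers=dim_payload,
        backend=backend, basis=basis_name,
    )


def whole_system_energy(geom: ClusterGeometry, basis_name: str,
                        method: str = "rhf",
                        screen_threshold: float = 1e-3,
                        qcc_pool_size: Optional[int] = None) -> float:
    """Conventional single-system calculation (no fragmentation).

    method: rhf | ccsd | fci | vqe-uccsd | vqe-qcc.  FCI uses the
    determinant solver (independent of the qubit route).
    """
    ints = compute_ao_integrals(build_basis(geom, basis_name))
    st = rhf(ints, geom.n_electrons)
    if method == "rhf":
        return st.energy
    mo = mo_transform(st)
    if method == "ccsd":
        return ccsd(mo, geom.n_electrons).e_total
    if method == "fci":
        return fci_ground_energy(mo, geom.n_electrons)
    ham = jordan_wigner(mo)
    if method == "vqe-uccsd":
        spec = _vqe.mp2_initial_amplitudes(mo, geom.n_electrons, screen_threshold)
        return _vqe.vqe_minimize_uccsd(ham, spec, geom.n_electrons).energy
    if method == "vqe-qcc":
        return _vqe.vqe_minimize_qcc(ham, geom.n_electrons,
                                     pool_size=qcc_pool_size).energy
    raise ValueError(f"unknown method {method!r}")
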