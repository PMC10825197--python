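"""Shared fixtures: small hydrogen clusters and cached SCF/FMO results.

Everything is generated programmatically; expensive objects (the optimized
H5+ stand-in geometry, SCC-converged fragment states) are session-scoped so
the suite computes them once.
"""

import numpy as np
import pytest
from hypothesis import settings

from fmovqe.geometry import ClusterGeometry, auto_fragment_pairs
from fmovqe.basis import build_basis
from fmovqe.integrals import compute_ao_integrals
from fmovqe.scf import rhf, scc_monomers, solve_dimer
from fmovqe.clusters import (ClusterGenSpec, generate_cluster, h3_cation,
                             h5_cation, optimize_structure)
from fmovqe.fmo import whole_system_energy
from fmovqe.qubit import mo_transform

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

H2_BOND = 0.7414  # A, equilibrium H2 distance


@pytest.fixture(scope="session")
def h2_geom():
    return ClusterGeometry(("H", "H"), np.array([[0.0, 0.0, 0.0],
                                                 [0.0, 0.0, H2_BOND]]), 0)


@pytest.fixture(scope="session")
def h2_scf(h2_geom):
    return rhf(compute_ao_integrals(build_basis(h2_geom, "STO-3G")), 2)


@pytest.fixture(scope="session")
def h2_mo(h2_scf):
    return mo_transform(h2_scf)


@pytest.fixture(scope="session")
def h_anion_scf():
    geom = ClusterGeometry(("H",), np.zeros((1, 3)), total_charge=-1)
    return rhf(compute_ao_integrals(build_basis(geom, "STO-3G")), 2)


@pytest.fixture(scope="session")
def h4_geom():
    """Two interacting H2 units, slightly jittered off the lattice."""
    return generate_cluster(ClusterGenSpec(2, spacing=2.5, jitter=0.1, seed=3))


@pytest.fixture(scope="session")
def h6_geom():
    """Three H2 units at a van-der-Waals-like 3 A pitch."""
    return generate_cluster(ClusterGenSpec(3, spacing=3.0, jitter=0.1, seed=7))


@pytest.fixture(scope="session")
def h6_far_geom():
    """Three H2 units at 30 A: the non-interacting reference limit."""
    return generate_cluster(ClusterGenSpec(3, spacing=30.0))


@pytest.fixture(scope="session")
def h6_fragments(h6_geom):
    scheme = auto_fragment_pairs(h6_geom)
    monomers = scc_monomers(h6_geom, scheme, "STO-3G")
    dimers = {(i, j): solve_dimer(i, j, monomers, h6_geom, scheme, "STO-3G")
              for i in range(3) for j in range(i + 1, 3)}
    return scheme, monomers, dimers


@pytest.fixture(scope="session")
def h3p_geom():
    """Equilateral H3+ relaxed at CCSD/6-31G (1-d search, deterministic)."""
    geom, _, _ = optimize_structure(
        h3_cation, [0.9],
        lambda g: whole_system_energy(g, "6-31G", "ccsd"),
        bounds=[(0.7, 1.1)])
    return geom


@pytest.fixture(scope="session")
def h5p_geom():
    """D2d shared-proton H5+ stand-in relaxed at CCSD/6-31G."""
    geom, _, _ = optimize_structure(
        h5_cation, [1.15, 0.78],
        lambda g: whole_system_energy(g, "6-31G", "ccsd"))
    return geom
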