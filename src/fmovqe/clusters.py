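"""Synthetic hydrogen-cluster generation and prototype ion geometries.

The lattice generator produces H2 clusters for testing and benchmarking:
molecules sit on a cubic lattice with a given pitch, bonds along z, with an
optional seeded uniform jitter.  It stands in for externally optimized
cluster geometries, which are ordinary inputs to the method.

The ion builders (`h3_cation`, `h5_cation`) construct the symmetric
equilibrium motifs of H3+ (equilateral triangle) and H5+ (shared-proton
[H2-H-H2]+ with perpendicular H2 units, D2d); `optimize_structure` relaxes
the free parameters of such a motif on any energy function the caller
supplies (e.g. a CCSD or FCI total energy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize_scalar, minimize

from .geometry import ClusterGeometry

__all__ = ["ClusterGenSpec", "generate_cluster", "h3_cation", "h5_cation",
           "h3_anion", "optimize_structure"]


@dataclass(frozen=True)
class ClusterGenSpec:
    """Parameters of the lattice H2-cluster generator.

    bond_length defaults to the H2 equilibrium distance 0.7414 A; spacing is
    the lattice pitch between molecular centers.  ``extra_species`` may be
    "anion" (adds one H and sets total charge -1) or "cation" (adds one H
    and sets charge +1, so automatic fragmentation yields an H3+ core).
    """

    n_molecules: int
    bond_length: float = 0.7414
    spacing: float = 3.0
    jitter: float = 0.0
    seed: int = 0
    extra_species: Optional[str] = None

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        if self.spacing <= self.bond_length:
            raise ValueError("lattice spacing must exceed the bond length")
        if self.jitter < 0 or self.jitter >= self.spacing / 4:
            raise ValueError("jitter must lie in [0, spacing/4)")
        if self.extra_species not in (None, "anion", "cation"):
            raise ValueError("extra_species must be None, 'anion' or 'cation'")


def generate_cluster(spec: ClusterGenSpec) -> ClusterGeometry:
    """Deterministic (seeded) lattice cluster of H2 units."""
    n_sites = spec.n_molecules + (1 if spec.extra_species else 0)
    side = int(np.ceil(n_sites ** (1.0 / 3.0)))
    sites = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                sites.append(np.array([i, j, k], dtype=float) * spec.spacing)
                if len(sites) == n_sites:
                    break
            if len(sites) == n_sites:
                break
        if len(sites) == n_sites:
            break
    half = np.array([0.0, 0.0, spec.bond_length / 2.0])
    coords = []
    for center in sites[: spec.n_molecules]:
        coords.append(center - half)
        coords.append(center + half)
    charge = 0
    if spec.extra_species is not None:
        coords.append(sites[-1])
        charge = -1 if spec.extra_species == "anion" else +1
    coords = np.array(coords)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.uniform(-spec.jitter, spec.jitter, size=coords.shape)
    return ClusterGeometry(("H",) * len(coords), coords, total_charge=charge)


def h3_cation(side: float = 0.90) -> ClusterGeometry:
    """Equilateral-triangle H3+ with the given side length (A)."""
    r = side / np.sqrt(3.0)  # circumradius
    ang = np.array([90.0, 210.0, 330.0]) * np.pi / 180.0
    coords = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(3)], axis=1)
    return ClusterGeometry(("H",) * 3, coords, total_charge=+1)


def h5_cation(arm: float = 1.15, bond: float = 0.78) -> ClusterGeometry:
    """D2d shared-proton H5+: central H, two H2 units at +-z.

    ``arm`` is the distance from the central proton to each H2 centroid;
    ``bond`` the H2 bond length; the two H2 bonds are perpendicular (x / y).
    """
    b = bond / 2.0
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [-b, 0.0, arm],
            [b, 0.0, arm],
            [0.0, -b, -arm],
            [0.0, b, -arm],
        ]
    )
    return ClusterGeometry(("H",) * 5, coords, total_charge=+1)


def h3_anion(bond: float = 0.75, gap: float = 2.8) -> ClusterGeometry:
    """Linear H3-: an H2 molecule with an H- at distance ``gap`` along the axis."""
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, bond], [0.0, 0.0, bond + gap]])
    return ClusterGeometry(("H",) * 3, coords, total_charge=-1)


def optimize_structure(
    builder: Callable[..., ClusterGeometry],
    x0: np.ndarray,
    energy: Callable[[ClusterGeometry], float],
    bounds=None,
    xtol: float = 1e-4,
) -> tuple[ClusterGeometry, np.ndarray, float]:
    """Relax the free parameters of a structural motif.

    ``builder(*x)`` maps a parameter vector to a geometry and ``energy``
    evaluates it (Ha).  Nelder-Mead is used: the energy surfaces here are
    low-dimensional and smooth, and no analytic gradients exist for the
    correlated backends.  Returns (geometry, parameters, energy).
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))

    def fun(x):
        return energy(builder(*x))

    if x0.size == 1 and bounds is not None:
        res = minimize_scalar(lambda t: fun([t]), bounds=bounds[0], method="bounded",
                              options={"xatol": xtol})
        x_opt = np.array([res.x])
        e_opt = res.fun
    else:
        res = minimize(fun, x0, method="Nelder-Mead",
                       options={"xatol": xtol, "fatol": 1e-9, "maxiter": 400})
        x_opt, e_opt = res.x, res.fun
    return builder(*x_opt), x_opt, float(e_opt)
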