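"""Gaussian basis sets for hydrogen: STO-3G and 6-31G.

Both sets contract only s-type primitives on H, so every integral in this
package has a closed form (see :mod:`fmovqe.integrals`).  Exponents and
contraction coefficients are the standard published values; contracted
functions are renormalized to unit self-overlap at load time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ClusterGeometry, ANGSTROM_TO_BOHR

__all__ = ["BasisFunction", "BasisSet", "build_basis", "n_basis_functions"]

# exponents, contraction coefficients (s shells on H)
_HYDROGEN_SHELLS = {
    "STO-3G": [
        (
            np.array([3.425250914, 0.6239137298, 0.1688554040]),
            np.array([0.1543289673, 0.5353281423, 0.4446345422]),
        ),
    ],
    "6-31G": [
        (
            np.array([18.73113696, 2.825394365, 0.6401216923]),
            np.array([0.03349460434, 0.2347269535, 0.8137573261]),
        ),
        (np.array([0.1612777588]), np.array([1.0])),
    ],
}


@dataclass(frozen=True)
class BasisFunction:
    """Contracted s-type Gaussian: sum_k c_k (2 a_k / pi)^(3/4) exp(-a_k r^2)."""

    center: np.ndarray  # Bohr
    exponents: np.ndarray
    coefficients: np.ndarray  # includes primitive norms; contraction normalized


def _normalize(exponents: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
    c = coefficients * (2.0 * exponents / np.pi) ** 0.75
    a = exponents[:, None] + exponents[None, :]
    s = (np.pi / a) ** 1.5
    norm2 = c @ s @ c
    return c / np.sqrt(norm2)


@dataclass(frozen=True)
class BasisSet:
    name: str
    functions: tuple[BasisFunction, ...]
    nuclei: tuple[tuple[float, np.ndarray], ...]  # (Z, position in Bohr)

    @property
    def n_functions(self) -> int:
        return len(self.functions)


def n_basis_functions(basis_name: str, n_atoms: int) -> int:
    """Spatial orbitals per H: 1 for STO-3G, 2 for 6-31G."""
    return n_atoms * len(_shells(basis_name))


def _shells(basis_name: str):
    try:
        return _HYDROGEN_SHELLS[basis_name]
    except KeyError:
        raise ValueError(
            f"unsupported basis {basis_name!r}; available: {sorted(_HYDROGEN_SHELLS)}"
        ) from None


def build_basis(geom: ClusterGeometry, basis_name: str) -> BasisSet:
    shells = _shells(basis_name)
    functions = []
    nuclei = []
    for xyz in geom.coords:
        center = np.asarray(xyz, dtype=float) * ANGSTROM_TO_BOHR
        nuclei.append((1.0, center))
        for exps, coefs in shells:
            functions.append(
                BasisFunction(center=center, exponents=exps,
                              coefficients=_normalize(exps, coefs))
            )
    return BasisSet(name=basis_name, functions=tuple(functions), nuclei=tuple(nuclei))
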