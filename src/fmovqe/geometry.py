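"""Hydrogen-cluster geometries and fragment schemes.

The systems treated by this package are clusters of hydrogen molecules and
ions (total charge -1, 0 or +1).  A :class:`ClusterGeometry` holds the atoms
and the total charge; a :class:`FragmentScheme` partitions the atoms into
closed-shell fragments (H2, H-, H3+) for the two-body fragment molecular
orbital (FMO2) expansion.

Coordinates are stored in Angstrom everywhere outside the integral code;
the integral layer converts to Bohr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ANGSTROM_TO_BOHR = 1.88972612463

__all__ = [
    "ANGSTROM_TO_BOHR",
    "ClusterGeometry",
    "FragmentScheme",
    "read_xyz",
    "write_xyz",
    "read_fragment_scheme",
    "write_fragment_scheme",
    "auto_fragment_pairs",
]


class GeometryError(ValueError):
    """Invalid geometry or fragment scheme."""


@dataclass(frozen=True)
class ClusterGeometry:
    """All-hydrogen cluster: element symbols, coordinates (A), total charge.

    The electron count is ``n_atoms - total_charge``; it must be even and
    positive (closed shell, multiplicity 1).
    """

    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    total_charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) == 0:
            raise GeometryError("empty geometry")
        if coords.shape != (len(self.elements), 3):
            raise GeometryError(
                f"coords shape {coords.shape} does not match {len(self.elements)} atoms"
            )
        bad = sorted({e for e in self.elements if e != "H"})
        if bad:
            raise GeometryError(f"only hydrogen is supported, got {bad}")
        if self.multiplicity != 1:
            raise GeometryError("only closed-shell (multiplicity 1) systems are supported")
        if self.n_electrons <= 0 or self.n_electrons % 2 != 0:
            raise GeometryError(
                f"electron count {self.n_electrons} must be even and positive "
                f"({self.n_atoms} H atoms, charge {self.total_charge:+d})"
            )
        if self.n_atoms > 1:
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 0.1:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise GeometryError(
                    f"atoms {i} and {j} are {d.min():.4f} A apart (< 0.1 A)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_electrons(self) -> int:
        return self.n_atoms - self.total_charge

    def distance_matrix(self) -> np.ndarray:
        d = np.linalg.norm(self.coords[:, None, :] - self.coords[None, :, :], axis=-1)
        return d


def _subset(geom: ClusterGeometry, idx: list[int], charge: int = 0) -> ClusterGeometry:
    return ClusterGeometry(
        elements=tuple(geom.elements[i] for i in idx),
        coords=geom.coords[idx].copy(),
        total_charge=charge,
    )


def fragment_geometry(geom: ClusterGeometry, atoms, charge: int) -> ClusterGeometry:
    """Geometry of a fragment (atom subset with its fragment charge)."""
    return _subset(geom, list(atoms), charge)


@dataclass(frozen=True)
class FragmentScheme:
    """Ordered partition of the atoms into charged closed-shell fragments."""

    fragments: tuple[tuple[tuple[int, ...], int], ...]  # ((atom indices), charge)

    def __post_init__(self):
        frags = tuple(
            (tuple(sorted(int(a) for a in atoms)), int(charge))
            for atoms, charge in self.fragments
        )
        object.__setattr__(self, "fragments", frags)
        seen: set[int] = set()
        for atoms, charge in frags:
            if not atoms:
                raise GeometryError("empty fragment")
            if seen & set(atoms):
                raise GeometryError("fragments overlap")
            seen |= set(atoms)
            n_el = len(atoms) - charge
            if n_el <= 0 or n_el % 2 != 0:
                raise GeometryError(
                    f"fragment {atoms} with charge {charge:+d} has {n_el} electrons "
                    "(must be even and positive)"
                )

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def atom_indices(self) -> set[int]:
        return {a for atoms, _ in self.fragments for a in atoms}

    @property
    def total_charge(self) -> int:
        return sum(charge for _, charge in self.fragments)

    def validate_against(self, geom: ClusterGeometry) -> None:
        if self.atom_indices != set(range(geom.n_atoms)):
            missing = set(range(geom.n_atoms)) - self.atom_indices
            extra = self.atom_indices - set(range(geom.n_atoms))
            raise GeometryError(
                f"scheme does not partition the atoms (missing {sorted(missing)}, "
                f"unknown {sorted(extra)})"
            )
        if self.total_charge != geom.total_charge:
            raise GeometryError(
                f"fragment charges sum to {self.total_charge:+d}, "
                f"system charge is {geom.total_charge:+d}"
            )

    def electrons(self, i: int) -> int:
        atoms, charge = self.fragments[i]
        return len(atoms) - charge


# ---------------------------------------------------------------------------
# XYZ I/O (standard 2-header-line dialect; charge in the comment line)
# ---------------------------------------------------------------------------

def read_xyz(path) -> ClusterGeometry:
    """Read a standard XYZ file; total charge parsed from ``charge=<int>``
    in the comment line (defaults to 0)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise GeometryError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise GeometryError(f"{path}: malformed atom-count line {lines[0]!r}") from exc
    comment = lines[1] if len(lines) > 1 else ""
    charge = 0
    for tok in comment.replace(",", " ").split():
        if tok.lower().startswith("charge="):
            charge = int(tok.split("=", 1)[1])
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < n:
        raise GeometryError(f"{path}: expected {n} atom lines, found {len(body)}")
    elements, coords = [], []
    for ln in body[:n]:
        parts = ln.split()
        if len(parts) < 4:
            raise GeometryError(f"{path}: malformed atom line {ln!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return ClusterGeometry(tuple(elements), np.array(coords), total_charge=charge)


def write_xyz(geom: ClusterGeometry, path, comment: str = "") -> None:
    """Write an XYZ file; round-trips through :func:`read_xyz` to 1e-6 A."""
    tag = f"charge={geom.total_charge}"
    comment = f"{comment} {tag}".strip() if comment else tag
    with open(path, "w") as fh:
        fh.write(f"{geom.n_atoms}\n{comment}\n")
        for el, xyz in zip(geom.elements, geom.coords):
            fh.write(f"{el} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")


# ---------------------------------------------------------------------------
# Fragment-scheme text format: "i j ... ; charge" per line, 0-based indices
# ---------------------------------------------------------------------------

def read_fragment_scheme(path) -> FragmentScheme:
    frags = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            try:
                atoms_part, charge_part = ln.split(";")
                atoms = tuple(int(a) for a in atoms_part.split())
                charge = int(charge_part)
            except ValueError as exc:
                raise GeometryError(f"{path}: malformed scheme line {ln!r}") from exc
            frags.append((atoms, charge))
    return FragmentScheme(tuple(frags))


def write_fragment_scheme(scheme: FragmentScheme, path) -> None:
    with open(path, "w") as fh:
        for atoms, charge in scheme.fragments:
            fh.write(" ".join(str(a) for a in atoms) + f" ; {charge}\n")


# ---------------------------------------------------------------------------
# Automatic fragmentation: one fragment per H2 molecule / ion
# ---------------------------------------------------------------------------

def auto_fragment_pairs(geom: ClusterGeometry) -> FragmentScheme:
    """Partition a cluster into H2 fragments by greedy nearest-neighbour
    matching.

    For an odd atom count the leftover atom becomes an H- fragment carrying
    the charge when the system is anionic; for a cationic system it is
    merged with its nearest H2 into an H3+ fragment (the bare leftover H+
    would have no electrons).  Neutral odd-atom clusters cannot be
    partitioned into closed shells and are rejected.
    """
    if geom.total_charge not in (-1, 0, 1):
        raise GeometryError("auto fragmentation handles total charge -1, 0, +1 only")
    n = geom.n_atoms
    if n % 2 == 0 and geom.total_charge != 0:
        raise GeometryError(
            "even atom count with nonzero charge gives an open-shell system"
        )
    if n % 2 == 1 and geom.total_charge == 0:
        raise GeometryError(
            "odd atom count with charge 0 cannot form closed-shell fragments"
        )
    d = geom.distance_matrix()
    # Greedy matching: repeatedly pair the globally closest unmatched atoms.
    # Ties are broken by (i, j) index order for permutation-stable output.
    pairs_sorted = sorted(
        ((d[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    matched: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in pairs_sorted:
        if i in matched or j in matched:
            continue
        pairs.append((i, j))
        matched |= {i, j}
        if len(matched) >= n - 1:
            break
    leftover = [i for i in range(n) if i not in matched]
    frags: list[tuple[tuple[int, ...], int]] = [(p, 0) for p in pairs]
    if leftover:
        (lone,) = leftover
        if geom.total_charge == -1:
            frags.append(((lone,), -1))
        else:  # +1: fold the proton-bearing atom into its nearest pair -> H3+
            nearest_pair = min(
                range(len(pairs)), key=lambda k: min(d[lone, pairs[k][0]], d[lone, pairs[k][1]])
            )
            i, j = pairs[nearest_pair]
            frags[nearest_pair] = (tuple(sorted((i, j, lone))), +1)
    # order fragments by their smallest atom index so output is canonical
    frags.sort(key=lambda f: f[0][0])
    scheme = FragmentScheme(tuple(frags))
    scheme.validate_against(geom)
    return scheme
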