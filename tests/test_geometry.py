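"""Geometry I/O, validation, automatic fragmentation and the lattice generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fmovqe.geometry import (ClusterGeometry, FragmentScheme, GeometryError,
                             read_xyz, write_xyz, read_fragment_scheme,
                             write_fragment_scheme, auto_fragment_pairs)
from fmovqe.clusters import ClusterGenSpec, generate_cluster


def triangle(side=0.9, charge=+1):
    r = side / np.sqrt(3.0)
    ang = np.deg2rad([90.0, 210.0, 330.0])
    coords = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(3)], axis=1)
    return ClusterGeometry(("H",) * 3, coords, total_charge=charge)


class TestClusterGeometry:
    def test_electron_count(self):
        g = triangle(charge=+1)
        assert g.n_electrons == 2

    @pytest.mark.parametrize("elements,charge,msg", [
        (("H", "He"), 0, "hydrogen"),
        (("H", "H", "H"), 0, "even"),      # 3 electrons, open shell
        (("H",), +1, "even"),              # 0 electrons
    ])
    def test_invalid_systems_rejected(self, elements, charge, msg):
        coords = np.arange(3 * len(elements), dtype=float).reshape(-1, 3)
        with pytest.raises(GeometryError, match=msg):
            ClusterGeometry(elements, coords, total_charge=charge)

    def test_near_coincident_atoms_rejected(self):
        with pytest.raises(GeometryError, match="0.1 A"):
            ClusterGeometry(("H", "H"), np.array([[0, 0, 0], [0, 0, 0.05]]), 0)


class TestXYZ:
    def test_round_trip(self, tmp_path, h4_geom):
        path = tmp_path / "c.xyz"
        write_xyz(h4_geom, path)
        back = read_xyz(path)
        assert back.elements == h4_geom.elements
        assert back.total_charge == h4_geom.total_charge
        np.testing.assert_allclose(back.coords, h4_geom.coords, atol=1e-6)

    def test_charge_round_trip(self, tmp_path):
        g = ClusterGeometry(("H",), np.zeros((1, 3)), total_charge=-1)
        write_xyz(g, tmp_path / "a.xyz")
        assert read_xyz(tmp_path / "a.xyz").total_charge == -1

    def test_minimal_file(self, tmp_path):
        (tmp_path / "h2.xyz").write_text("2\n\nH 0 0 0\nH 0 0 0.7414\n")
        g = read_xyz(tmp_path / "h2.xyz")
        assert g.n_electrons == 2 and g.total_charge == 0

    def test_comment_charge_parsed(self, tmp_path):
        (tmp_path / "h3.xyz").write_text(
            "3\ncharge=+1 triangle\nH 0 0.52 0\nH -0.45 -0.26 0\nH 0.45 -0.26 0\n")
        assert read_xyz(tmp_path / "h3.xyz").n_electrons == 2

    def test_non_hydrogen_rejected(self, tmp_path):
        (tmp_path / "he.xyz").write_text("1\n\nHe 0 0 0\n")
        with pytest.raises(GeometryError):
            read_xyz(tmp_path / "he.xyz")

    def test_malformed_count_line(self, tmp_path):
        (tmp_path / "bad.xyz").write_text("xx\n\nH 0 0 0\n")
        with pytest.raises(GeometryError, match="count"):
            read_xyz(tmp_path / "bad.xyz")


class TestFragmentScheme:
    def test_partition_enforced(self, h4_geom):
        scheme = FragmentScheme((((0, 1), 0),))
        with pytest.raises(GeometryError, match="partition"):
            scheme.validate_against(h4_geom)

    def test_overlap_rejected(self):
        with pytest.raises(GeometryError, match="overlap"):
            FragmentScheme((((0, 1), 0), ((1, 2), 0)))

    def test_open_shell_fragment_rejected(self):
        with pytest.raises(GeometryError, match="even"):
            FragmentScheme((((0,), 0),))

    def test_file_round_trip(self, tmp_path):
        scheme = FragmentScheme((((0, 1), 0), ((2, 3, 4), +1)))
        write_fragment_scheme(scheme, tmp_path / "s.txt")
        assert read_fragment_scheme(tmp_path / "s.txt") == scheme


class TestAutoFragment:
    def test_two_separated_molecules(self):
        geom = generate_cluster(ClusterGenSpec(2, spacing=30.0))
        scheme = auto_fragment_pairs(geom)
        assert scheme.fragments == (((0, 1), 0), ((2, 3), 0))

    def test_anion_leftover_is_hydride(self):
        geom = generate_cluster(ClusterGenSpec(2, spacing=3.0, extra_species="anion"))
        scheme = auto_fragment_pairs(geom)
        sizes = sorted(len(a) for a, _ in scheme.fragments)
        assert sizes == [1, 2, 2]
        lone = next(f for f in scheme.fragments if len(f[0]) == 1)
        assert lone[1] == -1

    def test_cation_leftover_forms_h3_core(self):
        geom = generate_cluster(ClusterGenSpec(2, spacing=3.0, extra_species="cation"))
        scheme = auto_fragment_pairs(geom)
        sizes = sorted(len(a) for a, _ in scheme.fragments)
        assert sizes == [2, 3]
        core = next(f for f in scheme.fragments if len(f[0]) == 3)
        assert core[1] == +1

    def test_neutral_odd_count_rejected(self):
        # 3 collinear atoms with charge 0 is open shell: rejected as soon as
        # the geometry is built (odd electron count)
        with pytest.raises(GeometryError, match="even"):
            ClusterGeometry(("H",) * 3,
                            np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]]), 0)
        # the same atoms as an anion fragment fine: H2 + H-
        good = ClusterGeometry(("H",) * 3,
                               np.array([[0, 0, 0], [0, 0, 0.75], [0, 0, 3.0]]),
                               total_charge=-1)
        assert auto_fragment_pairs(good).n_fragments == 2

    @given(st.randoms(use_true_random=False))
    def test_permutation_invariance(self, rnd):
        geom = generate_cluster(ClusterGenSpec(3, spacing=3.0, jitter=0.2, seed=11))
        perm = list(range(geom.n_atoms))
        rnd.shuffle(perm)
        permuted = ClusterGeometry(geom.elements, geom.coords[perm], 0)
        base = {frozenset(a) for a, _ in auto_fragment_pairs(geom).fragments}
        mapped = {frozenset(perm[i] for i in a)
                  for a, _ in auto_fragment_pairs(permuted).fragments}
        assert base == mapped


class TestGenerator:
    def test_zero_jitter_is_exact_lattice(self):
        geom = generate_cluster(ClusterGenSpec(3, spacing=30.0))
        np.testing.assert_allclose(geom.coords[0], [0, 0, -0.3707], atol=1e-12)
        np.testing.assert_allclose(geom.coords[1], [0, 0, +0.3707], atol=1e-12)
        centers = 0.5 * (geom.coords[0::2] + geom.coords[1::2])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() == 30.0  # nearest-neighbour centers sit one pitch apart

    def test_seed_determinism(self):
        spec = ClusterGenSpec(4, spacing=3.0, jitter=0.3, seed=42)
        np.testing.assert_array_equal(generate_cluster(spec).coords,
                                      generate_cluster(spec).coords)

    def test_h24_analog(self):
        geom = generate_cluster(ClusterGenSpec(12, spacing=3.0))
        assert geom.n_atoms == 24 and geom.n_electrons == 24

    @pytest.mark.parametrize("kwargs", [
        dict(n_molecules=2, spacing=0.5),           # pitch below bond length
        dict(n_molecules=2, spacing=3.0, jitter=1.0),  # jitter >= spacing/4
        dict(n_molecules=0),
    ])
    def test_invalid_spec(self, kwargs):
        with pytest.raises(ValueError):
            ClusterGenSpec(**kwargs)
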