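import numpy as np
import pytest

import biotite.structure as struc

from pairgeom.errors import (
    DegenerateGeometryError,
    InsufficientStructureError,
)
from pairgeom.geometry import (
    BackboneStructure,
    BinSpec,
    GeometryMaps,
    bin_centers,
    discretize,
    featurize,
    pair_geometries,
    read_backbone,
    virtual_cbeta,
)
from pairgeom.synthetic import (
    SyntheticBackboneSpec,
    synthetic_backbone,
    write_backbone_pdb,
)

from conftest import random_chain


def _rotation_matrix(seed=0):
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


IDEAL_N = np.array([0.0, 0.0, 0.0])
IDEAL_CA = np.array([1.458, 0.0, 0.0])
IDEAL_C = IDEAL_CA + 1.525 * np.array([np.cos(np.radians(69.0)),
                                       np.sin(np.radians(69.0)), 0.0])


class TestVirtualCbeta:
    def test_bond_length_on_ideal_backbone(self):
        cb = virtual_cbeta(IDEAL_N, IDEAL_CA, IDEAL_C)
        assert np.linalg.norm(cb - IDEAL_CA) == pytest.approx(1.53, abs=0.03)

    def test_tetrahedral_angles(self):
        """CB sits near the ideal ~110-degree angles to N and C."""
        cb = virtual_cbeta(IDEAL_N, IDEAL_CA, IDEAL_C)
        for other in (IDEAL_N, IDEAL_C):
            u = other - IDEAL_CA
            v = cb - IDEAL_CA
            ang = np.degrees(np.arccos(u @ v / np.linalg.norm(u) / np.linalg.norm(v)))
            assert ang == pytest.approx(110, abs=5)

    def test_translation_equivariance(self):
        t = np.array([5.0, 5.0, 5.0])
        a = virtual_cbeta(IDEAL_N + t, IDEAL_CA + t, IDEAL_C + t)
        b = virtual_cbeta(IDEAL_N, IDEAL_CA, IDEAL_C) + t
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_rotation_equivariance(self):
        R = _rotation_matrix(3)
        a = virtual_cbeta(IDEAL_N @ R.T, IDEAL_CA @ R.T, IDEAL_C @ R.T)
        b = virtual_cbeta(IDEAL_N, IDEAL_CA, IDEAL_C) @ R.T
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_collinear_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            virtual_cbeta(np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]))


def _two_residue_structure(cb0, cb1):
    n = np.array([[0.0, -1.5, 0.0], [10.0, -1.5, 0.0]])
    ca = np.array([[0.0, 0.0, 1.5], [10.0, 0.0, 1.5]])
    c = np.array([[1.5, 0.0, 0.0], [11.5, 0.0, 0.0]])
    return BackboneStructure(n=n, ca=ca, c=c,
                             cb=np.array([cb0, cb1], dtype=float),
                             residues=("ALA", "ALA"))


class TestPairGeometries:
    def test_three_four_five_distance(self):
        s = _two_residue_structure([0.0, 0.0, 0.0], [3.0, 4.0, 0.0])
        g = pair_geometries(s)
        assert g.d[0, 1] == pytest.approx(5.0)
        assert g.d[1, 0] == pytest.approx(5.0)
        assert g.d[0, 0] == 0.0

    def test_planar_trans_dihedral_is_180(self):
        # CA-CB-CB-CA all in one plane, CA atoms on opposite sides
        s = _two_residue_structure([0.0, 0.0, 0.0], [3.0, 0.0, 0.0])
        s = BackboneStructure(
            n=s.n, c=s.c, residues=s.residues,
            ca=np.array([[-1.0, 1.0, 0.0], [4.0, -1.0, 0.0]]),
            cb=s.cb,
        )
        g = pair_geometries(s)
        assert abs(g.omega[0, 1]) == pytest.approx(180.0, abs=1e-9)

    def test_symmetry_structure(self):
        g = pair_geometries(random_chain(6, seed=11))
        np.testing.assert_allclose(g.d, g.d.T, atol=1e-9)
        np.testing.assert_allclose(g.omega, g.omega.T, atol=1e-9)
        assert np.abs(g.theta - g.theta.T).max() > 1e-3  # directional

    def test_diagonal_invalid(self):
        g = pair_geometries(random_chain(5, seed=2))
        assert not g.valid.diagonal().any()

    @pytest.mark.parametrize("seed", range(10))
    def test_against_independent_biotite_oracle(self, seed):
        """d/omega/theta/phi agree with biotite's dihedral/angle routines."""
        s = random_chain(8, seed=100 + seed)
        g = pair_geometries(s)
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                assert g.d[i, j] == pytest.approx(
                    np.linalg.norm(s.cb[i] - s.cb[j]), abs=1e-6)
                om = np.degrees(struc.dihedral(s.ca[i], s.cb[i], s.cb[j], s.ca[j]))
                th = np.degrees(struc.dihedral(s.n[i], s.ca[i], s.cb[i], s.cb[j]))
                ph = np.degrees(struc.angle(s.ca[i], s.cb[i], s.cb[j]))
                # biotite computes in float32, hence the looser tolerance here
                assert g.omega[i, j] == pytest.approx(om, abs=5e-3)
                assert g.theta[i, j] == pytest.approx(th, abs=5e-3)
                assert g.phi[i, j] == pytest.approx(ph, abs=5e-3)


def _linear_scan_label(value, edges, top_closed=True):
    """Independent binning oracle: scan half-open [lo, hi) intervals."""
    for k in range(len(edges) - 1):
        if edges[k] <= value < edges[k + 1]:
            return k + 1
    if top_closed and value == edges[-1]:
        return len(edges) - 1
    return None


class TestDiscretize:
    def _maps_with_d(self, d01, omega=10.0, theta=20.0, phi=30.0):
        d = np.array([[0.0, d01], [d01, 0.0]])
        om = np.full((2, 2), omega)
        th = np.full((2, 2), theta)
        ph = np.full((2, 2), phi)
        valid = ~np.eye(2, dtype=bool)
        return GeometryMaps(d=d, omega=om, theta=th, phi=ph, valid=valid)

    def test_distance_bin_example(self):
        labels = discretize(self._maps_with_d(3.7))
        assert labels.dist[0, 1] == 4  # [3.5, 4.0) is the 4th contact bin

    def test_no_contact_masks_all_objectives(self):
        labels = discretize(self._maps_with_d(25.0))
        for arr in labels.as_dict().values():
            assert arr[0, 1] == 0

    def test_omega_180_wraps_into_top_bin(self):
        labels = discretize(self._maps_with_d(5.0, omega=180.0))
        assert labels.omega[0, 1] == 24

    def test_clash_clamps_into_first_bin(self, caplog):
        with caplog.at_level("WARNING"):
            labels = discretize(self._maps_with_d(1.2))
        assert labels.dist[0, 1] == 1
        assert "clamp" in caplog.text

    def test_diagonal_label_zero(self):
        labels = featurize(random_chain(6, seed=5))
        for arr in labels.as_dict().values():
            assert (np.diagonal(arr) == 0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_binning_matches_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        bins = BinSpec.default()
        spec = {
            "dist": (rng.uniform(2.0, 25.0, 300), bins.d_edges),
            "omega": (rng.uniform(-180.0, 180.0, 300), bins.dihedral_edges),
            "theta": (rng.uniform(-180.0, 180.0, 300), bins.dihedral_edges),
            "phi": (rng.uniform(0.0, 180.0, 300), bins.phi_edges),
        }
        for name, (values, edges) in spec.items():
            for v in np.concatenate([values, edges]):  # include exact boundaries
                if name == "dist":
                    if v >= 20.0:
                        continue  # no-contact handled by the mask, not the bins
                    v = max(v, 2.0)
                expected = _linear_scan_label(v, edges)
                g = self._maps_with_d(
                    5.0 if name != "dist" else v,
                    **({name: v} if name != "dist" else {}),
                )
                got = discretize(g).as_dict()[name][0, 1]
                if v == edges[0] and name != "phi" and name != "dist":
                    # dihedral range is (-180, 180]; -180 never occurs
                    continue
                assert got == (expected if expected is not None else 1), (name, v)

    def test_label_symmetry_and_ranges(self):
        labels = featurize(random_chain(12, seed=9))
        assert (labels.dist == labels.dist.T).all()
        assert (labels.omega == labels.omega.T).all()
        for name, top in (("theta", 25), ("phi", 13), ("omega", 25), ("dist", 37)):
            arr = labels.as_dict()[name]
            assert arr.min() >= 0 and arr.max() <= top - 1

    def test_rigid_body_invariance(self):
        s = random_chain(10, seed=21)
        R = _rotation_matrix(7)
        t = np.array([3.0, -8.0, 11.0])
        moved = BackboneStructure(
            n=s.n @ R.T + t, ca=s.ca @ R.T + t, c=s.c @ R.T + t,
            cb=s.cb @ R.T + t, residues=s.residues,
        )
        a, b = featurize(s), featurize(moved)
        for name in a.as_dict():
            np.testing.assert_array_equal(a.as_dict()[name], b.as_dict()[name])

    def test_bin_centers_invert_within_half_width(self):
        centers = bin_centers()
        bins = BinSpec.default()
        rng = np.random.default_rng(0)
        for v in rng.uniform(2.0, 19.99, 50):
            g = self._maps_with_d(v)
            lab = discretize(g).dist[0, 1]
            assert abs(centers["dist"][lab] - v) <= 0.25 + 1e-12


class TestReadBackbone:
    def test_round_trip_with_fixture(self, tmp_path, hth40):
        path = tmp_path / "hth.pdb"
        write_backbone_pdb(hth40, path)
        s = read_backbone(path)
        assert s.length == 40
        np.testing.assert_allclose(s.ca, hth40.ca, atol=1e-3)
        np.testing.assert_allclose(s.n, hth40.n, atol=1e-3)

    def test_glycine_gets_virtual_cb(self, tmp_path):
        s0 = synthetic_backbone(SyntheticBackboneSpec(L=10, seed=4))
        assert "GLY" in s0.residues  # seed chosen to include glycine
        path = tmp_path / "gly.pdb"
        write_backbone_pdb(s0, path)
        s = read_backbone(path)
        g = np.array(s.residues) == "GLY"
        # virtual CB is re-derived from coordinates rounded to 1e-3 by the
        # PDB writer, so its error is a few times the format precision
        np.testing.assert_allclose(s.cb[g], s0.cb[g], atol=3e-3)

    def test_residue_missing_ca_dropped(self, tmp_path, caplog):
        s0 = synthetic_backbone(SyntheticBackboneSpec(L=10, seed=0))
        path = tmp_path / "gap.pdb"
        write_backbone_pdb(s0, path)
        lines = [l for l in path.read_text().splitlines()
                 if not (l.startswith("ATOM")
                         and l[12:16].strip() == "CA"
                         and l[22:26].strip() == "5")]
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            s = read_backbone(path)
        assert s.length == 9
        assert "missing a backbone atom" in caplog.text

    def test_insufficient_structure(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(InsufficientStructureError):
            read_backbone(path)
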