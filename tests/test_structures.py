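import math

import numpy as np
import pytest

from lnbench.structures import (
    CutoffScheme,
    StructureError,
    detect_polyhedra,
    detect_polyhedron,
    pair_structures,
    read_structure_json,
    read_xyz,
    write_structure_json,
    write_xyz,
)
from conftest import make_structure


class TestXYZ:
    def test_single_lanthanide_detected_as_center(self, tmp_path):
        p = tmp_path / "a.xyz"
        p.write_text("2\ncomment\nDy 0 0 0\nO 2.3 0 0\n")
        s = read_xyz(p)
        assert s.center_indices == (0,)
        assert [a.element for a in s.atoms] == ["Dy", "O"]

    def test_roundtrip_preserves_elements_and_coordinates(self, tmp_path, rng):
        entries = [("Dy", rng.normal(size=3))] + [
            (el, rng.normal(size=3) * 3) for el in ("O", "N", "C", "S", "Cl")]
        s = make_structure(entries, "rt")
        path = tmp_path / "rt.xyz"
        write_xyz(s, path)
        s2 = read_xyz(path)
        assert [a.element for a in s2.atoms] == [a.element for a in s.atoms]
        np.testing.assert_allclose(s2.coordinates, s.coordinates, atol=5e-7)

    def test_two_lanthanides_both_flagged_as_centers(self, tmp_path):
        p = tmp_path / "d.xyz"
        p.write_text("3\nc\nDy 0 0 0\nHo 4.0 0 0\nO 2.3 0 0\n")
        s = read_xyz(p)
        assert s.center_indices == (0, 1)

    @pytest.mark.parametrize("body", [
        "x\nc\nDy 0 0 0\n",                 # malformed count
        "2\nc\nDy 0 0 0\nO 2.3 0\n",        # short record
        "2\nc\nDy 0 0 0\nO a b c\n",        # non-numeric
    ])
    def test_malformed_files_raise_parse_errors(self, tmp_path, body):
        p = tmp_path / "bad.xyz"
        p.write_text(body)
        with pytest.raises(StructureError):
            read_xyz(p)

    def test_no_lanthanide_raises_unless_center_supplied(self, tmp_path):
        p = tmp_path / "n.xyz"
        p.write_text("2\nc\nO 0 0 0\nN 1.5 0 0\n")
        with pytest.raises(StructureError, match="no lanthanide"):
            read_xyz(p)

    def test_json_dialect_roundtrip_with_explicit_donors(self, tmp_path, square_planar):
        path = tmp_path / "s.json"
        donors = [square_planar.atoms[i].label for i in (1, 2)]
        write_structure_json(square_planar, path, donors=donors)
        s2, donor_labels = read_structure_json(path)
        assert donor_labels == donors
        np.testing.assert_allclose(s2.coordinates, square_planar.coordinates)
        poly = detect_polyhedron(s2, donor_labels=donor_labels)
        assert poly.donor_count == 2


class TestPolyhedron:
    def test_far_atom_excluded_by_default_cutoff(self):
        s = make_structure([("Dy", (0, 0, 0)), ("O", (2.3, 0, 0)), ("C", (8.0, 0, 0))])
        poly = detect_polyhedron(s)
        assert [s.atoms[i].element for i in poly.donor_indices] == ["O"]

    def test_hydrogens_are_never_donors(self):
        s = make_structure([("Dy", (0, 0, 0)), ("O", (2.3, 0, 0)), ("H", (1.0, 0, 0))])
        poly = detect_polyhedron(s)
        assert [s.atoms[i].element for i in poly.donor_indices] == ["O"]

    def test_square_planar_bond_and_angle_inventory(self, square_planar):
        poly = detect_polyhedron(square_planar)
        assert len(poly.bonds) == 4
        assert all(cls == "Ln-O" and abs(d - 2.4) < 1e-12 for cls, d in poly.bonds)
        angles = sorted(round(a, 7) for _, _, a in poly.angles)
        assert angles == [90.0, 90.0, 90.0, 90.0, 180.0, 180.0]

    def test_partner_lanthanide_recorded_as_ln_ln_bond(self):
        s = make_structure([("Dy", (0, 0, 0)), ("Dy", (4.0, 0, 0)),
                            ("O", (-2.3, 0, 0)), ("O", (6.3, 0, 0))])
        polys = detect_polyhedra(s)
        assert len(polys) == 2
        for poly in polys:
            classes = sorted(cls for cls, _ in poly.bonds)
            assert classes == ["Ln-Ln", "Ln-O"]
            (lnln_dist,) = [d for cls, d in poly.bonds if cls == "Ln-Ln"]
            assert abs(lnln_dist - 4.0) < 1e-12

    def test_distant_partner_lanthanide_not_bonded(self):
        s = make_structure([("Dy", (0, 0, 0)), ("Dy", (8.0, 0, 0)),
                            ("O", (-2.3, 0, 0)), ("O", (10.3, 0, 0))])
        poly = detect_polyhedron(s, center_index=0)
        assert [cls for cls, _ in poly.bonds] == ["Ln-O"]

    def test_empty_donor_set_raises(self):
        s = make_structure([("Dy", (0, 0, 0)), ("O", (9.0, 0, 0))])
        with pytest.raises(StructureError, match="empty donor set"):
            detect_polyhedron(s)

    def test_oversized_donor_set_warns(self, rng):
        entries = [("Dy", (0, 0, 0))]
        for i in range(20):
            v = rng.normal(size=3)
            entries.append(("O", 2.4 * v / np.linalg.norm(v)))
        s = make_structure(entries)
        with pytest.warns(UserWarning, match="suspicious cutoff"):
            detect_polyhedron(s)

    def test_angle_count_is_pairs_of_angle_eligible_donors(self):
        # P is a donor but not an angle endpoint
        s = make_structure([("Dy", (0, 0, 0)), ("O", (2.3, 0, 0)),
                            ("N", (0, 2.4, 0)), ("P", (0, 0, 2.6))])
        poly = detect_polyhedron(s)
        assert poly.donor_count == 3
        assert len(poly.angles) == 1  # only the O-Dy-N pair

    def test_invariant_under_rigid_rotation_translation(self, rng):
        entries = [("Dy", (0, 0, 0))]
        for el in ("O", "N", "C", "S", "Cl", "Br"):
            v = rng.normal(size=3)
            entries.append((el, (2.2 + 0.6 * rng.random()) * v / np.linalg.norm(v)))
        s = make_structure(entries)
        poly = detect_polyhedron(s)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = s.with_coordinates(s.coordinates @ q.T + np.array([5.0, -3.0, 2.0]))
        poly2 = detect_polyhedron(moved)
        assert poly2.donor_indices == poly.donor_indices
        np.testing.assert_allclose([d for _, d in poly2.bonds],
                                   [d for _, d in poly.bonds], atol=1e-9)
        np.testing.assert_allclose([a for _, _, a in poly2.angles],
                                   [a for _, _, a in poly.angles], atol=1e-7)

    def test_cutoff_override_wins(self):
        s = make_structure([("Dy", (0, 0, 0)), ("O", (2.3, 0, 0))])
        with pytest.raises(StructureError):
            detect_polyhedron(s, CutoffScheme(overrides={("Dy", "O"): 2.0}))


class TestPairing:
    def test_identical_structures_identity_correspondence(self, square_planar):
        pair = pair_structures(square_planar, square_planar)
        assert pair.correspondence == {i: i for i in range(5)}

    def test_permuted_atoms_matched_by_label(self, square_planar):
        order = [0, 3, 1, 4, 2]
        permuted = make_structure([], "perm")
        permuted.atoms = [square_planar.atoms[i] for i in order]
        permuted.center_indices = (0,)
        pair = pair_structures(square_planar, permuted)
        assert pair.correspondence == {0: 0, 3: 1, 1: 2, 4: 3, 2: 4}
        for i, j in pair.correspondence.items():
            assert square_planar.atoms[i].label == permuted.atoms[j].label

    def test_missing_donor_label_raises(self, square_planar):
        short = make_structure([("Dy", (0, 0, 0)), ("O", (2.4, 0, 0))], "short")
        with pytest.raises(StructureError):
            pair_structures(square_planar, short)

    def test_element_mismatch_raises_with_labels(self):
        a = make_structure([("Dy", (0, 0, 0)), ("O", (2.3, 0, 0))])
        b = make_structure([("Dy", (0, 0, 0)), ("N", (2.3, 0, 0))])
        b.atoms = [b.atoms[0], b.atoms[1]]
        # same positions/labels? labels differ (N2 vs O2) and counts equal ->
        # positional fallback, which must flag the element mismatch
        with pytest.raises(StructureError, match="element mismatch"):
            pair_structures(a, b)
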