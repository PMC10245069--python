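"""Structure IO, contact mapping and rigid-body geometry."""

import warnings

import numpy as np
import pytest

from mlascan.structure import (
    StructureModel,
    conformation_metrics,
    footprint,
    footprint_by_chain,
    interchain_contacts,
    load_structure,
    overlap_with_dms,
    save_pdb,
    superpose,
)
from mlascan.synthetic import generate_toy_complex

from conftest import brute_force_contacts, random_two_chain_model


def _two_atom_model(distance):
    return StructureModel(
        chain_ids=np.array(["A", "B"]),
        res_ids=np.array([1, 1], dtype=np.int64),
        res_names=np.array(["ALA", "ALA"]),
        atom_names=np.array(["CA", "CA"]),
        elements=np.array(["C", "C"]),
        coords=np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
    )


def _rotation(axis, degrees):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    theta = np.radians(degrees)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


class TestIO:
    def test_pdb_round_trip_preserves_atoms(self, tmp_path):
        model = generate_toy_complex(6, 7, {(1, 1), (3, 5)}, seed=2)
        path = tmp_path / "toy.pdb"
        save_pdb(model, path)
        loaded = load_structure(path)
        assert loaded.n_atoms == model.n_atoms
        assert loaded.chains == model.chains
        np.testing.assert_allclose(
            np.sort(loaded.coords, axis=0), np.sort(model.coords, axis=0), atol=1e-3
        )

    def test_altlocs_resolve_to_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30 10.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70 10.00           C\n"
            "END\n"
        )
        path = tmp_path / "altloc.pdb"
        path.write_text(pdb)
        model = load_structure(path)
        assert model.n_atoms == 1
        assert model.coords[0, 0] == pytest.approx(5.0)

    def test_hydrogens_dropped(self, tmp_path):
        pdb = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "ATOM      2  H   ALA A   1       1.000   0.000   0.000  1.00 10.00           H\n"
            "END\n"
        )
        path = tmp_path / "h.pdb"
        path.write_text(pdb)
        assert load_structure(path).n_atoms == 1

    def test_numbering_offset_applied_to_footprints(self):
        model = generate_toy_complex(5, 5, {(2, 3)}, seed=1)
        model.numbering_offset["A"] = 21  # e.g. model omits a signal peptide
        contacts = interchain_contacts(model, {"A"}, {"B"}, 4.0)
        assert footprint(contacts, {"A"}, model) == {23}
        assert footprint(contacts, {"B"}, model) == {3}


class TestContacts:
    def test_strict_cutoff_boundary(self):
        assert len(interchain_contacts(_two_atom_model(3.9), {"A"}, {"B"}, 4.0).pairs) == 1
        assert len(interchain_contacts(_two_atom_model(4.1), {"A"}, {"B"}, 4.0).pairs) == 0
        assert len(interchain_contacts(_two_atom_model(4.0), {"A"}, {"B"}, 4.0).pairs) == 0

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(50):
            model = random_two_chain_model(rng, n_atoms_per_chain=30)
            fast = interchain_contacts(model, {"A"}, {"B"}, 4.0)
            brute = brute_force_contacts(model, {"A"}, {"B"}, 4.0)
            assert set(fast.pairs) == set(brute)
            for key in fast.pairs:
                assert fast.pairs[key] == pytest.approx(brute[key], abs=1e-9)

    def test_symmetry_under_group_swap(self, rng):
        model = random_two_chain_model(rng)
        ab = interchain_contacts(model, {"A"}, {"B"}, 4.0)
        ba = interchain_contacts(model, {"B"}, {"A"}, 4.0)
        assert {(b, a) for a, b in ab.pairs} == set(ba.pairs)

    def test_cutoff_monotonicity(self, rng):
        model = random_two_chain_model(rng)
        sets = [set(interchain_contacts(model, {"A"}, {"B"}, c).pairs) for c in (3.5, 4.0, 4.5)]
        assert sets[0] <= sets[1] <= sets[2]

    def test_overlapping_or_empty_groups_rejected(self, rng):
        model = random_two_chain_model(rng)
        with pytest.raises(ValueError):
            interchain_contacts(model, {"A"}, {"A"}, 4.0)
        with pytest.raises(ValueError):
            interchain_contacts(model, set(), {"A"}, 4.0)


class TestFootprintAndOverlap:
    def _map(self, pairs):
        from mlascan.structure import ContactMap

        return ContactMap(
            cutoff=4.0,
            group_a=frozenset({"A"}),
            group_b=frozenset({"B"}),
            pairs={((("A"), a), (("B"), b)): 3.0 for a, b in pairs},
        )

    def test_footprint_projection(self):
        cmap = self._map([(5, 10), (5, 12), (7, 10)])
        assert footprint(cmap, {"A"}) == {5, 7}
        assert footprint(cmap, {"B"}) == {10, 12}

    def test_empty_map_empty_footprint(self):
        assert footprint(self._map([]), {"A"}) == set()

    def test_random_maps_match_set_projection(self, rng):
        for _ in range(50):
            pairs = {(int(a), int(b)) for a, b in rng.integers(1, 30, size=(10, 2))}
            cmap = self._map(pairs)
            assert footprint(cmap, {"A"}) == {a for a, _ in pairs}
            assert footprint_by_chain(cmap, {"B"})["B"] == {b for _, b in pairs}

    def test_overlap_counts(self):
        rep = overlap_with_dms(set(range(1, 11)), {5, 6, 20})
        assert rep.n_intersection == 2
        assert rep.intersection == {5, 6}
        assert rep.hits_only == {20}
        assert rep.footprint_only == set(range(1, 11)) - {5, 6}

    def test_disjoint_ranges_warn(self):
        with pytest.warns(UserWarning, match="numbering offsets"):
            overlap_with_dms({1, 2, 3}, {100, 101})


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        tr = superpose(pts, pts)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-9)
        assert tr.rotation_angle == pytest.approx(0.0, abs=1e-6)

    def test_constructed_30_degree_rotation(self, rng):
        pts = rng.normal(size=(12, 3)) * 5
        rot = _rotation([1, 2, 3], 30.0)
        moved = pts @ rot.T + np.array([1.0, -2.0, 0.5])
        tr = superpose(pts, moved)
        assert tr.rotation_angle == pytest.approx(30.0, abs=1e-6)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_reflection_case_keeps_proper_rotation(self, rng):
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        tr = superpose(pts, mirrored)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
        assert tr.rmsd > 0

    def test_rmsd_invariant_to_rigid_pretransform(self, rng):
        pts = rng.normal(size=(15, 3)) * 3
        target = rng.normal(size=(15, 3)) * 3
        base = superpose(pts, target).rmsd
        rot = _rotation([0, 1, 1], 77.0)
        pre = pts @ rot.T + np.array([4.0, 5.0, -6.0])
        assert superpose(pre, target).rmsd == pytest.approx(base, abs=1e-9)

    def test_degenerate_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            superpose(line, line + 1.0)


def _ring_carrier_model(carrier_rotation_deg=0.0, carrier_shift=(0.0, 0.0, 0.0), seed=0):
    """Hexameric ring of CA atoms exactly in the xy-plane + a carrier chain.

    The ring is planar so its symmetry axis is exactly z; the carrier point
    cloud is centered then moved to (12, 0, 15), so its centroid is exact.
    """
    rng = np.random.default_rng(seed)
    records = []
    for k in range(6):
        ang = np.radians(60 * k)
        base = np.array([20 * np.cos(ang), 20 * np.sin(ang), 0.0])
        for r in range(4):
            jitter = np.array([rng.normal(0, 2.0), rng.normal(0, 2.0), 0.0])
            records.append((f"D{k+1}", r + 1, base + jitter))
    cloud = rng.normal(0, 3.0, size=(8, 3))
    cloud -= cloud.mean(axis=0)
    carrier_pts = cloud + np.array([12.0, 0.0, 15.0])
    rot = _rotation([0, 0, 1], carrier_rotation_deg)
    shift = np.asarray(carrier_shift, dtype=float)
    records += [("C", i + 1, rot @ p + shift) for i, p in enumerate(carrier_pts)]
    return StructureModel(
        chain_ids=np.array([r[0] for r in records]),
        res_ids=np.array([r[1] for r in records], dtype=np.int64),
        res_names=np.array(["GLY"] * len(records)),
        atom_names=np.array(["CA"] * len(records)),
        elements=np.array(["C"] * len(records)),
        coords=np.array([r[2] for r in records]),
    )


class TestConformationMetrics:
    RING = [f"D{i}" for i in range(1, 7)]

    def test_duplicate_models_give_zero_angles_and_equal_scores(self):
        m = _ring_carrier_model(seed=5)
        rep = conformation_metrics([m, m, m], self.RING, "C")
        assert rep.pairwise_angles == pytest.approx(0.0, abs=1e-6)
        assert len(set(np.round(rep.axis_distances, 9))) == 1

    def test_constructed_carrier_rotation_recovered(self):
        a = _ring_carrier_model(carrier_rotation_deg=0.0, seed=5)
        b = _ring_carrier_model(carrier_rotation_deg=21.0, seed=5)
        rep = conformation_metrics([a, b], self.RING, "C")
        assert rep.max_angle == pytest.approx(21.0, abs=1e-6)

    def test_radial_displacement_changes_score_by_displacement(self):
        a = _ring_carrier_model(seed=5)
        ring_mask = a.chain_ids != "C"
        ring_center = a.coords[ring_mask].mean(axis=0)
        centroid = np.array([12.0, 0.0, 15.0])
        radial = centroid - ring_center
        radial[2] = 0.0  # ring axis is exactly z for the planar ring
        radial /= np.linalg.norm(radial)
        b = _ring_carrier_model(carrier_shift=tuple(6.0 * radial), seed=5)
        rep = conformation_metrics([a, b], self.RING, "C")
        assert rep.axis_distances[1] - rep.axis_distances[0] == pytest.approx(6.0, abs=1e-6)
        assert rep.labels[0] == "inward" and rep.labels[1] == "outward"

    def test_missing_carrier_chain_errors(self):
        m = _ring_carrier_model(seed=5)
        with pytest.raises(ValueError, match="carrier chain"):
            conformation_metrics([m], self.RING, "Z")
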