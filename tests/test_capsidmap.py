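"""Angular projection, MSA conservation and map alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsidhs.capsidmap import (
    CapsidMap,
    ConservationConfig,
    MapPoint,
    align_maps,
    build_capsidmap,
    column_residue_maps,
    conserved_columns,
    predict_hotspots,
    project_point,
)
from capsidhs.interfaces import find_interfaces, interface_residue_union
from capsidhs.pipeline import predict_family
from capsidhs.structures import AlignmentSet, AsymmetricUnit
from capsidhs.symmetry import assemble_capsid


class TestProjectPoint:
    def test_north_pole(self):
        phi, psi = project_point([0, 0, 5])
        assert (phi, psi) == (0.0, 0.0)

    def test_equatorial_diagonal(self):
        phi, psi = project_point([2.0, 2.0, 0.0])
        assert phi == pytest.approx(45.0)
        assert psi == pytest.approx(90.0)

    def test_radius_independence(self):
        p1 = project_point([1.0, 2.0, 3.0])
        p2 = project_point([10.0, 20.0, 30.0])
        assert p1 == pytest.approx(p2)

    def test_center_rejected(self):
        with pytest.raises(ValueError):
            project_point([1.0, 1.0, 1.0], center=[1.0, 1.0, 1.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        angle=st.floats(-720, 720),
        x=st.floats(-10, 10), y=st.floats(-10, 10),
        z=st.floats(-10, 10),
    )
    def test_z_rotation_shifts_phi_exactly(self, angle, x, y, z):
        v = np.array([x, y, z])
        if np.hypot(x, y) < 1e-3:
            return
        c, s = np.cos(np.radians(angle)), np.sin(np.radians(angle))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        phi0, psi0 = project_point(v)
        phi1, psi1 = project_point(R @ v)
        assert psi1 == pytest.approx(psi0, abs=1e-8)
        d = (phi1 - phi0 - angle) % 360.0
        assert min(d, 360 - d) == pytest.approx(0.0, abs=1e-6)


class TestBuildMap:
    def test_one_point_per_interface_residue(self, toy_family, icosa_group):
        _, members, truth = toy_family
        au = members[0][0]
        cmap = build_capsidmap(au, truth.interface_keys)
        assert len(cmap.points) == len(truth.interface_keys)

    def test_map_equivariant_under_group_rotation(self, toy_family, icosa_group):
        """Rotating the AU by a symmetry operator rotates its map points."""
        _, members, truth = toy_family
        au = members[0][0]
        g = icosa_group.operators[23].matrix
        rotated = AsymmetricUnit(
            subunits=[s.transformed(g) for s in au.subunits], virus_id=au.virus_id
        )
        base = build_capsidmap(au, truth.interface_keys)
        rot = build_capsidmap(rotated, truth.interface_keys)
        for p0, p1 in zip(base.points, rot.points):
            assert p0.residue == p1.residue
            v = np.array([
                np.sin(np.radians(p0.psi)) * np.cos(np.radians(p0.phi)),
                np.sin(np.radians(p0.psi)) * np.sin(np.radians(p0.phi)),
                np.cos(np.radians(p0.psi)),
            ])
            phi_exp, psi_exp = project_point(g @ v)
            assert p1.psi == pytest.approx(psi_exp, abs=1e-6)
            dphi = (p1.phi - phi_exp) % 360
            assert min(dphi, 360 - dphi) == pytest.approx(0.0, abs=1e-6)

    def test_pooled_full_capsid_angle_set_invariant(self, toy_family, icosa_group):
        """The angle set of ALL subunits' interface residues is rotation-invariant."""
        _, members, truth = toy_family
        au = members[0][0]
        g = icosa_group.operators[41].matrix

        def pooled_angles(the_au):
            assembly = assemble_capsid(the_au, icosa_group)
            angles = set()
            for sub in assembly.subunits:
                for res in sub.residues:
                    cls = sub.label.rstrip("0123456789")
                    if (cls, res.seq_number, "") in truth.interface_keys:
                        phi, psi = project_point(res.atoms[0].coords)
                        angles.add((round(phi, 5) % 360.0, round(psi, 5)))
            return angles

        rotated = AsymmetricUnit(
            subunits=[s.transformed(g) for s in au.subunits], virus_id=au.virus_id
        )
        assert pooled_angles(au) == pooled_angles(rotated)


class TestConservedColumns:
    def test_all_identical(self):
        aln = AlignmentSet(sequences={"a": "ACD", "b": "ACD", "c": "ACD"})
        cols, per_virus = conserved_columns(aln)
        assert cols == [0, 1, 2]
        assert per_virus["a"] == {1, 2, 3}

    def test_single_mismatch(self):
        aln = AlignmentSet(sequences={"a": "ACD", "b": "AED", "c": "ACD"})
        cols, _ = conserved_columns(aln)
        assert cols == [0, 2]

    def test_gap_blocks_conservation(self):
        aln = AlignmentSet(sequences={"a": "A-D", "b": "A-D"})
        cols, _ = conserved_columns(aln)
        assert cols == [0, 2]

    def test_numbering_offsets(self):
        aln = AlignmentSet(sequences={"a": "MAC", "b": "M-C"})
        corr = column_residue_maps(aln, offsets={"a": 10, "b": 5})
        assert corr.col_to_resnum["a"] == {0: 10, 1: 11, 2: 12}
        assert corr.col_to_resnum["b"] == {0: 5, 2: 6}
        assert corr.corresponding("a", 12, "b") == 6
        assert corr.corresponding("a", 11, "b") is None


def _two_maps(displacement):
    """Reference map and a partner displaced by (dphi, dpsi)."""
    ref = CapsidMap(virus_id="r", points=[
        MapPoint(residue=("A", 1, ""), phi=10.0, psi=80.0),
    ])
    other = CapsidMap(virus_id="o", points=[
        MapPoint(residue=("A", 1, ""), phi=10.0 + displacement[0],
                 psi=80.0 + displacement[1]),
    ])
    aln = AlignmentSet(sequences={"r": "A", "o": "A"})
    return [ref, other], column_residue_maps(aln)


class TestAlignMaps:
    def test_identical_maps_fully_conserved(self):
        maps, corr = _two_maps((0.0, 0.0))
        out = align_maps(maps, corr)
        assert out["r"] == {("A", 1, "")}

    @pytest.mark.parametrize("dphi,conserved", [(2.9, True), (3.1, False)])
    def test_three_degree_threshold_boundary(self, dphi, conserved):
        maps, corr = _two_maps((dphi, 0.0))
        out = align_maps(maps, corr)
        assert (("A", 1, "") in out["r"]) is conserved

    def test_phi_wraparound(self):
        ref = CapsidMap(virus_id="r", points=[
            MapPoint(residue=("A", 1, ""), phi=-179.0, psi=90.0)])
        other = CapsidMap(virus_id="o", points=[
            MapPoint(residue=("A", 1, ""), phi=179.5, psi=90.0)])
        aln = AlignmentSet(sequences={"r": "A", "o": "A"})
        out = align_maps([ref, other], column_residue_maps(aln))
        assert out["r"] == {("A", 1, "")}  # 1.5° apart across the seam

    def test_monotone_in_threshold(self, toy_family):
        _, members, truth = toy_family
        from capsidhs.symmetry import generate_group
        group = generate_group()
        maps = []
        aln = AlignmentSet(sequences={au.virus_id: seq for au, seq in members})
        for au, _ in members:
            assembly = assemble_capsid(au, group)
            keys = interface_residue_union(find_interfaces(assembly))
            maps.append(build_capsidmap(au, keys))
        corr = column_residue_maps(aln)
        at3 = align_maps(maps, corr, ConservationConfig(angle_threshold=3.0))
        at4 = align_maps(maps, corr, ConservationConfig(angle_threshold=4.0))
        assert at3["toy0"] <= at4["toy0"]

    def test_requires_two_maps(self):
        maps, corr = _two_maps((0.0, 0.0))
        with pytest.raises(ValueError, match="two"):
            align_maps(maps[:1], corr)

    def test_mismatched_orientation_tags(self):
        maps, corr = _two_maps((0.0, 0.0))
        maps[1].orientation_tag = "other"
        with pytest.raises(ValueError, match="orientation"):
            align_maps(maps, corr)


class TestPredictHotspots:
    def test_empty_sequence_set_gives_no_hotspots(self):
        res = predict_hotspots(
            interface_sets={"r": {("A", 1, "")}},
            seq_conserved_sets={"r": set()},
            space_conserved_sets={"r": {("A", 1, "")}},
            reference="r",
        )
        assert res.hot_spots == []

    def test_intersection_subset_invariant(self, toy_family):
        _, members, truth = toy_family
        aln = AlignmentSet(sequences={au.virus_id: seq for au, seq in members})
        pred = predict_family({au.virus_id: au for au, _ in members}, aln)
        res = pred.result
        hs = set(res.hot_spots)
        assert hs <= res.interface_set[res.reference_virus]
        assert hs <= res.space_conserved_set[res.reference_virus]
        assert {k[1] for k in hs} <= res.sequence_conserved_set[res.reference_virus]

    def test_member_order_irrelevant(self, toy_family):
        _, members, truth = toy_family
        aln = AlignmentSet(sequences={au.virus_id: seq for au, seq in members})
        fwd = predict_family({au.virus_id: au for au, _ in members}, aln,
                             reference="toy0")
        rev = predict_family(
            {au.virus_id: au for au, _ in reversed(members)}, aln,
            reference="toy0",
        )
        assert fwd.result.hot_spots == rev.result.hot_spots

    def test_single_member_family_rejected(self, toy_family):
        _, members, _ = toy_family
        au, seq = members[0]
        aln = AlignmentSet(sequences={au.virus_id: seq})
        with pytest.raises(ValueError, match="two"):
            predict_family({au.virus_id: au}, aln)
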