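"""Rigid-body docking: superposition, component scoring, salt-bridge
detection and ensemble ranking."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hyalodyn.conformer_builder import Atom, Conformer, MolecularTopology, Placement
from hyalodyn.docking import (
    Pocket,
    Site,
    detect_salt_bridge,
    load_pocket,
    rank_ensemble,
    save_pocket,
    score_pose,
    superpose_anchor,
)
from hyalodyn.synthetic_data import centroid_conformer, make_pocket_fixture


def _probe_topology(flags=frozenset({"hbond_acceptor", "carboxylate_O"})):
    """Four-atom probe: three anchor atoms and one scored oxygen."""
    atoms = [
        Atom("P:a1", "C", "P"),
        Atom("P:a2", "C", "P"),
        Atom("P:a3", "C", "P"),
        Atom("P:o", "O", "P", flags=flags),
    ]
    tree = [
        Placement("P:a1", ()),
        Placement("P:a2", ("P:a1",), 1.5),
        Placement("P:a3", ("P:a2", "P:a1"), 1.5, 100.0),
        Placement("P:o", ("P:a3", "P:a2", "P:a1"), 1.4, 109.0, 60.0),
    ]
    return MolecularTopology(
        "probe", atoms, [("P:a1", "P:a2")], tree, anchor_atoms=["P:a1", "P:a2", "P:a3"]
    )


def _conformer(topo, coords):
    return Conformer(coordinates=np.asarray(coords, float), torsion_values={}, mode_labels={})


def _pocket_for(topo, coords, sites):
    return Pocket(
        sites=sites,
        anchor_reference={a: tuple(coords[topo.index[a]]) for a in topo.anchor_atoms},
    )


STERIC_FAR = Site("wall", "steric", (50.0, 50.0, 50.0), radius=1.0)


class TestSuperposition:
    def test_identity_when_already_aligned(self):
        topo = _probe_topology()
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        pocket = _pocket_for(topo, coords, [STERIC_FAR])
        placed, rmsd = superpose_anchor(_conformer(topo, coords), pocket, topo)
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(placed.coordinates, coords, atol=1e-7)

    def test_recovers_known_rigid_transform(self):
        """A 90-degree rotation plus translation applied to the reference is
        inverted to better than 1e-6 Å."""
        topo = _probe_topology()
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        rot = Rotation.from_euler("z", 90, degrees=True)
        ref_coords = rot.apply(coords) + np.array([1.0, 2.0, 3.0])
        pocket = _pocket_for(topo, ref_coords, [STERIC_FAR])
        placed, rmsd = superpose_anchor(_conformer(topo, coords), pocket, topo)
        assert rmsd < 1e-6
        assert np.allclose(placed.coordinates, ref_coords, atol=1e-6)

    def test_reflection_not_used(self):
        """A mirrored four-point anchor (non-coplanar) yields a
        proper-rotation fit with RMSD > 0 and preserved chirality."""
        topo = _probe_topology()
        # all four atoms act as the anchor so the correspondence is chiral
        topo = MolecularTopology(
            topo.name,
            topo.atoms,
            topo.bonds,
            topo.build_tree,
            anchor_atoms=[a.name for a in topo.atoms],
        )
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        assert abs(np.linalg.det(coords[1:] - coords[0])) > 1e-6  # non-coplanar
        mirrored = coords.copy()
        mirrored[:, 2] *= -1.0
        pocket = _pocket_for(topo, mirrored, [STERIC_FAR])
        placed, rmsd = superpose_anchor(_conformer(topo, coords), pocket, topo)
        assert rmsd > 1e-3
        v_orig = np.linalg.det(coords[1:] - coords[0])
        v_placed = np.linalg.det(placed.coordinates[1:] - placed.coordinates[0])
        assert np.sign(v_orig) == np.sign(v_placed)

    def test_too_few_correspondences(self):
        topo = _probe_topology()
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        pocket = Pocket(
            sites=[STERIC_FAR],
            anchor_reference={"P:a1": (0, 0, 0), "P:a2": (1, 0, 0)},
        )
        with pytest.raises(ValueError, match="3 anchor"):
            superpose_anchor(_conformer(topo, coords), pocket, topo)


class TestScoring:
    def test_empty_pocket_scores_zero(self):
        topo = _probe_topology()
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        pocket = _pocket_for(topo, coords, [STERIC_FAR])
        sc = score_pose(_conformer(topo, coords), pocket, topo)
        assert sc.hbond == 0.0
        assert abs(sc.vdw) < 1e-9  # far steric site
        assert sc.torsion_strain == 0.0
        assert sc.total == pytest.approx(sc.hbond + sc.vdw + sc.torsion_strain, abs=1e-9)

    def test_ideal_hbond_pair_scores_full_well(self):
        """An acceptor oxygen 2.9 Å from a donor site earns one full well:
        favorability 4.0."""
        topo = _probe_topology()
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        o = coords[topo.index["P:o"]]
        sites = [
            Site("don", "hbond_donor", tuple(o + np.array([2.9, 0, 0])), radius=1.6),
            STERIC_FAR,
        ]
        pocket = _pocket_for(topo, coords, sites)
        sc = score_pose(_conformer(topo, coords), pocket, topo)
        assert sc.favorability == pytest.approx(4.0, abs=1e-9)

    def test_hbond_zero_beyond_cutoff(self):
        topo = _probe_topology()
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        o = coords[topo.index["P:o"]]
        sites = [
            Site("don", "hbond_donor", tuple(o + np.array([6.0, 0, 0])), radius=1.6),
            STERIC_FAR,
        ]
        pocket = _pocket_for(topo, coords, sites)
        assert score_pose(_conformer(topo, coords), pocket, topo).hbond == 0.0

    def test_rigid_body_invariance(self, ha6_topology, ha6_model, groove_pocket):
        """Rotating pocket and pose together leaves the score unchanged."""
        conf = centroid_conformer(ha6_model, ha6_topology, 1)
        sc0 = score_pose(conf, groove_pocket, ha6_topology)
        rot = Rotation.from_euler("xyz", [31, -57, 112], degrees=True)
        shift = np.array([3.0, -1.0, 7.0])
        moved_conf = Conformer(
            coordinates=rot.apply(conf.coordinates) + shift,
            torsion_values=conf.torsion_values,
            mode_labels=conf.mode_labels,
        )
        moved_pocket = Pocket(
            sites=[
                Site(s.label, s.role, tuple(rot.apply(np.array(s.xyz)) + shift), s.radius)
                for s in groove_pocket.sites
            ],
            anchor_reference={
                k: tuple(rot.apply(np.array(v)) + shift)
                for k, v in groove_pocket.anchor_reference.items()
            },
        )
        sc1 = score_pose(moved_conf, moved_pocket, ha6_topology)
        assert sc1.total == pytest.approx(sc0.total, abs=1e-9)

    def test_carboxylate_monotonicity(self):
        """Pulling a lone carboxylate O from 3.0 to 5.0 Å from the only
        cation never increases favorability."""
        topo = _probe_topology()
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        o_idx = topo.index["P:o"]
        cation_xyz = coords[o_idx] + np.array([3.0, 0.0, 0.0])
        sites = [Site("arg", "cation", tuple(cation_xyz), radius=1.6), STERIC_FAR]
        pocket = _pocket_for(topo, coords, sites)
        favs = []
        for d in np.linspace(3.0, 5.0, 9):
            c = coords.copy()
            c[o_idx] = cation_xyz - np.array([d, 0.0, 0.0])
            favs.append(score_pose(_conformer(topo, c), pocket, topo).favorability)
        assert all(a >= b - 1e-12 for a, b in zip(favs, favs[1:]))


class TestSaltBridge:
    @pytest.mark.parametrize(
        "distance, expected", [(3.0, True), (6.0, False), (3.9, True), (4.1, False)]
    )
    def test_cutoff_inclusive(self, distance, expected):
        topo = _probe_topology()
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        o = coords[topo.index["P:o"]]
        pocket = _pocket_for(
            topo,
            coords,
            [Site("arg", "cation", tuple(o + np.array([distance, 0, 0])), 1.6), STERIC_FAR],
        )
        flag, dmin = detect_salt_bridge(_conformer(topo, coords), pocket, topo)
        assert flag is expected
        assert dmin == pytest.approx(distance)

    def test_two_oxygens_reports_minimum(self):
        topo = _probe_topology()
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        o = coords[topo.index["P:o"]]
        # cation 3.9 from the oxygen; a second farther oxygen is irrelevant
        pocket = _pocket_for(
            topo, coords, [Site("arg", "cation", tuple(o + np.array([3.9, 0, 0])), 1.6), STERIC_FAR]
        )
        flag, dmin = detect_salt_bridge(_conformer(topo, coords), pocket, topo)
        assert flag and dmin == pytest.approx(3.9)

    def test_no_carboxylate_returns_false_not_error(self):
        topo = _probe_topology(flags=frozenset())
        from hyalodyn.conformer_builder import build_cartesian

        coords = build_cartesian(topo, {})
        pocket = _pocket_for(
            topo, coords, [Site("arg", "cation", (0, 0, 5.0), 1.6), STERIC_FAR]
        )
        flag, dmin = detect_salt_bridge(_conformer(topo, coords), pocket, topo)
        assert flag is False
        assert np.isinf(dmin)


class TestRanking:
    def test_mode2_group_dominates(self, docking_ensemble, groove_pocket, ha6_model):
        """On the groove fixture the joint-mode-2 group has the highest mean
        favorability and the best pose is a mode-2 member with a salt
        bridge."""
        ranked, summary = rank_ensemble(docking_ensemble, groove_pocket, ha6_model)
        table = summary.table.set_index("mode")
        assert table.loc[1, "mean"] == table["mean"].max()
        assert ranked[0].mode_label == 1
        assert ranked[0].score.salt_bridge

    def test_summary_conservation(self, docking_ensemble, groove_pocket, ha6_model):
        ranked, summary = rank_ensemble(docking_ensemble, groove_pocket, ha6_model)
        assert summary.n_total == len(docking_ensemble)
        global_max = max(r.score.favorability for r in ranked)
        assert summary.table["max"].max() == pytest.approx(global_max)

    def test_ranking_deterministic(self, docking_ensemble, groove_pocket, ha6_model):
        r1, _ = rank_ensemble(docking_ensemble, groove_pocket, ha6_model)
        r2, _ = rank_ensemble(docking_ensemble, groove_pocket, ha6_model)
        assert [r.conformer_id for r in r1] == [r.conformer_id for r in r2]

    def test_identical_conformers_rank_by_index(self, ha6_topology, ha6_model, groove_pocket):
        from hyalodyn.conformer_builder import Ensemble

        conf = centroid_conformer(ha6_model, ha6_topology, 1)
        ens = Ensemble(topology=ha6_topology, conformers=[conf] * 5, seed=0)
        ranked, _ = rank_ensemble(ens, groove_pocket, ha6_model)
        assert [r.conformer_id for r in ranked] == [0, 1, 2, 3, 4]


class TestPocketIO:
    def test_json_round_trip(self, groove_pocket, tmp_path):
        path = save_pocket(groove_pocket, tmp_path / "p.json")
        back = load_pocket(path)
        assert [s.label for s in back.sites] == [s.label for s in groove_pocket.sites]
        assert back.anchor_reference == pytest.approx(groove_pocket.anchor_reference)

    def test_pocket_requires_steric_site(self):
        with pytest.raises(ValueError, match="steric"):
            Pocket(sites=[Site("c", "cation", (0, 0, 0))], anchor_reference={})

    def test_fixture_deterministic(self):
        p1, _ = make_pocket_fixture()
        p2, _ = make_pocket_fixture()
        assert [s.xyz for s in p1.sites] == [s.xyz for s in p2.sites]

    def test_fixture_anchor_noncollinear(self, groove_pocket):
        pts = np.array(list(groove_pocket.anchor_reference.values()))
        assert len(pts) >= 3
        svals = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        assert svals[1] > 1.0  # genuinely 2D-spread anchor

    def test_mode2_centroid_makes_salt_bridge(self, ha6_topology, ha6_model, groove_pocket):
        conf = centroid_conformer(ha6_model, ha6_topology, 1)
        flag, dmin = detect_salt_bridge(conf, groove_pocket, ha6_topology)
        assert flag
        assert dmin <= 4.0
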