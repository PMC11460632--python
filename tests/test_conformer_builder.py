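"""Conformer construction: NeRF placement, sampling law, ensembles, PDB I/O."""

import numpy as np
import pytest

from hyalodyn.conformer_builder import (
    Atom,
    BuildError,
    MolecularTopology,
    Placement,
    TorsionRef,
    build_cartesian,
    generate_ensemble,
    measure_torsion,
    read_ensemble,
    sample_torsion,
    signed_volume,
    write_ensemble,
)
from hyalodyn.dynamics_model import CodependentGroup, TorsionMode
from tests.conftest import TRUE_POPULATIONS


def _chain4(dihedral=180.0):
    atoms = [Atom(f"X:a{i}", "C", "X") for i in range(4)]
    tree = [
        Placement("X:a0", ()),
        Placement("X:a1", ("X:a0",), 1.5),
        Placement("X:a2", ("X:a1", "X:a0"), 1.5, 109.5),
        Placement("X:a3", ("X:a2", "X:a1", "X:a0"), 1.5, 109.5, dihedral),
    ]
    bonds = [("X:a0", "X:a1"), ("X:a1", "X:a2"), ("X:a2", "X:a3")]
    return MolecularTopology("chain4", atoms, bonds, tree)


class TestBuildCartesian:
    def test_four_atom_anti_chain(self):
        """1.5 Å / 109.5° chain at dihedral 180° is planar anti and
        re-measures exactly."""
        topo = _chain4(180.0)
        coords = build_cartesian(topo, {})
        assert np.allclose(np.linalg.norm(coords[1] - coords[0]), 1.5)
        assert np.allclose(np.linalg.norm(coords[3] - coords[2]), 1.5)
        # planar: all atoms in z=0 plane by the seeding convention
        assert np.allclose(coords[:, 2], 0.0, atol=1e-12)
        assert measure_torsion(coords, [0, 1, 2, 3]) == pytest.approx(180.0)

    def test_dihedral_wrapping_0_vs_360(self):
        topo0 = _chain4(0.0)
        topo360 = _chain4(360.0)
        assert np.allclose(build_cartesian(topo0, {}), build_cartesian(topo360, {}))

    def test_bond_geometry_matches_tree(self, ha4_topology, ha4_model):
        """Every placed bond length and angle reproduces its build-tree
        value (1e-6 Å / 1e-4 deg)."""
        ens = generate_ensemble(ha4_model, ha4_topology, 1, seed=5)
        coords = ens.conformers[0].coordinates
        idx = ha4_topology.index
        for k, p in enumerate(ha4_topology.build_tree):
            if k < 1:
                continue
            d = np.linalg.norm(coords[idx[p.atom]] - coords[idx[p.refs[0]]])
            assert d == pytest.approx(p.length, abs=1e-6)
            if k >= 2:
                v1 = coords[idx[p.atom]] - coords[idx[p.refs[0]]]
                v2 = coords[idx[p.refs[1]]] - coords[idx[p.refs[0]]]
                ang = np.degrees(
                    np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                )
                assert ang == pytest.approx(p.angle, abs=1e-4)

    def test_round_trip_100_random_torsion_sets(self, ha4_topology, ha4_model):
        """Build -> measure round-trips every named torsion within 1e-4 deg
        over 100 random draws."""
        rng = np.random.default_rng(42)
        names = ha4_topology.torsion_names()
        quads = {n: ha4_topology.torsion_quadruple(n) for n in names}
        for _ in range(100):
            values = {n: float(rng.uniform(-180.0, 180.0)) for n in names}
            coords = build_cartesian(ha4_topology, values)
            for n in names:
                measured = measure_torsion(coords, quads[n], ha4_topology)
                delta = (measured - values[n] + 180.0) % 360.0 - 180.0
                assert abs(delta) < 1e-4

    def test_unresolved_torsion_raises(self, ha4_topology):
        with pytest.raises(BuildError, match="unresolved"):
            build_cartesian(ha4_topology, {})

    def test_measure_torsion_cis_trans(self):
        square = np.array(
            [[1.0, 1.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]
        )
        assert measure_torsion(square, [0, 1, 2, 3]) == pytest.approx(0.0)
        zigzag = np.array(
            [[1.0, 1.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]
        )
        assert abs(measure_torsion(zigzag, [0, 1, 2, 3])) == pytest.approx(180.0)

    def test_collinear_dihedral_raises(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
        with pytest.raises(BuildError, match="collinear"):
            measure_torsion(line, [0, 1, 2, 3])


class TestSampling:
    def test_degenerate_group_returns_mean(self):
        group = CodependentGroup(
            group_id="g",
            torsions=["t"],
            modes=[{"t": TorsionMode(-60.0, 1e-9)}],
            populations=[1.0],
        )
        angles, mode = sample_torsion(group, np.random.default_rng(0))
        assert mode == 0
        assert angles["t"] == pytest.approx(-60.0, abs=1e-6)

    def test_same_seed_identical_draws(self, ha4_model):
        g = ha4_model.groups[0]
        r1 = [sample_torsion(g, np.random.default_rng(3)) for _ in range(5)]
        r2 = [sample_torsion(g, np.random.default_rng(3)) for _ in range(5)]
        assert r1 == r2

    def test_mode_frequencies_converge_to_occupancies(self, ha4_model):
        """10,000 joint-mode draws land within 3 standard errors of every
        occupancy."""
        g = ha4_model.groups[0]
        rng = np.random.default_rng(123)
        counts = np.zeros(5)
        n = 10_000
        for _ in range(n):
            _, mode = sample_torsion(g, rng)
            counts[mode] += 1
        freqs = counts / n
        for f, pi in zip(freqs, TRUE_POPULATIONS):
            se = np.sqrt(pi * (1 - pi) / n)
            assert abs(f - pi) < 3 * se + 1e-12


class TestEnsemble:
    def test_reproducible_from_seed(self, ha4_model, ha4_topology):
        e1 = generate_ensemble(ha4_model, ha4_topology, 5, seed=9)
        e2 = generate_ensemble(ha4_model, ha4_topology, 5, seed=9)
        assert np.array_equal(e1.coordinates(), e2.coordinates())
        assert [c.mode_labels for c in e1.conformers] == [
            c.mode_labels for c in e2.conformers
        ]

    def test_singleton_ensemble(self, ha4_model, ha4_topology):
        ens = generate_ensemble(ha4_model, ha4_topology, 1, seed=0)
        assert len(ens) == 1

    def test_anchor_atoms_bitwise_identical(self, small_ensemble):
        topo = small_ensemble.topology
        idx = [topo.index[a] for a in topo.anchor_atoms]
        coords = small_ensemble.coordinates()[:, idx, :]
        assert np.all(coords == coords[0])

    def test_chirality_preserved_across_ensemble(self, small_ensemble):
        """Signed stereocenter volumes keep their sign in every conformer."""
        topo = small_ensemble.topology
        for center, neighbors in topo.stereocenters:
            signs = {
                np.sign(signed_volume(c.coordinates, topo, center, neighbors))
                for c in small_ensemble.conformers
            }
            assert len(signs) == 1

    def test_mode_counts_multinomial(self, docking_ensemble):
        """250 conformers distribute over joint modes around n*pi."""
        counts = np.zeros(5)
        for c in docking_ensemble.conformers:
            counts[next(iter(c.mode_labels.values()))] += 1
        assert counts.sum() == 250
        for k, pi in enumerate(TRUE_POPULATIONS):
            sd = np.sqrt(250 * pi * (1 - pi))
            assert abs(counts[k] - 250 * pi) < 4 * sd + 1e-9

    def test_invalid_size(self, ha4_model, ha4_topology):
        with pytest.raises(BuildError):
            generate_ensemble(ha4_model, ha4_topology, 0, seed=1)


class TestPdbIO:
    def test_model_count_matches_ensemble(self, small_ensemble, tmp_path):
        path = write_ensemble(small_ensemble, tmp_path / "ens.pdb")
        text = path.read_text()
        assert text.count("MODEL ") == len(small_ensemble)
        assert "REMARK 250 SEED 11" in text

    def test_write_read_write_byte_identical(self, small_ensemble, tmp_path):
        p1 = write_ensemble(small_ensemble, tmp_path / "a.pdb")
        back = read_ensemble(p1, small_ensemble.topology)
        p2 = write_ensemble(back, tmp_path / "b.pdb")
        assert p1.read_bytes() == p2.read_bytes()
        assert back.seed == small_ensemble.seed
        assert [c.mode_labels for c in back.conformers] == [
            c.mode_labels for c in small_ensemble.conformers
        ]

    def test_empty_path_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            write_ensemble(small_ensemble, "")
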