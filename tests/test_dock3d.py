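import numpy as np
import pytest

from aptevolve.dock3d import (
    ContactRecord,
    Structure3D,
    brute_force_correlate,
    correlate_grids,
    detect_hbonds,
    embed_coarse_3d,
    fft_shape_dock,
    import_external_scores,
    read_pdb,
    rotation_set,
    voxelize,
    write_pdb,
)
from aptevolve.fixtures import make_block_with_notch
from aptevolve.folding import fold_mfe
from aptevolve.sequences import NucleotideSequence


def _structure(coords, names=None, chains=None, resids=None):
    n = len(coords)
    return Structure3D(
        atom_names=names or ["C"] * n,
        residue_names=["RES"] * n,
        chain_ids=chains or ["A"] * n,
        residue_indices=np.array(resids if resids is not None else range(1, n + 1)),
        coords=np.array(coords, dtype=float),
    )


class TestPdbIO:
    def test_round_trip_preserves_coordinates_and_chains(self, tmp_path):
        s = _structure(
            [(1.234, -2.5, 0.001), (4.0, 4.0, 4.0), (-3.25, 1.0, 2.75)],
            names=["N1", "O2", "CA"],
            chains=["A", "B", "B"],
        )
        path = tmp_path / "x.pdb"
        write_pdb(s, path)
        back = read_pdb(path)
        assert np.allclose(back.coords, s.coords, atol=1e-3)
        assert back.chain_ids == s.chain_ids
        assert back.atom_names == s.atom_names

    def test_file_without_atoms_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER  nothing\nEND\n")
        with pytest.raises(ValueError):
            read_pdb(p)


class TestEmbedding:
    def test_open_chain_spacing_is_the_backbone_step(self, energy_model):
        fold = fold_mfe(NucleotideSequence("a", "A" * 10), model=energy_model)
        s = embed_coarse_3d(fold)
        assert len(s) == 10
        d = np.linalg.norm(np.diff(s.coords, axis=0), axis=1)
        assert np.allclose(d, 6.5)

    def test_hairpin_partners_sit_across_the_helix_diameter(self, energy_model):
        fold = fold_mfe(NucleotideSequence("hp", "GCGCGCAAAAGCGCGC"), model=energy_model)
        assert fold.structure.pairs
        s = embed_coarse_3d(fold)
        for i, j in fold.structure.pairs:
            dist = np.linalg.norm(s.coords[i - 1] - s.coords[j - 1])
            assert dist == pytest.approx(20.0, abs=1.0)

    def test_embedding_is_deterministic(self, energy_model):
        fold = fold_mfe(NucleotideSequence("hp", "GGGGAAAACCCC"), model=energy_model)
        a = embed_coarse_3d(fold)
        b = embed_coarse_3d(fold)
        assert np.array_equal(a.coords, b.coords)


class TestVoxelisation:
    def test_single_atom_count_matches_direct_geometry(self):
        s = _structure([(0.0, 0.0, 0.0)])
        g = voxelize(s, spacing=2.0, radius=2.0)
        idx = np.stack(np.nonzero(g.occupied), axis=1)
        centres = g.origin + idx * g.spacing
        direct = sum(
            1
            for x in np.arange(-3, 4) * 2.0
            for y in np.arange(-3, 4) * 2.0
            for z in np.arange(-3, 4) * 2.0
            if np.linalg.norm([x, y, z]) <= 2.0
        )
        assert g.occupied.sum() == direct
        assert all(np.linalg.norm(c) <= 2.0 for c in centres)

    def test_coarser_grid_marks_fewer_voxels(self):
        rec, _, _ = make_block_with_notch(8, 2)
        fine = voxelize(rec, spacing=1.0, radius=1.0)
        coarse = voxelize(rec, spacing=2.0, radius=1.0)
        assert coarse.occupied.sum() < fine.occupied.sum()

    def test_surface_plus_interior_partition_occupancy(self):
        rec, _, _ = make_block_with_notch(8, 2)
        g = voxelize(rec, spacing=2.0, radius=1.0)
        assert not (g.surface & g.interior).any()
        assert ((g.surface | g.interior) == g.occupied).all()
        assert g.surface.sum() > 0 and g.interior.sum() > 0


class TestDocking:
    def test_fft_equals_brute_force_on_random_grids(self):
        rng = np.random.default_rng(2)
        for _ in range(4):
            rs = tuple(rng.integers(3, 9, size=3))
            ls = tuple(rng.integers(2, 5, size=3))
            R = rng.normal(size=rs)
            L = rng.normal(size=ls)
            assert np.allclose(
                correlate_grids(R, L), brute_force_correlate(R, L), atol=1e-6
            )

    def test_notch_fixture_docks_at_the_constructed_offset(self):
        rec, lig, expected = make_block_with_notch(10, 3)
        grid = voxelize(rec, spacing=2.0, radius=1.0)
        poses = fft_shape_dock(
            grid, lig, rotations=rotation_set(1), top_n=10, ligand_radius=1.0
        )
        assert np.allclose(poses[0].shift_angstrom, expected, atol=grid.spacing)
        assert poses[0].score > poses[1].score
        scores = [p.score for p in poses]
        assert scores == sorted(scores, reverse=True)

    def test_zero_ligand_grid_scores_zero(self):
        rec, _, _ = make_block_with_notch(6, 2)
        g = voxelize(rec, spacing=2.0, radius=1.0)
        from aptevolve.dock3d import receptor_docking_weights

        corr = correlate_grids(receptor_docking_weights(g), np.zeros((3, 3, 3)))
        assert corr.max() == 0.0

    def test_enlarging_rotation_set_never_lowers_best_score(self, energy_model):
        rec, lig, _ = make_block_with_notch(8, 3)
        grid = voxelize(rec, spacing=2.0, radius=1.0)
        best4 = fft_shape_dock(grid, lig, rotation_set(4), top_n=1, ligand_radius=1.0)[0].score
        best8 = fft_shape_dock(grid, lig, rotation_set(8), top_n=1, ligand_radius=1.0)[0].score
        assert best8 >= best4
        with pytest.raises(ValueError):
            fft_shape_dock(grid, lig, [], top_n=1)

    def test_rigid_translation_of_both_partners_preserves_score(self):
        rec, lig, _ = make_block_with_notch(8, 3)
        grid = voxelize(rec, spacing=2.0, radius=1.0)
        ref = fft_shape_dock(grid, lig, rotation_set(1), top_n=1, ligand_radius=1.0)[0].score
        vec = np.array([1.3, -2.7, 0.9])
        grid2 = voxelize(rec.translated(vec), spacing=2.0, radius=1.0)
        moved = fft_shape_dock(
            grid2, lig.translated(vec), rotation_set(1), top_n=1, ligand_radius=1.0
        )[0].score
        assert moved == pytest.approx(ref, abs=1e-6)


class TestHydrogenBonds:
    def _complex(self, da_dist, angle_deg):
        """Donor N + its H on chain A; acceptor O on chain B."""
        theta = np.deg2rad(180.0 - angle_deg)
        h = np.array([1.0, 0.0, 0.0])
        acceptor = h + (da_dist - 1.0) * np.array([np.cos(theta), np.sin(theta), 0.0])
        return _structure(
            [(0.0, 0.0, 0.0), tuple(h), tuple(acceptor)],
            names=["N", "H", "O"],
            chains=["A", "A", "B"],
            resids=[1, 1, 1],
        )

    def test_good_geometry_yields_one_bond(self):
        c = self._complex(2.9, 165.0)
        records = detect_hbonds(c, "A", "B")
        assert len(records) == 1
        rec = records[0]
        assert rec.donor[0] == "A" and rec.acceptor[0] == "B"
        assert rec.distance == pytest.approx(np.linalg.norm(c.coords[2]), abs=1e-6)

    def test_long_distance_or_bent_angle_rejected(self):
        assert detect_hbonds(self._complex(5.0, 165.0), "A", "B") == []
        assert detect_hbonds(self._complex(2.9, 90.0), "A", "B") == []

    def test_symmetric_under_chain_relabelling(self):
        c = self._complex(2.9, 165.0)
        swapped = Structure3D(
            atom_names=c.atom_names,
            residue_names=c.residue_names,
            chain_ids=["B", "B", "A"],
            residue_indices=c.residue_indices,
            coords=c.coords,
        )
        assert len(detect_hbonds(swapped, "A", "B")) == 1

    def test_missing_chain_errors(self):
        with pytest.raises(KeyError):
            detect_hbonds(self._complex(2.9, 165.0), "A", "Z")


class TestExternalScores:
    def test_ranking_matches_reported_docking_order(self, tmp_path):
        csv = tmp_path / "scores.csv"
        csv.write_text(
            "sequence_id,score\nB1-4,1246.537\nM5-5,1543.334\nB1-4-neg,1124.301\n"
        )
        fitness = import_external_scores(csv)
        m55 = NucleotideSequence("M5-5", "ACGT")
        b14 = NucleotideSequence("B1-4", "ACGT")
        neg = NucleotideSequence("B1-4-neg", "ACGT")
        assert fitness(m55) > fitness(b14) > fitness(neg)

    def test_unknown_sequence_is_an_error_not_zero(self, tmp_path):
        csv = tmp_path / "scores.csv"
        csv.write_text("sequence_id,score\nB1-4,1246.537\n")
        fitness = import_external_scores(csv)
        with pytest.raises(KeyError):
            fitness(NucleotideSequence("mystery", "ACGT"))

    def test_duplicates_equal_ok_conflicting_rejected(self, tmp_path):
        ok = tmp_path / "ok.csv"
        ok.write_text("sequence_id,score\na,1.5\na,1.5\n")
        assert import_external_scores(ok)(NucleotideSequence("a", "ACGT")) == 1.5
        bad = tmp_path / "bad.csv"
        bad.write_text("sequence_id,score\na,1.5\na,2.5\n")
        with pytest.raises(ValueError):
            import_external_scores(bad)
        nocol = tmp_path / "nocol.csv"
        nocol.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError):
            import_external_scores(nocol)
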