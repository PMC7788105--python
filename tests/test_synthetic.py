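"""Generators: determinism, geometric guarantees, truth bookkeeping."""

import numpy as np
import pytest

from orthosite.alignment import matrix_score
from orthosite.binding import fit_kd
from orthosite.structure import extract_sequence
from orthosite.superposition import kabsch_fit
from orthosite.synthetic import (
    GenerationError,
    make_ortholog,
    make_toy_domain,
    perturb_copy,
    plant_ligand,
    simulate_titration,
)


def _coords(structure):
    return np.array(
        [a.xyz for c in structure.chains for r in c.residues for a in r.atoms]
    )


class TestMakeToyDomain:
    def test_helix_ca_spacing(self):
        s = make_toy_domain("ACDEFGHIKL", "helix", seed=0)
        cas = np.array([r.atom("CA").xyz for r in s.chain("A").residues])
        spacing = np.linalg.norm(np.diff(cas, axis=0), axis=1)
        assert np.all(np.abs(spacing - 3.8) < 0.1)
        assert len(cas) == 10

    def test_deterministic(self):
        a = make_toy_domain("ACDEFGHIKL", "helix", seed=7)
        b = make_toy_domain("ACDEFGHIKL", "helix", seed=7)
        np.testing.assert_array_equal(_coords(a), _coords(b))

    def test_glycine_has_no_cb(self):
        s = make_toy_domain("AGAGA", "strand", seed=0)
        for res in s.chain("A").residues:
            has_cb = res.atom("CB") is not None
            assert has_cb == (res.name3 != "GLY")

    def test_sequence_round_trip(self):
        seq = "MKVLYACDEF"
        assert extract_sequence(make_toy_domain(seq, "helix", seed=1).chain("A")) == seq

    def test_too_short_rejected(self):
        with pytest.raises(GenerationError, match="too short"):
            make_toy_domain("ACD", "helix")

    def test_unknown_geometry_rejected(self):
        with pytest.raises(GenerationError, match="geometry"):
            make_toy_domain("ACDEF", "sheet")


class TestPerturbCopy:
    def test_zero_noise_transform_recovered(self, toy_domain):
        copy, (R, t) = perturb_copy(toy_domain, rotation_seed=3, noise_sd=0.0, seed=3)
        A = np.array([r.atom("CA").xyz for r in toy_domain.chain("A").residues])
        B = np.array([r.atom("CA").xyz for r in copy.chain("A").residues])
        sup = kabsch_fit(A, B)
        assert sup.rmsd <= 1e-9
        # the fitted transform inverts the applied one
        np.testing.assert_allclose(sup.rotation @ R, np.eye(3), atol=1e-9)

    def test_fixed_rotation_seed_gives_fixed_transform(self, toy_domain):
        _, (r1, t1) = perturb_copy(toy_domain, rotation_seed=5, noise_sd=0.3, seed=1)
        _, (r2, t2) = perturb_copy(toy_domain, rotation_seed=5, noise_sd=0.3, seed=2)
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_array_equal(t1, t2)

    def test_noise_distribution_over_seeds(self, toy_domain):
        A = np.array([r.atom("CA").xyz for r in toy_domain.chain("A").residues])
        rmsds = []
        for seed in range(50):
            copy, _ = perturb_copy(toy_domain, rotation_seed=0, noise_sd=0.5, seed=seed)
            B = np.array([r.atom("CA").xyz for r in copy.chain("A").residues])
            rmsds.append(kabsch_fit(A, B).rmsd)
        assert all(0 < r < 2 for r in rmsds)

    def test_applied_transform_maps_copy_back(self, toy_domain):
        copy, (R, t) = perturb_copy(toy_domain, rotation_seed=11, noise_sd=0.0, seed=0)
        orig = _coords(toy_domain)
        moved = _coords(copy)
        np.testing.assert_allclose(moved, orig @ R.T + t, atol=1e-9)


class TestPlantLigand:
    def test_exact_distance_invariant(self, toy_complex):
        s = toy_complex.structure
        lig = [a for a in s.chain("L").residues[0].atoms]
        lig_xyz = np.array([a.xyz for a in lig])
        for res in s.chain("A").residues:
            coords = np.array([a.xyz for a in res.atoms])
            dmin = np.linalg.norm(coords[:, None] - lig_xyz[None, :], axis=2).min()
            if res.number in toy_complex.planted_epitope:
                assert dmin == pytest.approx(3.5, abs=1e-6)
            else:
                assert dmin > 3.5 + 2.0

    def test_ligand_written_as_hetatm(self, toy_complex, tmp_path):
        from orthosite.structure import read_structure, write_pdb

        p = tmp_path / "cx.pdb"
        write_pdb(toy_complex.structure, p)
        text = p.read_text()
        assert "HETATM" in text and "LIG" in text
        s2 = read_structure(p)
        assert any(r.name3 == "LIG" for c in s2.chains for r in c.residues)

    def test_empty_epitope_rejected(self, toy_domain):
        with pytest.raises(GenerationError, match="at least one"):
            plant_ligand(toy_domain, ())

    def test_unknown_residue_rejected(self, toy_domain):
        with pytest.raises(GenerationError, match="not in receptor"):
            plant_ligand(toy_domain, (999,))

    def test_all_residue_epitope(self):
        from orthosite.interface import LigandSelection, interface_residues

        dom = make_toy_domain("ACDEFGHIKL", "helix", seed=2)
        numbers = tuple(r.number for r in dom.chain("A").residues)
        truth = plant_ligand(dom, numbers, 3.5, seed=2, clearance=2.0)
        site = interface_residues(truth.structure, "A", LigandSelection.het("LIG"), 4.5)
        assert site.numbers == numbers

    def test_deterministic(self, toy_domain):
        t1 = plant_ligand(toy_domain, (5, 9), 3.5, seed=4)
        t2 = plant_ligand(toy_domain, (5, 9), 3.5, seed=4)
        np.testing.assert_array_equal(_coords(t1.structure), _coords(t2.structure))


class TestMakeOrtholog:
    def test_full_identity_unchanged(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        truth = make_ortholog(seq, 100.0, seed=1)
        assert truth.seq_ortholog == seq
        assert truth.mutated_positions == ()

    def test_target_on_109_mer(self):
        seq = ("ACDEFGHIKLMNPQRSTVWY" * 6)[:109]
        truth = make_ortholog(seq, 69.4, seed=1)
        n_identical = 109 - len(truth.mutated_positions)
        assert n_identical in (75, 76)  # round(109 * 0.694) = 76
        assert truth.realized_identity == pytest.approx(100.0 * n_identical / 109)

    def test_same_seed_same_mutations(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEF"
        t1 = make_ortholog(seq, 70.0, seed=9)
        t2 = make_ortholog(seq, 70.0, seed=9)
        assert t1.seq_ortholog == t2.seq_ortholog
        assert t1.mutated_positions == t2.mutated_positions

    def test_mutations_change_exactly_listed_positions(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEF"
        truth = make_ortholog(seq, 60.0, seed=3)
        for i, (a, b) in enumerate(zip(truth.seq_parent, truth.seq_ortholog)):
            assert (a != b) == (i in truth.mutated_positions)

    def test_minor_fraction_extremes(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        all_minor = make_ortholog(seq, 50.0, seed=5, minor_fraction=1.0)
        for i in all_minor.mutated_positions:
            a, b = all_minor.seq_parent[i], all_minor.seq_ortholog[i]
            # a conservative replacement unless none exists for that residue
            if any(matrix_score(a, x) > 0 for x in "ACDEFGHIKLMNPQRSTVWY" if x != a):
                assert matrix_score(a, b) > 0


class TestSimulateTitration:
    def test_noiseless_round_trip(self):
        data = simulate_titration(kd=1e-5, target_conc=2e-8, noise_sd=0.0, seed=0)
        fit = fit_kd(data)
        assert fit.kd == pytest.approx(1e-5, rel=1e-6)

    def test_huge_kd_flat_at_baseline(self):
        data = simulate_titration(
            kd=10.0, target_conc=2e-8, response_free=850.0, response_bound=900.0,
            noise_sd=0.0, seed=0,
        )
        np.testing.assert_allclose(data.response, 850.0, atol=1e-2)

    def test_fixed_seed_identical(self):
        d1 = simulate_titration(kd=1e-6, target_conc=2e-8, noise_sd=3.0, seed=8)
        d2 = simulate_titration(kd=1e-6, target_conc=2e-8, noise_sd=3.0, seed=8)
        np.testing.assert_array_equal(d1.response, d2.response)
        np.testing.assert_array_equal(d1.ligand_conc, d2.ligand_conc)

    def test_serial_dilution_structure(self):
        data = simulate_titration(kd=1e-6, target_conc=2e-8, n_points=10,
                                  dilution_factor=3.0, top_conc=9e-5, seed=0)
        ratios = data.ligand_conc[:-1] / data.ligand_conc[1:]
        np.testing.assert_allclose(ratios, 3.0)
        assert data.ligand_conc[0] == pytest.approx(9e-5)
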