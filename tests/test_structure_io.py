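"""Structure and sequence I/O: parsing rules, round trips, selections."""

import numpy as np
import pytest

from orthosite.structure import (
    Atom,
    Chain,
    Residue,
    Structure,
    StructureError,
    count_polymer_chains,
    extract_sequence,
    read_fasta,
    read_structure,
    write_fasta,
    write_pdb,
)
from orthosite.synthetic import make_toy_domain

MINI_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CA  GLY B   7       2.286   8.018  -1.805  1.00  0.00           C
ATOM      4  C   GLY B   7       1.091   7.319  -1.169  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1      10.000   6.000  -6.000  1.00  0.00           N
ATOM      2  CA ASER A   1      11.000   6.000  -5.000  0.60  0.00           C
ATOM      3  CA BSER A   1      12.000   6.000  -5.000  0.40  0.00           C
ATOM      4  OG  SER A   1      11.500   7.200  -4.100  1.00  0.00           O
END
"""

HETERO_PDB = """\
ATOM      1  CA  MSE A   1      11.000   6.000  -5.000  1.00  0.00           C
ATOM      2  CA  ALA A   2      14.500   6.500  -5.200  1.00  0.00           C
HETATM    3  C1  LIG B   1       2.000   2.000   2.000  1.00  0.00           C
HETATM    4  O   HOH C   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      5  H   ALA A   2      14.800   6.900  -5.600  1.00  0.00           H
END
"""


class TestReadStructure:
    def test_hand_written_two_chains(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        s = read_structure(p, format="pdb")
        assert [c.id for c in s.chains] == ["A", "B"]
        assert sum(len(c.residues) for c in s.chains) == 2
        assert s.chain("A").residues[0].number == 1
        assert s.chain("B").residues[0].number == 7

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        p.write_text(ALTLOC_PDB)
        s = read_structure(p)
        res = s.chain("A").residues[0]
        cas = [a for a in res.atoms if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].xyz[0] == pytest.approx(11.0)  # altloc A, occ 0.6
        assert len(res.atoms) == 3  # N, CA, OG

    def test_altloc_tie_broken_lexicographically(self, tmp_path):
        text = ALTLOC_PDB.replace("0.60", "0.40")
        p = tmp_path / "tie.pdb"
        p.write_text(text)
        res = read_structure(p).chain("A").residues[0]
        ca = res.atom("CA")
        assert ca.xyz[0] == pytest.approx(11.0)  # altloc 'A' < 'B'

    def test_waters_and_hydrogens_dropped(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(HETERO_PDB)
        s = read_structure(p)
        assert {c.id for c in s.chains} == {"A", "B"}  # water-only chain gone
        names = [a.name for a in s.chain("A").residues[1].atoms]
        assert "H" not in names

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        with pytest.raises(StructureError, match="unknown structure format"):
            read_structure(p, format="xyzzy")

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(StructureError, match="not found"):
            read_structure(tmp_path / "absent.pdb")

    def test_garbage_rejected(self, tmp_path):
        p = tmp_path / "bad.cif"
        p.write_text("this is not a structure\n")
        with pytest.raises(StructureError):
            read_structure(p, format="mmcif")


class TestPolymerDetection:
    def test_single_chain_toy_domain(self):
        s = make_toy_domain("ACDEFGH", "helix", seed=0)
        assert count_polymer_chains(s) == 1

    def test_ligand_only_chain_not_counted(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(HETERO_PDB)
        s = read_structure(p)
        # brute-force expectation: per-chain scan for standard aa with CA
        expected = sum(
            1 for c in s.chains
            if any(r.is_standard_aa and r.atom("CA") for r in c.residues)
        )
        assert count_polymer_chains(s) == expected == 1


class TestExtractSequence:
    def test_three_residues(self):
        chain = Chain(id="A", residues=[
            Residue("ALA", 1, atoms=[Atom("CA", "C", (0, 0, 0))]),
            Residue("CYS", 2, atoms=[Atom("CA", "C", (3.8, 0, 0))]),
            Residue("ASP", 3, atoms=[Atom("CA", "C", (7.6, 0, 0))]),
        ])
        assert extract_sequence(chain) == "ACD"

    def test_selenomethionine_maps_to_m(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(HETERO_PDB)
        assert extract_sequence(read_structure(p).chain("A")) == "MA"

    def test_generator_round_trip(self, tmp_path):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        s = make_toy_domain(seq, "strand", seed=1)
        p = tmp_path / "toy.pdb"
        write_pdb(s, p)
        assert extract_sequence(read_structure(p).chain("A")) == seq

    def test_length_equals_polymer_residues(self, toy_domain):
        chain = toy_domain.chain("A")
        assert len(extract_sequence(chain)) == len(chain.polymer_residues())

    def test_non_polymer_chain_rejected(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(HETERO_PDB)
        with pytest.raises(StructureError, match="not polymeric"):
            extract_sequence(read_structure(p).chain("B"))


class TestPdbRoundTrip:
    def test_counts_and_coordinates_preserved(self, toy_complex, tmp_path):
        s = toy_complex.structure
        p = tmp_path / "out.pdb"
        write_pdb(s, p)
        s2 = read_structure(p, format="pdb")
        assert [c.id for c in s2.chains] == [c.id for c in s.chains]
        for c1, c2 in zip(s.chains, s2.chains):
            assert len(c1.residues) == len(c2.residues)
            for r1, r2 in zip(c1.residues, c2.residues):
                assert (r1.name3, r1.number) == (r2.name3, r2.number)
                assert len(r1.atoms) == len(r2.atoms)
                for a1, a2 in zip(r1.atoms, r2.atoms):
                    np.testing.assert_allclose(a1.xyz, a2.xyz, atol=1e-3)

    def test_altloc_resolution_keeps_residue_count(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        p.write_text(ALTLOC_PDB)
        s = read_structure(p)
        assert len(s.chain("A").residues) == 1


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta([("a", "ACD")], p)
        assert p.read_text() == ">a\nACD\n"

    def test_round_trip(self, tmp_path):
        records = [("x", "ACDEFG"), ("y", "MKV" * 30)]
        p = tmp_path / "two.fasta"
        write_fasta(records, p)
        assert read_fasta(p) == records

    def test_wrapped_at_60_columns(self, tmp_path):
        seq = "A" * 70
        p = tmp_path / "wrap.fasta"
        write_fasta([("long", seq)], p)
        lines = p.read_text().splitlines()
        assert lines[1:] == ["A" * 60, "A" * 10]

    def test_duplicate_ids_rejected(self, tmp_path):
        with pytest.raises(StructureError, match="duplicate"):
            write_fasta([("a", "ACD"), ("a", "WYV")], tmp_path / "dup.fasta")

    def test_empty_sequence_rejected(self, tmp_path):
        with pytest.raises(StructureError, match="empty"):
            write_fasta([("a", "")], tmp_path / "empty.fasta")


class TestInvariants:
    def test_atom_occupancy_validated(self):
        with pytest.raises(StructureError):
            Atom("CA", "C", (0, 0, 0), occupancy=1.5)

    def test_atom_coordinates_validated(self):
        with pytest.raises(StructureError):
            Atom("CA", "C", (np.nan, 0, 0))

    def test_duplicate_chain_ids_rejected(self):
        res = [Residue("ALA", 1, atoms=[Atom("CA", "C", (0, 0, 0))])]
        with pytest.raises(StructureError, match="duplicate chain"):
            Structure(id="x", chains=[Chain("A", res), Chain("A", res)])
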