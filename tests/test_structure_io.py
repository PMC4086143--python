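import numpy as np
import pytest

from protstab import (build_mutant_placeholder, enumerate_mutants, parse_mutation,
                      read_pdb, write_pdb)
from protstab.structure_io import STANDARD_AA, MutationError, PDBParseError


def test_mini_helix_parses_with_expected_counts(mini_helix_pdb):
    s = read_pdb(mini_helix_pdb)
    assert len(s.residues) == 12
    assert s.n_atoms == 60
    assert all(r.aa == "A" for r in s.residues)


def test_round_trip_preserves_coordinates_to_pdb_precision(mini_helix_pdb, tmp_path):
    s1 = read_pdb(mini_helix_pdb)
    out = tmp_path / "rt.pdb"
    write_pdb(s1, str(out))
    s2 = read_pdb(str(out))
    assert [r.key for r in s1.residues] == [r.key for r in s2.residues]
    assert [r.aa for r in s1.residues] == [r.aa for r in s2.residues]
    for r1, r2 in zip(s1.residues, s2.residues):
        assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
        for a1, a2 in zip(r1.atoms, r2.atoms):
            np.testing.assert_allclose(a1.coord, a2.coord, atol=5e-4)


def test_multi_model_file_keeps_first_model_only(mini_helix_pdb, tmp_path):
    body = open(mini_helix_pdb).read().splitlines()
    atoms = [l for l in body if l.startswith("ATOM")]
    shifted = []
    for l in atoms:
        x = float(l[30:38]) + 50.0
        shifted.append(l[:30] + f"{x:8.3f}" + l[38:])
    text = "MODEL     1\n" + "\n".join(atoms) + "\nENDMDL\nMODEL     2\n" + \
        "\n".join(shifted) + "\nENDMDL\nEND\n"
    path = tmp_path / "nmr.pdb"
    path.write_text(text)
    s = read_pdb(str(path))
    ref = read_pdb(mini_helix_pdb)
    assert s.n_atoms == ref.n_atoms
    np.testing.assert_allclose(s.residues[0].atoms[0].coord,
                               ref.residues[0].atoms[0].coord, atol=1e-3)


def test_altloc_resolves_to_highest_occupancy(tmp_path):
    lines = [
        "ATOM      1  N   ALA A   5      11.000  10.000  10.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   5      12.458  10.000  10.000  1.00  0.00           C",
        "ATOM      3  C   ALA A   5      13.000  11.400  10.000  1.00  0.00           C",
        "ATOM      4  O   ALA A   5      12.400  12.400  10.000  1.00  0.00           O",
        "ATOM      5  CB AALA A   5      13.000   9.000  11.000  0.60  0.00           C",
        "ATOM      6  CB BALA A   5      13.000   9.000   9.000  0.40  0.00           C",
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    s = read_pdb(str(path))
    cb = s.residues[0].atom("CB")
    assert cb.occupancy == pytest.approx(0.6)
    assert cb.coord[2] == pytest.approx(11.0, abs=1e-3)


def test_waters_and_hetero_groups_are_excluded_mse_kept(tmp_path):
    lines = [
        "ATOM      1  N   MET A   1      11.000  10.000  10.000  1.00  0.00           N",
        "ATOM      2  CA  MET A   1      12.458  10.000  10.000  1.00  0.00           C",
        "ATOM      3  C   MET A   1      13.000  11.400  10.000  1.00  0.00           C",
        "ATOM      4  O   MET A   1      12.400  12.400  10.000  1.00  0.00           O",
        "HETATM    5  SE  MSE A   2      15.000  10.000  10.000  1.00  0.00          SE",
        "HETATM    6  CA  MSE A   2      16.458  10.000  10.000  1.00  0.00           C",
        "HETATM    7  N   MSE A   2      17.000  11.400  10.000  1.00  0.00           N",
        "HETATM    8  C   MSE A   2      17.400  12.400  10.000  1.00  0.00           C",
        "HETATM    9  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O",
        "HETATM   10 ZN    ZN A 102      25.000  25.000  25.000  1.00  0.00          ZN",
        "END",
    ]
    path = tmp_path / "het.pdb"
    path.write_text("\n".join(lines) + "\n")
    s = read_pdb(str(path))
    assert len(s.residues) == 2
    mse = s.get_residue("A", 2)
    assert mse.aa == "M"
    assert mse.atom("SD") is not None  # SE renamed, element S
    assert mse.atom("SD").element == "S"


def test_unreadable_coordinates_raise_with_line_number(tmp_path):
    lines = [
        "ATOM      1  N   ALA A   1      11.000  10.000  10.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1      12.4xx  10.000  10.000  1.00  0.00           C",
    ]
    path = tmp_path / "bad.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(PDBParseError, match="line 2"):
        read_pdb(str(path))


def test_file_without_atom_records_raises(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(PDBParseError):
        read_pdb(str(path))


class TestParseMutation:
    def test_valid_spec_resolves_against_structure(self, mini_helix):
        m = parse_mutation("A3G", "A", mini_helix)
        assert (m.chain_id, m.seq_num, m.icode, m.wt_aa, m.mut_aa) == ("A", 3, "", "A", "G")

    def test_wild_type_mismatch_reports_both_codes(self, mini_helix):
        with pytest.raises(MutationError, match="spec says G.*structure has A"):
            parse_mutation("G3A", "A", mini_helix)

    def test_nonstandard_mutant_code_rejected(self, mini_helix):
        with pytest.raises(MutationError, match="standard amino acid"):
            parse_mutation("A3B", "A", mini_helix)

    def test_missing_residue_rejected(self, mini_helix):
        with pytest.raises(MutationError, match="no residue"):
            parse_mutation("A99G", "A", mini_helix)


class TestEnumerateMutants:
    def test_exactly_19_distinct_sorted_mutants(self, mini_helix):
        muts = enumerate_mutants(mini_helix, "A", 3)
        codes = [m.mut_aa for m in muts]
        assert len(muts) == 19
        assert "A" not in codes
        assert codes == sorted(codes)
        assert set(codes) | {"A"} == set(STANDARD_AA)

    def test_missing_position_raises(self, mini_helix):
        with pytest.raises(MutationError):
            enumerate_mutants(mini_helix, "A", 42)


class TestMutantPlaceholder:
    def test_relabels_and_truncates_beyond_cb(self, mini_helix):
        m = parse_mutation("A3G", "A", mini_helix)
        mut = build_mutant_placeholder(mini_helix, m)
        res = mut.get_residue("A", 3)
        assert res.aa == "G"
        assert res.atom("CB") is None  # glycine has no CB
        # every other residue bit-identical
        for r_old, r_new in zip(mini_helix.residues, mut.residues):
            if r_old.seq_num == 3:
                continue
            for a_old, a_new in zip(r_old.atoms, r_new.atoms):
                np.testing.assert_array_equal(a_old.coord, a_new.coord)

    def test_identity_mutation_leaves_structure_unchanged(self, mini_helix):
        from protstab.structure_io import Mutation
        mut = build_mutant_placeholder(mini_helix, Mutation("A", 3, "", "A", "A"))
        assert mut.get_residue("A", 3).aa == "A"
        assert mut.n_atoms == mini_helix.n_atoms

    def test_large_sidechain_truncated_to_cb(self):
        from protstab import make_toy_structure
        from protstab.structure_io import Mutation
        s = make_toy_structure("helix", 6, "ALALAL", seed=0)
        mut = build_mutant_placeholder(s, Mutation("A", 2, "", "L", "F"))
        res = mut.get_residue("A", 2)
        assert {a.name for a in res.atoms} <= {"N", "CA", "C", "O", "CB"}
        assert res.aa == "F"
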