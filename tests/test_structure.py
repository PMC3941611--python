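"""Structure model: PDB parsing, radii/typing, topology, mutants, waters."""

import numpy as np
import pytest

from betacv import tables
from betacv.structure import (Atom, MutationRecord, Structure,
                              assign_radii_and_types, covalent_steps,
                              detect_bound_waters, infer_covalent_topology,
                              is_nearby, make_alanine_mutant, parse_pdb,
                              read_mutation_table, split_unbound, to_pdb)


def _pdb_line(serial, name, res, chain, resseq, x, y, z, element,
              record="ATOM", altloc=" "):
    return (f"{record:<6}{serial:>5} {name:^4}{altloc}{res:<3} {chain}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {element:>2}")


SMALL_PDB = "\n".join([
    _pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
    _pdb_line(2, "CA", "GLY", "A", 1, 1.45, 0.0, 0.0, "C"),
    _pdb_line(3, "C", "GLY", "A", 1, 2.0, 1.4, 0.0, "C"),
    _pdb_line(4, "O", "GLY", "A", 1, 1.3, 2.4, 0.0, "O"),
    _pdb_line(5, "N", "GLY", "B", 1, 0.0, 5.0, 0.0, "N"),
    _pdb_line(6, "CA", "GLY", "B", 1, 1.45, 5.0, 0.0, "C"),
    _pdb_line(7, "O", "HOH", "W", 1, 1.0, 2.5, 3.0, "O", record="HETATM"),
    "END",
]) + "\n"

ALTLOC_PDB = "\n".join([
    _pdb_line(1, "N", "SER", "A", 1, 0.0, 0.0, 0.0, "N"),
    _pdb_line(2, "CA", "SER", "A", 1, 1.45, 0.0, 0.0, "C", altloc="A"),
    _pdb_line(3, "CA", "SER", "A", 1, 1.55, 0.1, 0.0, "C", altloc="B"),
    _pdb_line(4, "N", "GLY", "B", 1, 0.0, 5.0, 0.0, "N"),
    "END",
]) + "\n"


class TestParsePdb:
    def test_toy_file_counts(self):
        s = parse_pdb(SMALL_PDB, ({"A"}, {"B"}))
        assert len(s.protein_atoms) == 6
        assert len(s.waters) == 1
        assert s.waters[0].name == "O"

    def test_altloc_keeps_first_conformer(self):
        s = parse_pdb(ALTLOC_PDB, ({"A"}, {"B"}))
        cas = [a for a in s.atoms if a.name == "CA"]
        assert len(cas) == 1
        assert np.isclose(cas[0].coords[0], 1.45)

    def test_missing_side_chain_errors(self):
        with pytest.raises(ValueError):
            parse_pdb(SMALL_PDB, ({"A"}, {"Z"}))
        with pytest.raises(ValueError, match="absent"):
            parse_pdb(SMALL_PDB, ({"A", "B"}, {"Z"}))

    def test_uncovered_chain_errors(self):
        with pytest.raises(ValueError):
            parse_pdb(SMALL_PDB, ({"A"}, set()))

    def test_file_order_is_preserved(self):
        s = parse_pdb(SMALL_PDB, ({"A"}, {"B"}))
        assert [a.name for a in s.atoms[:4]] == ["N", "CA", "C", "O"]


def test_roundtrip_through_pdb(toy):
    text = to_pdb(toy)
    back = parse_pdb(text, ({"A"}, {"B"}))
    assert len(back.atoms) == len(toy.atoms)
    assert [a.name for a in back.atoms] == [a.name for a in toy.atoms]
    # PDB coordinates carry three decimals
    np.testing.assert_allclose(back.coords(), toy.coords(), atol=5e-4)


class TestRadiiAndTypes:
    def test_ala_cb_is_aliphatic_carbon(self, toy):
        s = parse_pdb(SMALL_PDB, ({"A"}, {"B"}))
        s = assign_radii_and_types(s)
        water = s.waters[0]
        assert water.atom_type == tables.O_WATER
        assert tables.DEFAULT_ATOM_TYPES[("ALA", "CB")] == tables.C_SP3
        assert tables.DEFAULT_RADII[("ALA", "CB")] == pytest.approx(1.87)

    def test_unknown_residue_strict_raises(self):
        bad = SMALL_PDB.replace("GLY A", "MSE A")
        s = parse_pdb(bad, ({"A"}, {"B"}))
        with pytest.raises(KeyError):
            assign_radii_and_types(s, strict=True)

    def test_unknown_residue_lenient_skips(self):
        bad = SMALL_PDB.replace("GLY A", "MSE A")
        s = parse_pdb(bad, ({"A"}, {"B"}))
        with pytest.warns(UserWarning):
            s = assign_radii_and_types(s, strict=False)
        assert all(a.residue_name != "MSE" for a in s.atoms)

    def test_every_standard_heavy_atom_is_covered(self):
        for res, side in tables.SIDE_CHAIN_ATOMS.items():
            for name in tables.BACKBONE_ATOMS + side:
                assert (res, name) in tables.DEFAULT_RADII
                assert (res, name) in tables.DEFAULT_ATOM_TYPES
                assert tables.DEFAULT_RADII[(res, name)] > 0


class TestTopology:
    def test_single_ala_template(self):
        lines = [
            _pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
            _pdb_line(2, "CA", "ALA", "A", 1, 1.458, 0.0, 0.0, "C"),
            _pdb_line(3, "C", "ALA", "A", 1, 2.0, 1.42, 0.0, "C"),
            _pdb_line(4, "O", "ALA", "A", 1, 1.36, 2.45, 0.0, "O"),
            _pdb_line(5, "CB", "ALA", "A", 1, 2.0, -0.77, 1.2, "C"),
            _pdb_line(6, "N", "GLY", "B", 1, 0.0, 9.0, 0.0, "N"),
        ]
        s = parse_pdb("\n".join(lines) + "\nEND\n", ({"A"}, {"B"}))
        bonds = infer_covalent_topology(s)
        names = {frozenset((s.atom(i).name, s.atom(j).name))
                 for b in bonds for i, j in [tuple(b)]
                 if s.atom(i).chain == "A"}
        assert names == {frozenset(p) for p in
                         [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")]}

    def test_peptide_bond_distance_gate(self, toy):
        # consecutive residues in the toy chain are bonded; a 4 Å break is not
        bonds = toy.bonds
        by_res = {a.atom_id: a for a in toy.atoms}
        peptide = [b for b in bonds
                   if {by_res[i].name for i in b} == {"C", "N"}
                   and len({by_res[i].residue_id for i in b}) == 2]
        assert len(peptide) == 2 * (6 - 1)  # two chains of six residues

    def test_template_bond_counts_match_chemistry(self):
        # e.g. LYS: 4 backbone-ish bonds (N-CA, CA-C, C-O, CA-CB) + 4 side
        expected = {"GLY": 3, "ALA": 4, "SER": 5, "LEU": 7, "TRP": 15}
        for res, n in expected.items():
            template = [b for b in tables.residue_bond_template(res)
                        if "OXT" not in b]
            assert len(template) == n

    def test_no_water_bonds(self, toy_bound_water):
        wid = toy_bound_water.waters[0].atom_id
        assert all(wid not in b for b in toy_bound_water.bonds)


class TestCovalentSteps:
    BONDS = {frozenset(p) for p in [(0, 1), (1, 2), (2, 3), (3, 4)]}

    def test_chain_walk(self):
        # i-j-k-l-m: l is three steps from i (nearby), m is four (not)
        assert covalent_steps(self.BONDS, 0, 3) == 3
        assert covalent_steps(self.BONDS, 0, 4) == 4
        assert is_nearby(self.BONDS, 0, 3)
        assert not is_nearby(self.BONDS, 0, 4)

    def test_identity_and_disconnected(self):
        assert covalent_steps(self.BONDS, 2, 2) == 0
        assert covalent_steps(self.BONDS, 0, 99) == float("inf")


class TestAlanineMutant:
    def test_arg_truncation(self, toy):
        rid = ("A", 3, "")  # ARG
        before = [a for a in toy.atoms if a.residue_id == rid]
        assert len(before) == 11
        mut = make_alanine_mutant(toy, rid)
        after = [a for a in mut.atoms if a.residue_id == rid]
        assert sorted(a.name for a in after) == ["C", "CA", "CB", "N", "O"]

    def test_ser_truncation(self, toy):
        mut = make_alanine_mutant(toy, ("A", 2, ""))
        after = [a for a in mut.atoms if a.residue_id == ("A", 2, "")]
        assert "OG" not in {a.name for a in after}
        assert len(after) == 5

    def test_counts_match_template_for_every_residue(self, toy):
        for rid, atoms in toy.residues().items():
            rname = atoms[0].residue_name
            if rname in ("ALA", "GLY"):
                continue
            mut = make_alanine_mutant(toy, rid)
            removed = len(toy.atoms) - len(mut.atoms)
            expected = sum(1 for n in tables.SIDE_CHAIN_ATOMS[rname]
                           if n not in tables.ALANINE_SCAFFOLD)
            assert removed == expected

    def test_gly_and_ala_rejected(self):
        lines = [
            _pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
            _pdb_line(2, "CA", "GLY", "A", 1, 1.45, 0.0, 0.0, "C"),
            _pdb_line(3, "N", "ALA", "B", 1, 0.0, 9.0, 0.0, "N"),
            _pdb_line(4, "CB", "ALA", "B", 1, 1.4, 9.0, 0.0, "C"),
        ]
        s = parse_pdb("\n".join(lines) + "\nEND\n", ({"A"}, {"B"}))
        with pytest.raises(ValueError, match="GLY"):
            make_alanine_mutant(s, ("A", 1, ""))
        with pytest.raises(ValueError, match="ALA"):
            make_alanine_mutant(s, ("B", 1, ""))

    def test_remaining_coordinates_untouched(self, toy):
        mut = make_alanine_mutant(toy, ("A", 3, ""))
        for a in mut.atoms:
            np.testing.assert_array_equal(a.coords, toy.atom(a.atom_id).coords)


class TestSplitUnbound:
    def test_partition_and_rigidity(self, toy_bound_water):
        s = toy_bound_water
        a, b = split_unbound(s)
        assert len(a.atoms) + len(b.atoms) == len(s.protein_atoms)
        assert not a.waters and not b.waters
        for part in (a, b):
            for at in part.atoms:
                np.testing.assert_array_equal(at.coords,
                                              s.atom(at.atom_id).coords)


def _water_scene(protein_specs):
    """Water at the origin plus protein atoms at given (element, distance)."""
    atoms = [Atom(atom_id=0, name="O", element="O", residue_name="HOH",
                  residue_id=("W", 1, ""), coords=np.zeros(3), is_water=True)]
    directions = np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [0.7, 0.7, 0], [0.7, -0.7, 0],
    ], dtype=float)
    for k, (element, dist) in enumerate(protein_specs):
        d = directions[k] / np.linalg.norm(directions[k])
        name = {"N": "N", "O": "O", "C": "CA"}[element]
        atoms.append(Atom(
            atom_id=k + 1, name=name, element=element, residue_name="GLY",
            residue_id=("A", k + 1, ""), coords=dist * d))
    return Structure(atoms=atoms, sides=(frozenset("A"), frozenset("B")))


class TestBoundWaters:
    def test_three_hbonds_bound(self):
        s = _water_scene([("N", 2.9), ("O", 2.9), ("N", 2.9)])
        assert detect_bound_waters(s) == {0}

    def test_two_hbonds_two_others_bound(self):
        s = _water_scene([("N", 3.0), ("O", 3.0), ("C", 3.8), ("C", 3.8)])
        assert detect_bound_waters(s) == {0}

    def test_two_hbonds_one_other_not_bound(self):
        s = _water_scene([("N", 3.0), ("O", 3.0), ("C", 3.8)])
        assert detect_bound_waters(s) == set()

    def test_hbond_needs_n_or_o(self):
        s = _water_scene([("C", 2.9), ("C", 2.9), ("C", 2.9), ("C", 3.8)])
        assert detect_bound_waters(s) == set()

    def test_adding_close_polar_atom_never_unbinds(self):
        base = [("N", 3.0), ("O", 3.0), ("C", 3.8), ("C", 3.8)]
        assert detect_bound_waters(_water_scene(base)) == {0}
        assert detect_bound_waters(_water_scene(base + [("N", 3.0)])) == {0}
        assert detect_bound_waters(_water_scene(base + [("O", 2.5)])) == {0}

    def test_water_water_contacts_ignored(self, toy_free_water):
        assert detect_bound_waters(toy_free_water) == set()


class TestMutationRecords:
    def test_hotspot_flag_follows_threshold(self):
        assert MutationRecord(("A", 1, ""), "TYR", 2.0).is_hotspot
        assert not MutationRecord(("A", 1, ""), "TYR", 1.99).is_hotspot

    def test_ala_gly_wild_types_rejected(self):
        with pytest.raises(ValueError):
            MutationRecord(("A", 1, ""), "ALA", 1.0)
        with pytest.raises(ValueError):
            MutationRecord(("A", 1, ""), "GLY", 1.0)

    def test_read_mutation_table(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text("chain\tresnum\twt_res\tddg_exp\n"
                        "A\t6\tTYR\t3.1\nB\t5\targ\t1.0\n")
        recs = read_mutation_table(path)
        assert [r.residue_id for r in recs] == [("A", 6, ""), ("B", 5, "")]
        assert recs[1].wild_type == "ARG"
        assert recs[0].is_hotspot and not recs[1].is_hotspot

    def test_read_mutation_table_missing_column(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text("chain\tresnum\tddg_exp\nA\t6\t3.1\n")
        with pytest.raises(ValueError, match="wt_res"):
            read_mutation_table(path)
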