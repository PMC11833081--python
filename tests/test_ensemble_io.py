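"""Multi-model PDB round trips, parsing rules and atom selection."""

from __future__ import annotations

import numpy as np
import pytest

from loopscape.ensemble_io import (
    parse_residue_spec,
    parse_selection_config,
    read_multimodel_pdb,
    select_atoms,
    write_multimodel_pdb,
)
from loopscape.errors import FormatError, InputError, SelectionError
from loopscape.synthetic import SyntheticSpec, generate_two_state_enzyme

from conftest import make_ensemble

THREE_MODEL_PDB = """\
MODEL        1
ATOM      1  N1  ALA E   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  C1  ALA E   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  O1  ALA E   2       3.000   0.000   0.000  1.00  0.00           O
TER
ENDMDL
MODEL        2
ATOM      1  N1  ALA E   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  C1  ALA E   1       1.500   1.000   0.000  1.00  0.00           C
ATOM      3  O1  ALA E   2       3.000   1.000   0.000  1.00  0.00           O
TER
ENDMDL
MODEL        3
ATOM      1  N1  ALA E   1       0.000   2.000   0.000  1.00  0.00           N
ATOM      2  C1  ALA E   1       1.500   2.000   0.000  1.00  0.00           C
ATOM      3  O1  ALA E   2       3.000   2.000   0.000  1.00  0.00           O
TER
ENDMDL
END
"""


@pytest.fixture()
def three_model_path(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_MODEL_PDB)
    return path


class TestRead:
    def test_model_count_and_frame_ids(self, three_model_path):
        ens = read_multimodel_pdb(three_model_path)
        assert ens.n_frames == 3
        assert ens.topology.n_atoms == 3
        assert list(ens.frame_ids) == [1, 2, 3]

    def test_implicit_single_model(self, tmp_path):
        lines = [
            line
            for line in THREE_MODEL_PDB.splitlines()[1:5]  # first model body
        ]
        path = tmp_path / "single.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        ens = read_multimodel_pdb(path)
        assert ens.n_frames == 1
        assert list(ens.frame_ids) == [1]

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            read_multimodel_pdb(tmp_path / "absent.pdb")

    def test_differing_atom_counts_name_the_model(self, three_model_path):
        text = three_model_path.read_text().splitlines()
        del text[8]  # drop one atom of MODEL 2
        bad = three_model_path.with_name("bad.pdb")
        bad.write_text("\n".join(text) + "\n")
        with pytest.raises(FormatError, match="MODEL 2"):
            read_multimodel_pdb(bad)

    def test_unknown_element_rejected(self, tmp_path):
        path = tmp_path / "xx.pdb"
        path.write_text(
            "ATOM      1 XX   ALA E   1       0.000   0.000   0.000"
            "  1.00  0.00          XX\nEND\n"
        )
        with pytest.raises(FormatError, match="element"):
            read_multimodel_pdb(path)

    def test_insertion_code_rejected(self, tmp_path):
        path = tmp_path / "icode.pdb"
        path.write_text(
            "ATOM      1  C1  ALA E   1A      0.000   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        with pytest.raises(FormatError, match="insertion"):
            read_multimodel_pdb(path)

    def test_secondary_altloc_dropped(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  C1 AALA E   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      2  C1 BALA E   1       0.500   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        ens = read_multimodel_pdb(path)
        assert ens.topology.n_atoms == 1

    def test_element_falls_back_to_atom_name(self, tmp_path):
        path = tmp_path / "noelem.pdb"
        path.write_text(
            "ATOM      1  CA  ALA E   1       0.000   0.000   0.000"
            "  1.00  0.00\n"
            "ATOM      2 1HB  ALA E   1       1.000   0.000   0.000"
            "  1.00  0.00\nEND\n"
        )
        ens = read_multimodel_pdb(path)
        assert [a.element for a in ens.topology.atoms] == ["C", "H"]
        assert [a.is_heavy for a in ens.topology.atoms] == [True, False]


class TestRoundTrip:
    def test_write_then_read_preserves_everything(self, tmp_path):
        ensemble, _ = generate_two_state_enzyme(
            SyntheticSpec(n_frames=3, seed=5)
        )
        path = tmp_path / "rt.pdb"
        write_multimodel_pdb(ensemble, [0, 1, 2], path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == 3
        assert back.topology.n_atoms == ensemble.topology.n_atoms
        for a, b in zip(ensemble.topology.atoms, back.topology.atoms):
            assert (a.chain_id, a.residue_number, a.element) == (
                b.chain_id,
                b.residue_number,
                b.element,
            )
        np.testing.assert_allclose(
            back.coordinates, ensemble.coordinates, atol=5e-4
        )

    def test_subset_writes_requested_model_count(self, tmp_path, three_model_path):
        ens = read_multimodel_pdb(three_model_path)
        out = tmp_path / "two.pdb"
        write_multimodel_pdb(ens, [0, 2], out)
        assert out.read_text().count("MODEL ") == 2
        assert list(read_multimodel_pdb(out).frame_ids) == [1, 3]

    def test_empty_subset_rejected(self, three_model_path, tmp_path):
        ens = read_multimodel_pdb(three_model_path)
        with pytest.raises(InputError):
            write_multimodel_pdb(ens, [], tmp_path / "never.pdb")

    def test_mdanalysis_reads_our_output_identically(self, tmp_path):
        mda = pytest.importorskip("MDAnalysis")
        ensemble, _ = generate_two_state_enzyme(SyntheticSpec(n_frames=2, seed=3))
        path = tmp_path / "mda.pdb"
        write_multimodel_pdb(ensemble, [0, 1], path)
        universe = mda.Universe(str(path))
        assert len(universe.atoms) == ensemble.topology.n_atoms
        got = np.array([universe.atoms.positions.copy() for _ in universe.trajectory])
        np.testing.assert_allclose(got, ensemble.coordinates, atol=5e-4)


class TestSelectAtoms:
    ATOMS = [
        ("E", 185, "C", "C1"),
        ("E", 185, "H", "H1"),
        ("E", 185, "H", "H2"),
        ("E", 186, "N", "N1"),
        ("E", 300, "O", "O1"),
        ("I", 185, "C", "C1"),
    ]

    def test_selects_only_requested_chain_and_residues(self):
        ens = make_ensemble(self.ATOMS, [np.zeros((6, 3))])
        sel = select_atoms(ens.topology, "E", {185, 186}, heavy_only=True)
        assert sel.atom_indices == (0, 3)

    def test_heavy_only_excludes_exactly_the_hydrogens(self):
        ens = make_ensemble(self.ATOMS, [np.zeros((6, 3))])
        heavy = select_atoms(ens.topology, "E", {185}, heavy_only=True)
        full = select_atoms(ens.topology, "E", {185}, heavy_only=False)
        assert len(full) - len(heavy) == 2

    def test_absent_residue_raises_selection_error(self):
        ens = make_ensemble(self.ATOMS, [np.zeros((6, 3))])
        with pytest.raises(SelectionError, match="999"):
            select_atoms(ens.topology, "E", {999})

    def test_order_independent_in_residue_input(self):
        ens = make_ensemble(self.ATOMS, [np.zeros((6, 3))])
        a = select_atoms(ens.topology, "E", [186, 185])
        b = select_atoms(ens.topology, "E", [185, 186])
        assert a.atom_indices == b.atom_indices

    def test_union_of_chain_selections_covers_topology(self):
        ens = make_ensemble(self.ATOMS, [np.zeros((6, 3))])
        union: set[int] = set()
        for chain in ens.topology.chain_ids:
            residues = {
                a.residue_number
                for a in ens.topology.atoms
                if a.chain_id == chain
            }
            union |= set(
                select_atoms(ens.topology, chain, residues, heavy_only=False).atom_indices
            )
        assert union == set(range(ens.topology.n_atoms))


class TestSelectionConfig:
    def test_residue_spec_parsing(self):
        assert parse_residue_spec("185-187") == {185, 186, 187}
        assert parse_residue_spec("108,278,298") == {108, 278, 298}
        assert parse_residue_spec("1-3,10") == {1, 2, 3, 10}

    def test_config_file_round_trip(self, tmp_path):
        cfg = tmp_path / "groups.cfg"
        cfg.write_text(
            "# loop / site groups\n"
            "group.loop = chain:E residues:185-200 heavy_only:true\n"
            "group.site = chain:E residues:108,278,298\n"
        )
        groups = parse_selection_config(cfg)
        assert groups["loop"]["residues"] == set(range(185, 201))
        assert groups["site"] == {
            "chain": "E",
            "residues": {108, 278, 298},
            "heavy_only": True,
        }

    def test_malformed_line_rejected(self, tmp_path):
        cfg = tmp_path / "bad.cfg"
        cfg.write_text("group.loop = residues:185-200\n")
        with pytest.raises(FormatError):
            parse_selection_config(cfg)
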