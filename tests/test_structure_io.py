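"""Structure parsing, residue classification and validation."""

import numpy as np
import pytest

from contactscales import (
    GeneratorConfig,
    ParseError,
    Structure,
    generate_structure,
    parse_pdb,
    side_chain_atoms,
    validate_structure,
    write_pdb,
)
from contactscales.structure_io import (
    BACKBONE_ATOMS,
    CHARGED,
    HYDROPHILIC,
    HYDROPHOBIC,
    RESIDUE_CLASS,
    SIDE_CHAIN_COMPOSITION,
)

from conftest import make_residue


def test_class_partition_covers_all_twenty_codes_once():
    """B/I/C classes partition the 20 amino acids with sizes 8/7/5."""
    assert len(HYDROPHOBIC) == 8
    assert len(HYDROPHILIC) == 7
    assert len(CHARGED) == 5
    union = HYDROPHOBIC | HYDROPHILIC | CHARGED
    assert len(union) == 20
    assert not (HYDROPHOBIC & HYDROPHILIC)
    assert not (HYDROPHOBIC & CHARGED)
    assert not (HYDROPHILIC & CHARGED)
    assert set(RESIDUE_CLASS) == union


@pytest.mark.parametrize("aa,atoms,expected", [
    # alanine: backbone excluded, CB remains
    ("A", {"N": (0, 0, 0), "CA": (1, 0, 0), "C": (2, 0, 0), "O": (3, 0, 0),
           "CB": (1, 1, 0)}, ["CB"]),
    # glycine: no side-chain heavy atom -> CA surrogate
    ("G", {"N": (0, 0, 0), "CA": (1, 0, 0), "C": (2, 0, 0), "O": (3, 0, 0)},
     ["CA"]),
])
def test_side_chain_extraction(aa, atoms, expected):
    res = make_residue(1, aa, atoms)
    sc = side_chain_atoms(res)
    want = np.array([atoms[n] for n in expected], dtype=float)
    assert np.allclose(sc, want)


def test_tryptophan_has_ten_side_chain_atoms():
    """The 14 heavy atoms of Trp minus the 4 backbone atoms leave 10."""
    names = ("N", "CA", "C", "O") + SIDE_CHAIN_COMPOSITION["W"]
    assert len(names) == 14
    res = make_residue(1, "W", {n: (i, 0.0, 0.0) for i, n in enumerate(names)})
    assert len(side_chain_atoms(res)) == 10


def test_write_parse_round_trip(tmp_path):
    """Writing a synthetic structure and reparsing reproduces it."""
    cfg = GeneratorConfig(n_residues=50, topology="helix_chain",
                          side_chain_mode="full", seed=7)
    s = generate_structure(cfg, path=tmp_path / "helix.pdb")
    back = parse_pdb(tmp_path / "helix.pdb")
    assert back.length == 50
    assert [r.seq_index for r in back.residues] == list(range(1, 51))
    assert back.sequence == s.sequence
    assert [r.res_class for r in back.residues] == [r.res_class for r in s.residues]
    for a, b in zip(s.residues, back.residues):
        assert a.atom_names == b.atom_names
        assert np.allclose(a.all_atoms, b.all_atoms, atol=1.5e-3)


def _pdb_atom(serial, name, resname, resseq, x, y, z, altloc=" ", occ=1.0,
              chain="A"):
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (f"ATOM  {serial:5d} {name_field}{altloc}{resname} {chain}{resseq:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           "
            f"{name.strip()[0]}\n")


def test_multi_model_files_use_first_model_only(tmp_path):
    lines = ["MODEL     1\n"]
    for i in (1, 2):
        lines.append(_pdb_atom(i, "CA", "ALA", i, float(i) * 4, 0.0, 0.0))
    lines += ["ENDMDL\n", "MODEL     2\n"]
    for i in (1, 2, 3):
        lines.append(_pdb_atom(10 + i, "CA", "GLY", i, float(i) * 4, 9.0, 0.0))
    lines += ["ENDMDL\n", "END\n"]
    path = tmp_path / "multi.pdb"
    path.write_text("".join(lines))
    s = parse_pdb(path)
    assert s.length == 2
    assert s.sequence == "AA"
    assert np.allclose(s.residues[0].all_atoms[0], [4.0, 0.0, 0.0])


def test_alternate_locations_keep_highest_occupancy(tmp_path):
    lines = [
        _pdb_atom(1, "CA", "ALA", 1, 0.0, 0.0, 0.0),
        _pdb_atom(2, "CB", "ALA", 1, 1.0, 0.0, 0.0, altloc="A", occ=0.4),
        _pdb_atom(3, "CB", "ALA", 1, 2.0, 0.0, 0.0, altloc="B", occ=0.6),
        _pdb_atom(4, "CA", "GLY", 2, 4.0, 0.0, 0.0),
        "END\n",
    ]
    path = tmp_path / "alt.pdb"
    path.write_text("".join(lines))
    s = parse_pdb(path)
    cb = s.residues[0].all_atoms[list(s.residues[0].atom_names).index("CB")]
    assert np.allclose(cb, [2.0, 0.0, 0.0])  # occupancy 0.6 wins


def test_numbering_gap_raises_naming_missing_residue(tmp_path):
    """A residue whose atoms were stripped leaves a gap; the parser names it."""
    lines = []
    serial = 1
    for i in (5, 6, 8, 9):  # residue 7 has no atoms
        lines.append(_pdb_atom(serial, "CA", "ALA", i, float(i) * 4, 0.0, 0.0))
        serial += 1
    lines.append("END\n")
    path = tmp_path / "gap.pdb"
    path.write_text("".join(lines))
    with pytest.raises(ParseError, match="7"):
        parse_pdb(path)
    # non-strict mode renumbers through the gap
    s = parse_pdb(path, strict=False)
    assert s.length == 4


def test_parse_errors(tmp_path):
    with pytest.raises(ParseError):
        parse_pdb(tmp_path / "nonexistent.pdb")
    path = tmp_path / "empty.pdb"
    path.write_text("HETATM    1  O   HOH A   1       0.000   0.000   0.000"
                    "  1.00  0.00           O\nEND\n")
    with pytest.raises(ParseError):
        parse_pdb(path)
    helix = tmp_path / "helix.pdb"
    generate_structure(GeneratorConfig(n_residues=30, topology="helix_chain",
                                       seed=0), path=helix)
    with pytest.raises(ParseError, match="chain"):
        parse_pdb(helix, chain="Z")


def test_validation_report_completeness(tmp_path):
    full = generate_structure(GeneratorConfig(n_residues=40,
                                              topology="compact_globule",
                                              side_chain_mode="full", seed=3))
    assert validate_structure(full).ok

    # drop one CB from a non-glycine residue
    residues = list(full.residues)
    for i, res in enumerate(residues):
        if res.aa_code != "G":
            keep = [j for j, n in enumerate(res.atom_names) if n != "CB"]
            residues[i] = make_residue(
                res.seq_index, res.aa_code,
                {res.atom_names[j]: tuple(res.all_atoms[j]) for j in keep},
            )
            break
    damaged = Structure(id="damaged", chain_id="A", residues=tuple(residues))
    report = validate_structure(damaged)
    assert len(report.incomplete) == 1
    assert "CB" in report.incomplete[0][2]
    assert not report.rejectable


def test_zero_atom_residue_marks_structure_rejectable():
    empty = make_residue(2, "A", {})
    ok = make_residue(1, "A", {"CA": (0, 0, 0), "CB": (1, 0, 0)})
    s = Structure(id="broken", chain_id="A", residues=(ok, empty))
    report = validate_structure(s)
    assert report.rejectable


def test_structure_requires_contiguous_numbering():
    r1 = make_residue(1, "A", {"CA": (0, 0, 0)})
    r3 = make_residue(3, "A", {"CA": (4, 0, 0)})
    with pytest.raises(ValueError):
        Structure(id="bad", chain_id="A", residues=(r1, r3))


def test_backbone_set_is_fixed():
    assert BACKBONE_ATOMS == {"N", "CA", "C", "O"}
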