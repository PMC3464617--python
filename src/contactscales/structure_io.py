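"""Parsing and validation of single-chain protein structures.

A :class:`Structure` is the ordered list of residues of one chain, each
residue carrying its heavy-atom coordinates split into backbone and
side-chain sets.  Residues are renumbered contiguously ``1..L`` so that the
sequence separation ``x = |i - j|`` used by the length-scale filters is
always well defined, regardless of author numbering or insertion codes.

The twenty standard amino acids are partitioned into three
physico-chemical classes used throughout the package:

* hydrophobic (``B``): F, M, W, I, V, L, P, A
* hydrophilic (``I``): N, C, Q, G, S, T, Y
* charged (``C``): R, D, E, H, K
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "HYDROPHOBIC",
    "HYDROPHILIC",
    "CHARGED",
    "RESIDUE_CLASS",
    "BACKBONE_ATOMS",
    "SIDE_CHAIN_COMPOSITION",
    "Residue",
    "Structure",
    "ValidationReport",
    "ParseError",
    "parse_pdb",
    "side_chain_atoms",
    "validate_structure",
    "write_pdb",
]

# ---------------------------------------------------------------------------
# Residue classification
# ---------------------------------------------------------------------------

HYDROPHOBIC = frozenset("FMWIVLPA")
HYDROPHILIC = frozenset("NCQGSTY")
CHARGED = frozenset("RDEHK")

#: one-letter code -> class label ("B" hydrophobic, "I" hydrophilic, "C" charged)
RESIDUE_CLASS: dict[str, str] = {}
for _aa in HYDROPHOBIC:
    RESIDUE_CLASS[_aa] = "B"
for _aa in HYDROPHILIC:
    RESIDUE_CLASS[_aa] = "I"
for _aa in CHARGED:
    RESIDUE_CLASS[_aa] = "C"

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: standard heavy side-chain atom names per amino acid (wwPDB nomenclature)
SIDE_CHAIN_COMPOSITION: dict[str, tuple[str, ...]] = {
    "A": ("CB",),
    "R": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "N": ("CB", "CG", "OD1", "ND2"),
    "D": ("CB", "CG", "OD1", "OD2"),
    "C": ("CB", "SG"),
    "Q": ("CB", "CG", "CD", "OE1", "NE2"),
    "E": ("CB", "CG", "CD", "OE1", "OE2"),
    "G": (),
    "H": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "I": ("CB", "CG1", "CG2", "CD1"),
    "L": ("CB", "CG", "CD1", "CD2"),
    "K": ("CB", "CG", "CD", "CE", "NZ"),
    "M": ("CB", "CG", "SD", "CE"),
    "F": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "P": ("CB", "CG", "CD"),
    "S": ("CB", "OG"),
    "T": ("CB", "OG1", "CG2"),
    "W": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "Y": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "V": ("CB", "CG1", "CG2"),
}

THREE_FROM_ONE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
ONE_FROM_THREE = {v: k for k, v in THREE_FROM_ONE.items()}


class ParseError(ValueError):
    """Raised when a PDB file cannot be turned into a usable chain model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Residue:
    """One residue of a chain with its heavy-atom coordinates.

    ``seq_index`` is the contiguous 1-based position after renumbering.
    ``side_chain_atoms`` excludes the backbone set {N, CA, C, O}; for
    glycine, which has no heavy side-chain atom, the CA coordinate is used
    as a side-chain surrogate so glycine can still form contacts.
    """

    seq_index: int
    aa_code: str
    atom_names: tuple[str, ...]
    all_atoms: np.ndarray  # (n_atoms, 3) in Angstrom

    def __post_init__(self) -> None:
        if self.aa_code not in RESIDUE_CLASS:
            raise ValueError(f"unknown amino-acid code {self.aa_code!r}")
        if len(self.atom_names) != len(self.all_atoms):
            raise ValueError("atom_names and all_atoms length mismatch")

    @property
    def res_class(self) -> str:
        return RESIDUE_CLASS[self.aa_code]

    @property
    def side_chain_atoms(self) -> np.ndarray:
        return side_chain_atoms(self)


def side_chain_atoms(res: Residue) -> np.ndarray:
    """Coordinates of the side-chain heavy atoms of ``res``.

    Backbone atoms (N, CA, C, O) are excluded.  Glycine falls back to its
    CA atom so that every residue exposes at least one interaction site.
    """
    mask = [name not in BACKBONE_ATOMS for name in res.atom_names]
    coords = res.all_atoms[np.asarray(mask, dtype=bool)]
    if len(coords) == 0:
        ca = [i for i, n in enumerate(res.atom_names) if n == "CA"]
        if not ca:
            return res.all_atoms[:0]
        coords = res.all_atoms[ca[:1]]
    return coords


@dataclass(frozen=True)
class Structure:
    """An ordered single protein chain."""

    id: str
    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a Structure needs at least 2 residues")
        for pos, res in enumerate(self.residues, start=1):
            if res.seq_index != pos:
                raise ValueError(
                    f"residues must be numbered contiguously 1..L; "
                    f"position {pos} has seq_index {res.seq_index}"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa_code for r in self.residues)

    def class_counts(self) -> dict[str, int]:
        """Number of hydrophobic/hydrophilic/charged residues (keys B/I/C)."""
        counts = {"B": 0, "I": 0, "C": 0}
        for res in self.residues:
            counts[res.res_class] += 1
        return counts


@dataclass
class ValidationReport:
    """Completeness report relative to standard heavy-atom composition."""

    structure_id: str
    incomplete: list[tuple[int, str, tuple[str, ...]]] = field(default_factory=list)
    rejectable: bool = False

    @property
    def ok(self) -> bool:
        return not self.incomplete and not self.rejectable


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _dedupe_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties to the first listed."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of first appearance
    order: list[str] = []
    for atom in res:
        if atom.name not in order:
            order.append(atom.name)
    return [best[name] for name in order]


def _one_letter(name: str) -> str | None:
    """Map a residue name to its parent one-letter code, or None."""
    if name in ONE_FROM_THREE:
        return ONE_FROM_THREE[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code in RESIDUE_CLASS:
            return code
    return None


def parse_pdb(path: str | os.PathLike, chain: str = "auto", strict: bool = True) -> Structure:
    """Read one protein chain from a PDB file.

    Only the first model is used; hydrogens, waters and non-mappable
    heteroatoms are dropped; of alternate locations the highest-occupancy
    one is kept.  Residues are renumbered contiguously ``1..L`` in file
    order.  With ``strict=True`` (default) a gap in the author residue
    numbering — the footprint of residues whose coordinates are missing —
    raises :class:`ParseError` naming the absent residues, mirroring the
    exclusion of incomplete structures from cohort work.
    """
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    st.remove_hydrogens()
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    model = st[0]

    gchain = None
    if chain in ("auto", None, ""):
        for cand in model:
            if any(_one_letter(r.name) is not None for r in cand):
                gchain = cand
                break
        if gchain is None:
            raise ParseError(f"{path}: no protein chain found")
    else:
        for cand in model:
            if cand.name == chain:
                gchain = cand
                break
        if gchain is None:
            raise ParseError(f"{path}: chain {chain!r} not found")

    residues: list[Residue] = []
    prev_num: int | None = None
    missing: list[int] = []
    for gres in gchain:
        code = _one_letter(gres.name)
        if code is None:
            continue  # water, ligand, unmappable non-standard residue
        num = gres.seqid.num
        if prev_num is not None and num > prev_num + 1:
            missing.extend(range(prev_num + 1, num))
        prev_num = num
        atoms = _dedupe_altlocs(gres)
        if not atoms:
            continue
        names = tuple(a.name for a in atoms)
        coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms], dtype=float)
        residues.append(
            Residue(
                seq_index=len(residues) + 1,
                aa_code=code,
                atom_names=names,
                all_atoms=coords,
            )
        )

    if strict and missing:
        shown = ", ".join(str(n) for n in missing[:10])
        raise ParseError(
            f"{path} chain {gchain.name}: missing residue(s) at author "
            f"position(s) {shown}{'...' if len(missing) > 10 else ''}"
        )
    if len(residues) < 2:
        raise ParseError(f"{path} chain {gchain.name}: fewer than 2 standard residues")

    struct_id = st.name.strip() or os.path.splitext(os.path.basename(str(path)))[0]
    return Structure(id=struct_id, chain_id=gchain.name, residues=tuple(residues))


# ---------------------------------------------------------------------------
# Validation and writing
# ---------------------------------------------------------------------------


def validate_structure(s: Structure) -> ValidationReport:
    """Report residues missing atoms relative to their standard composition.

    A structure containing a residue with no atoms at all is marked
    ``rejectable``; contact counts computed from it would be meaningless.
    """
    report = ValidationReport(structure_id=s.id)
    for res in s.residues:
        if len(res.all_atoms) == 0:
            report.rejectable = True
            report.incomplete.append((res.seq_index, res.aa_code, ("*",)))
            continue
        expected = set(BACKBONE_ATOMS) | set(SIDE_CHAIN_COMPOSITION[res.aa_code])
        absent = tuple(sorted(expected - set(res.atom_names)))
        if absent:
            report.incomplete.append((res.seq_index, res.aa_code, absent))
    return report


def write_pdb(s: Structure, path: str | os.PathLike) -> None:
    """Write a Structure as a minimal single-chain PDB file (ATOM records)."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chain = gemmi.Chain(s.chain_id or "A")
    for res in s.residues:
        gres = gemmi.Residue()
        gres.name = THREE_FROM_ONE[res.aa_code]
        gres.seqid = gemmi.SeqId(res.seq_index, " ")
        for name, xyz in zip(res.atom_names, res.all_atoms):
            atom = gemmi.Atom()
            atom.name = name
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = 0.0
            element = name[0] if name[0] in "NCOSH" else "C"
            atom.element = gemmi.Element(element)
            gres.add_atom(atom)
        chain.add_residue(gres)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)
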