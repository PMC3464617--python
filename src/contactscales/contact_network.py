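"""Interaction strengths and the residue contact map.

The strength of the van der Waals contact between residues *i* and *j* is
the percentage

    I_ij = n_ij / sqrt(N_i * N_j) * 100

where ``n_ij`` counts distinct pairs of *side-chain* atoms of the two
residues within the attractive London-van der Waals cutoff (5 A, closed
comparison), and ``N_i`` is a per-residue-type normalization factor:
the number of interaction pairs a residue of type *i* makes with all its
surrounding residues — *including* main-chain atoms — is evaluated for
every residue of the type in a protein, the per-protein maximum is taken,
and the maxima are averaged over the proteins of the reference set.  The
main-chain/side-chain asymmetry between the numerator and the
normalization is deliberate and matched to the published construction;
the geometric-mean denominator keeps strengths on the percent scale on
which the transition thresholds (I_min from 0 to 10%) operate.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import RESIDUE_CLASS, Residue, Structure, side_chain_atoms

__all__ = [
    "DEFAULT_CUTOFF",
    "NormalizationTable",
    "ContactMap",
    "count_contact_pairs",
    "compute_normalization",
    "interaction_strength",
    "build_contact_map",
]

#: upper cutoff for attractive London-van der Waals contacts, in Angstrom
DEFAULT_CUTOFF = 5.0

AA_CODES = tuple(sorted(RESIDUE_CLASS))


@dataclass(frozen=True)
class NormalizationTable:
    """Per-type normalization factors ``N_i`` with their provenance label."""

    values: dict[str, float]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        missing = [aa for aa in AA_CODES if aa not in self.values]
        if missing:
            raise ValueError(f"normalization table missing residue types: {missing}")
        bad = [aa for aa, v in self.values.items() if not v > 0]
        if bad:
            raise ValueError(f"normalization factors must be positive; bad: {bad}")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def scaled(self, c: float) -> "NormalizationTable":
        return NormalizationTable(
            {aa: v * c for aa, v in self.values.items()},
            provenance=f"{self.provenance} (scaled x{c:g})",
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# normalization factors; provenance: {self.provenance}\n")
            for aa in AA_CODES:
                fh.write(f"{aa}\t{self.values[aa]:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "NormalizationTable":
        values: dict[str, float] = {}
        provenance = os.path.basename(str(path))
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "provenance:" in line:
                        provenance = line.split("provenance:", 1)[1].strip()
                    continue
                aa, val = line.split("\t")
                values[aa] = float(val)
        return cls(values, provenance=provenance)


@dataclass(frozen=True)
class ContactMap:
    """All pairwise interaction data of one chain.

    ``strength[i, j]`` is I_ij in percent, ``raw_pairs[i, j]`` the integer
    side-chain atom-pair count n_ij, and ``sep[i, j] = |i - j|`` the
    sequence separation.  Matrices are 0-indexed by ``seq_index - 1``.
    """

    structure_id: str
    aa_codes: tuple[str, ...]
    strength: np.ndarray
    raw_pairs: np.ndarray
    cutoff: float = DEFAULT_CUTOFF
    norm_provenance: str = "unspecified"

    def __post_init__(self) -> None:
        L = len(self.aa_codes)
        for name in ("strength", "raw_pairs"):
            m = getattr(self, name)
            if m.shape != (L, L):
                raise ValueError(f"{name} must be {L}x{L}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if np.any(np.diag(self.strength) != 0):
            raise ValueError("strength diagonal must be zero")
        if np.any(self.raw_pairs < 0):
            raise ValueError("raw_pairs must be non-negative")

    @property
    def L(self) -> int:
        return len(self.aa_codes)

    @property
    def sep(self) -> np.ndarray:
        idx = np.arange(self.L)
        return np.abs(idx[:, None] - idx[None, :])

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(RESIDUE_CLASS[aa] for aa in self.aa_codes)

    def to_edge_tsv(self, path: str | os.PathLike) -> None:
        """Write contacts as a 4-column edge list (i, j, n_ij, I_ij)."""
        with open(path, "w") as fh:
            fh.write(f"# {self.structure_id}; cutoff {self.cutoff} A; "
                     f"normalization: {self.norm_provenance}\n")
            fh.write("i\tj\tn_ij\tI_ij\n")
            ii, jj = np.nonzero(np.triu(self.raw_pairs, k=1))
            for i, j in zip(ii, jj):
                fh.write(f"{i + 1}\t{j + 1}\t{int(self.raw_pairs[i, j])}\t"
                         f"{self.strength[i, j]:.6g}\n")

    def to_matrix_csv(self, path: str | os.PathLike) -> None:
        np.savetxt(path, self.strength, delimiter=",", fmt="%.6g")


# ---------------------------------------------------------------------------
# Pair counting
# ---------------------------------------------------------------------------


def count_contact_pairs(res_i: Residue, res_j: Residue,
                        cutoff: float = DEFAULT_CUTOFF) -> int:
    """Number of side-chain atom pairs of two residues within ``cutoff``."""
    if res_i is res_j or res_i.seq_index == res_j.seq_index:
        raise ValueError("count_contact_pairs needs two distinct residues")
    a = side_chain_atoms(res_i)
    b = side_chain_atoms(res_j)
    if len(a) == 0 or len(b) == 0:
        return 0
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return int(np.count_nonzero(d2 <= cutoff * cutoff))


def interaction_strength(n_ij: int, n_i: float, n_j: float) -> float:
    """Percent interaction strength ``n_ij / sqrt(N_i * N_j) * 100``."""
    if n_ij < 0:
        raise ValueError("n_ij must be non-negative")
    if not (n_i > 0 and n_j > 0):
        raise ValueError("normalization factors must be positive")
    return n_ij / math.sqrt(n_i * n_j) * 100.0


# ---------------------------------------------------------------------------
# Normalization factors
# ---------------------------------------------------------------------------


def _all_atom_pair_counts(s: Structure, cutoff: float) -> np.ndarray:
    """Per-residue count of all-atom interaction pairs with other residues.

    All heavy atoms (main-chain plus side-chain) of a residue are counted
    against the atoms of every other residue of the chain under the 5 A
    rule; this is the quantity whose per-protein, per-type maximum enters
    the normalization factors.
    """
    coords = np.concatenate([r.all_atoms for r in s.residues])
    owner = np.concatenate(
        [np.full(len(r.all_atoms), r.seq_index - 1) for r in s.residues]
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    counts = np.zeros(s.length, dtype=int)
    if len(pairs):
        oa, ob = owner[pairs[:, 0]], owner[pairs[:, 1]]
        inter = oa != ob
        np.add.at(counts, oa[inter], 1)
        np.add.at(counts, ob[inter], 1)
    return counts


def compute_normalization(structures: Sequence[Structure],
                          cutoff: float = DEFAULT_CUTOFF,
                          provenance: str | None = None) -> NormalizationTable:
    """Normalization factors from a reference structure set.

    For each amino-acid type, every protein containing it contributes the
    maximum all-atom interaction-pair count achieved by a residue of that
    type; the factor is the arithmetic mean of these per-protein maxima.
    A type absent from every structure is an error: its factor would be
    undefined and downstream strengths could not be computed.
    """
    if not structures:
        raise ValueError("need at least one structure")
    maxima: dict[str, list[int]] = {aa: [] for aa in AA_CODES}
    for s in structures:
        counts = _all_atom_pair_counts(s, cutoff)
        per_type: dict[str, int] = {}
        for res, c in zip(s.residues, counts):
            if c > per_type.get(res.aa_code, -1):
                per_type[res.aa_code] = int(c)
        for aa, m in per_type.items():
            maxima[aa].append(m)
    absent = [aa for aa, v in maxima.items() if not v]
    if absent:
        raise ValueError(
            f"amino-acid type(s) {absent} absent from every reference structure"
        )
    values = {aa: float(np.mean(v)) for aa, v in maxima.items()}
    # a residue type may occur only in positions with zero contacts
    for aa, v in values.items():
        if v <= 0:
            values[aa] = 1.0
    label = provenance or f"computed from {len(structures)} structure(s)"
    return NormalizationTable(values, provenance=label)


# ---------------------------------------------------------------------------
# Contact map
# ---------------------------------------------------------------------------


def build_contact_map(s: Structure, table: NormalizationTable,
                      cutoff: float = DEFAULT_CUTOFF) -> ContactMap:
    """Evaluate n_ij and I_ij for every residue pair of a chain."""
    for res in s.residues:
        if res.aa_code not in table.values:
            raise ValueError(f"residue type {res.aa_code} missing from table")
    L = s.length
    sc = [side_chain_atoms(r) for r in s.residues]
    coords = np.concatenate(sc)
    owner = np.concatenate(
        [np.full(len(c), i) for i, c in enumerate(sc)]
    )
    n = np.zeros((L, L), dtype=int)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        oa, ob = owner[pairs[:, 0]], owner[pairs[:, 1]]
        inter = oa != ob
        np.add.at(n, (oa[inter], ob[inter]), 1)
        np.add.at(n, (ob[inter], oa[inter]), 1)
    factors = np.array([table[r.aa_code] for r in s.residues])
    strength = n / np.sqrt(factors[:, None] * factors[None, :]) * 100.0
    np.fill_diagonal(strength, 0.0)
    return ContactMap(
        structure_id=s.id,
        aa_codes=tuple(r.aa_code for r in s.residues),
        strength=strength,
        raw_pairs=n,
        cutoff=cutoff,
        norm_provenance=table.provenance,
    )
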