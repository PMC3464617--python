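"""Shared fixtures: hand-built residues and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from contactscales import (
    GeneratorConfig,
    Residue,
    Structure,
    build_contact_map,
    compute_normalization,
    generate_structure,
)


def make_residue(seq_index: int, aa: str, atoms: dict[str, tuple]) -> Residue:
    """Build a residue from a name -> (x, y, z) mapping."""
    names = tuple(atoms)
    coords = np.array([atoms[n] for n in names], dtype=float)
    return Residue(seq_index=seq_index, aa_code=aa, atom_names=names,
                   all_atoms=coords)


def single_atom_residue(seq_index: int, aa: str, xyz: tuple) -> Residue:
    """Residue whose only side-chain atom (CB) sits at ``xyz``; CA far away."""
    x, y, z = xyz
    return make_residue(seq_index, aa, {
        # backbone parked out of everything's contact range (staggered)
        "CA": (x, y, z + 100.0 + 7.0 * seq_index),
        "CB": (x, y, z),
    })


@pytest.fixture(scope="session")
def helix_cohort() -> list[Structure]:
    return [
        generate_structure(GeneratorConfig(n_residues=80, topology="helix_chain",
                                           seed=s))
        for s in range(6)
    ]


@pytest.fixture(scope="session")
def globule_cohort() -> list[Structure]:
    return [
        generate_structure(GeneratorConfig(n_residues=100,
                                           topology="compact_globule", seed=100 + s))
        for s in range(6)
    ]


@pytest.fixture(scope="session")
def blob_globule_cohort() -> list[Structure]:
    return [
        generate_structure(GeneratorConfig(n_residues=100,
                                           topology="compact_globule",
                                           side_chain_mode="blob", seed=200 + s))
        for s in range(6)
    ]


@pytest.fixture(scope="session")
def mixed_table(helix_cohort, globule_cohort):
    return compute_normalization(helix_cohort + globule_cohort)


@pytest.fixture(scope="session")
def globule_maps(globule_cohort, mixed_table):
    return [build_contact_map(s, mixed_table) for s in globule_cohort]
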