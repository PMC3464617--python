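"""Synthetic PDB structures and abstract graph fixtures.

Two contrasting chain geometries cover the regimes the analyses care
about:

* ``helix_chain`` — residues along a gently waving extended chain whose
  side chains touch only their sequence neighbours.  The contact graph is
  chain-like and entirely short-range, the regime where the largest
  component collapses sharply (cooperatively) once the threshold crosses
  the narrow band of contact strengths.
* ``compact_globule`` — the chain is folded onto a jittered space-filling
  (boustrophedon) lattice walk inside a cube, so residues far apart in
  sequence pack against each other and a large share of contacts are
  long-range.  Contact strengths are heterogeneous and the collapse of
  the largest component is gradual.
* ``planted_cliques`` — a compact globule in which chosen residue triples
  are given prescribed classes and mutually touching side chains, placing
  known 3-cliques for recovery tests.

By default every residue carries one pseudo side-chain atom, so the pair
count ``n_ij`` between two residues is 0 or 1 and all downstream numbers
are hand-checkable.  ``side_chain_mode="blob"`` gives every residue three
tightly clustered pseudo atoms — pair counts then vary with packing
geometry while staying independent of residue identity, which is the mode
used for transition studies on globules.  ``side_chain_mode="full"`` lays
out the standard heavy side-chain atom set of each amino acid as a short
outward chain; it exercises the normalization-factor machinery on
realistically sized residues and passes structure validation.

All randomness flows from the config seed; a fixed config reproduces the
identical structure (and identical PDB bytes) on every run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .structure_io import (
    CHARGED,
    HYDROPHILIC,
    HYDROPHOBIC,
    SIDE_CHAIN_COMPOSITION,
    Residue,
    Structure,
    write_pdb,
)
from .subnetworks import NetworkSpec, ResidueGraph

__all__ = [
    "GeneratorConfig",
    "generate_structure",
    "generate_graph_fixture",
]

TOPOLOGIES = ("helix_chain", "compact_globule", "planted_cliques")

_CODES_OF_CLASS = {
    "B": tuple(sorted(HYDROPHOBIC)),
    "I": tuple(sorted(HYDROPHILIC)),
    "C": tuple(sorted(CHARGED)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic structure.

    ``class_fractions`` are the expected shares of hydrophobic,
    hydrophilic and charged residues (default 0.45/0.33/0.22, roughly the
    composition of globular proteins).  ``contact_density`` is the target
    number of side-chain contacts per residue for the globule topologies;
    it controls the packing tightness of the lattice walk.
    """

    n_residues: int = 100
    class_fractions: tuple[float, float, float] = (0.45, 0.33, 0.22)
    topology: str = "compact_globule"
    contact_density: float | None = None  # default: 2.0 helix, 5.0 globule
    seed: int = 0
    side_chain_mode: str = "single"  # "single" or "full"
    n_planted: int = 5
    planted_type: str = "CCC"

    def __post_init__(self) -> None:
        if self.n_residues < 30:
            raise ValueError("n_residues must be >= 30 (subcluster threshold)")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}")
        f = self.class_fractions
        if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("class_fractions must be 3 non-negative shares summing to 1")
        if self.side_chain_mode not in ("single", "blob", "full"):
            raise ValueError("side_chain_mode must be 'single', 'blob' or 'full'")
        lo, hi = (0.5, 2.5) if self.topology == "helix_chain" else (1.0, 9.0)
        if self.contact_density is None:
            object.__setattr__(self, "contact_density",
                               2.0 if self.topology == "helix_chain" else 5.0)
        if not (lo <= self.contact_density <= hi):
            raise ValueError(
                f"contact_density {self.contact_density} infeasible for "
                f"{self.topology}: geometric capacity is [{lo}, {hi}]"
            )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _sample_sequence(cfg: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    classes = rng.choice(["B", "I", "C"], size=cfg.n_residues,
                         p=list(cfg.class_fractions))
    return [
        _CODES_OF_CLASS[c][rng.integers(len(_CODES_OF_CLASS[c]))]
        for c in classes
    ]


def _chain_ca(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Extended, gently waving chain; CA spacing 3.8 A."""
    i = np.arange(cfg.n_residues, dtype=float)
    ca = np.stack([3.8 * i, 1.2 * np.sin(0.6 * i), 1.2 * np.cos(0.6 * i)], axis=1)
    ca += rng.normal(0.0, 0.08, size=ca.shape)
    return ca


def _snake_lattice(n: int) -> np.ndarray:
    """Self-avoiding boustrophedon walk through a near-cubic lattice."""
    side = math.ceil(n ** (1.0 / 3.0))
    coords = []
    for z in range(side):
        ys = range(side) if z % 2 == 0 else range(side - 1, -1, -1)
        for yi, y in enumerate(ys):
            fwd = (z + yi) % 2 == 0
            xs = range(side) if fwd else range(side - 1, -1, -1)
            for x in xs:
                coords.append((x, y, z))
                if len(coords) == n:
                    return np.array(coords, dtype=float)
    return np.array(coords[:n], dtype=float)


def _globule_spacing(density: float) -> float:
    """Lattice spacing (A) realizing roughly the requested contact density."""
    # calibrated once on generated globules: tighter lattice -> more and
    # stronger side-chain contacts; clipped to keep the walk self-avoiding
    return float(np.clip(6.05 - 0.33 * density, 3.4, 5.8))


def _globule_ca(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    ca = _snake_lattice(cfg.n_residues) * _globule_spacing(cfg.contact_density)
    ca += rng.normal(0.0, 0.25, size=ca.shape)
    return ca


def _backbone(ca: np.ndarray, rng: np.random.Generator) -> list[dict[str, np.ndarray]]:
    """N, CA, C, O positions per residue, oriented along the local chain."""
    n = len(ca)
    out = []
    for i in range(n):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[i + 1] - ca[i])
        next_ca = ca[i + 1] if i < n - 1 else ca[i] + (ca[i] - ca[i - 1])
        u = next_ca - prev_ca
        norm = np.linalg.norm(u)
        u = u / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        perp = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        out.append({
            "N": ca[i] - 1.2 * u + 0.35 * perp,
            "CA": ca[i].copy(),
            "C": ca[i] + 1.2 * u + 0.35 * perp,
            "O": ca[i] + 1.4 * u - 0.75 * perp,
        })
    return out


def _side_chain_direction(ca: np.ndarray, i: int, centroid: np.ndarray,
                          topology: str, rng: np.random.Generator) -> np.ndarray:
    if topology == "helix_chain":
        d = np.array([0.0, 1.0, 0.25]) + rng.normal(0.0, 0.05, 3)
        return d / np.linalg.norm(d)
    # globule: side chains point perpendicular to the local chain direction,
    # cycling around it so consecutive side chains diverge and contacts are
    # made across the fold (long-range) rather than along the chain
    nres = len(ca)
    prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[i + 1] - ca[i])
    next_ca = ca[i + 1] if i < nres - 1 else ca[i] + (ca[i] - ca[i - 1])
    u = next_ca - prev_ca
    norm = np.linalg.norm(u)
    u = u / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, [0.0, 1.0, 0.0])
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    d = (v, w, -v, -w)[i % 4] + rng.normal(0.0, 0.35, 3)
    return d / np.linalg.norm(d)


def _side_chain_atoms(aa: str, ca_pos: np.ndarray, direction: np.ndarray,
                      mode: str, rng: np.random.Generator
                      ) -> tuple[tuple[str, ...], np.ndarray]:
    if mode == "single":
        if aa == "G":
            return (), np.zeros((0, 3))
        pos = ca_pos + 1.9 * direction + rng.normal(0.0, 0.12, 3)
        return ("CB",), pos[None, :]
    if mode == "blob":
        # two pseudo atoms in a loose cluster, identical for every type:
        # contact-pair counts then reflect packing geometry, not residue size
        center = ca_pos + 2.2 * direction
        coords = center[None, :] + rng.normal(0.0, 0.8, (2, 3))
        return ("CB", "CG"), coords
    names = SIDE_CHAIN_COMPOSITION[aa]
    if not names:
        return (), np.zeros((0, 3))
    coords = []
    for k in range(len(names)):
        coords.append(
            ca_pos + (1.5 + 0.8 * k) * direction + rng.normal(0.0, 0.25, 3)
        )
    return names, np.array(coords)


def _build_residues(codes: Sequence[str], ca: np.ndarray, topology: str,
                    mode: str, rng: np.random.Generator) -> list[Residue]:
    centroid = ca.mean(axis=0)
    backbone = _backbone(ca, rng)
    residues = []
    for i, aa in enumerate(codes):
        d = _side_chain_direction(ca, i, centroid, topology, rng)
        sc_names, sc_coords = _side_chain_atoms(aa, ca[i], d, mode, rng)
        names = ("N", "CA", "C", "O") + sc_names
        coords = np.vstack([
            backbone[i]["N"], backbone[i]["CA"], backbone[i]["C"],
            backbone[i]["O"],
        ] + ([sc_coords] if len(sc_coords) else []))
        residues.append(Residue(seq_index=i + 1, aa_code=aa,
                                atom_names=names, all_atoms=coords))
    return residues


def _plant_cliques(residues: list[Residue], cfg: GeneratorConfig,
                   rng: np.random.Generator) -> list[Residue]:
    """Give chosen triples prescribed classes and mutually touching side chains."""
    n = len(residues)
    ca = np.array([r.all_atoms[list(r.atom_names).index("CA")] for r in residues])
    used: set[int] = set()
    letters = tuple(cfg.planted_type)
    for _ in range(cfg.n_planted):
        candidates = [i for i in range(n) if i not in used]
        if len(candidates) < 3:
            break
        anchor = int(rng.choice(candidates))
        others = [i for i in candidates if i != anchor and abs(i - anchor) > 2]
        if len(others) < 2:
            break
        others.sort(key=lambda j: float(np.linalg.norm(ca[j] - ca[anchor])))
        triple = sorted([anchor, others[0], others[1]])
        used.update(triple)
        center = ca[triple].mean(axis=0)
        offsets = np.array([[1.0, 0.0, 0.0], [-0.5, 0.87, 0.0], [-0.5, -0.87, 0.0]])
        for member, letter, off in zip(triple, letters, offsets):
            old = residues[member]
            code = _CODES_OF_CLASS[letter][rng.integers(len(_CODES_OF_CLASS[letter]))]
            sc_pos = center + 0.9 * off
            bb_names = old.atom_names[:4]
            bb_coords = old.all_atoms[:4]
            residues[member] = Residue(
                seq_index=old.seq_index,
                aa_code=code,
                atom_names=bb_names + ("CB",),
                all_atoms=np.vstack([bb_coords, sc_pos[None, :]]),
            )
    return residues


def generate_structure(cfg: GeneratorConfig, path=None) -> Structure:
    """Generate a synthetic structure; optionally write it as a PDB file."""
    rng = np.random.default_rng(cfg.seed)
    codes = _sample_sequence(cfg, rng)
    if cfg.topology == "helix_chain":
        ca = _chain_ca(cfg, rng)
    else:
        ca = _globule_ca(cfg, rng)
    residues = _build_residues(codes, ca, cfg.topology, cfg.side_chain_mode, rng)
    if cfg.topology == "planted_cliques":
        residues = _plant_cliques(residues, cfg, rng)
    label = f"synthetic-{cfg.topology}-n{cfg.n_residues}-s{cfg.seed}"
    s = Structure(id=label, chain_id="A", residues=tuple(residues))
    if path is not None:
        write_pdb(s, path)
    return s


# ---------------------------------------------------------------------------
# Abstract graph fixtures
# ---------------------------------------------------------------------------


def generate_graph_fixture(kind: str, n: int, p: float = 0.1,
                           seed: int = 0) -> ResidueGraph:
    """Small labelled graphs (star, path, complete, er_random) for metric tests."""
    if kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "er_random":
        g = nx.gnp_random_graph(n, p, seed=seed)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    g = nx.relabel_nodes(g, {v: v + 1 for v in sorted(g.nodes)})
    rng = np.random.default_rng(seed)
    for v in g.nodes:
        g.nodes[v]["res_class"] = ("B", "I", "C")[rng.integers(3)]
    for u, v in g.edges:
        g.edges[u, v]["strength"] = 1.0
    return ResidueGraph(spec=NetworkSpec("arn", "an", 0.0), graph=g,
                        n_total=n, structure_id=f"fixture-{kind}-{n}")
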