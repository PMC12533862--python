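"""Independent brute-force oracles used to check the fast implementations."""

from __future__ import annotations

import itertools

import numpy as np

from docktriage.struct_io import AtomRecord, MolecularGraph


def brute_force_mappings(a: MolecularGraph, b: MolecularGraph) -> list[tuple[int, ...]]:
    """All element- and bond-preserving heavy-atom bijections by raw enumeration.

    Tries every permutation of B's heavy atoms against A's sorted heavy atoms.
    Exponential — only for molecules with ≤ 8 heavy atoms.
    """
    heavy_a = sorted(a.heavy_indices)
    heavy_b = sorted(b.heavy_indices)
    assert len(heavy_a) == len(heavy_b) <= 8
    elems_a = [a.atoms[i].element for i in heavy_a]
    bonds_a = {(min(i, j), max(i, j)) for i, j in a.bonds
               if not a.atoms[i].is_hydrogen and not a.atoms[j].is_hydrogen}
    bonds_b = {(min(i, j), max(i, j)) for i, j in b.bonds
               if not b.atoms[i].is_hydrogen and not b.atoms[j].is_hydrogen}
    out = []
    for perm in itertools.permutations(heavy_b):
        ok = True
        for ai, bj in zip(heavy_a, perm):
            if a.atoms[ai].element != b.atoms[bj].element:
                ok = False
                break
        if not ok:
            continue
        pos = dict(zip(heavy_a, perm))
        mapped = {tuple(sorted((pos[i], pos[j]))) for i, j in bonds_a}
        if mapped == bonds_b:
            out.append(perm)
    return sorted(out)


def brute_force_min_rmsd(a: MolecularGraph, b: MolecularGraph) -> float:
    """Minimum heavy-atom RMSD over the brute-force mapping list."""
    heavy_a = sorted(a.heavy_indices)
    xa = np.array([a.atoms[i].coords for i in heavy_a])
    xb_all = np.array([at.coords for at in b.atoms])
    best = np.inf
    for perm in brute_force_mappings(a, b):
        rmsd = float(np.sqrt(np.mean(np.sum((xa - xb_all[list(perm)]) ** 2, axis=1))))
        best = min(best, rmsd)
    return best


def permute_graph(g: MolecularGraph, perm: list[int]) -> MolecularGraph:
    """Relabel atoms of a graph by ``perm`` (new index perm[i] gets old atom i)."""
    n = g.n_atoms
    new_atoms: list[AtomRecord | None] = [None] * n
    for old, new in enumerate(perm):
        new_atoms[new] = g.atoms[old]
    bonds = {(min(perm[i], perm[j]), max(perm[i], perm[j])) for i, j in g.bonds}
    return MolecularGraph(atoms=list(new_atoms), bonds=bonds, provenance=g.provenance)
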