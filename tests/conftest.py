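"""Shared fixtures: reference structures and a brute-force fragment oracle."""

from __future__ import annotations

from itertools import combinations

import pytest

from hdxrank.chem_core import MolecularGraph, parse_structure

GALLIC_ACID = "OC(=O)c1cc(O)c(O)c(O)c1"
MU_SULFATE = "Cc1cc(=O)oc2cc(OS(=O)(=O)O)ccc12"      # 4-methylumbelliferyl sulfate
ISOPHORONE_DIAMINE = "CC1(C)CC(N)CC(C)(CN)C1"
METOLACHLOR = "CCc1cccc(C)c1N(C(C)COC)C(=O)CCl"
CYSTEINE = "NC(CS)C(=O)O"


@pytest.fixture
def gallic():
    return parse_structure(GALLIC_ACID, identifier="gallic acid")


@pytest.fixture
def mu_sulfate():
    return parse_structure(MU_SULFATE, identifier="4-MU sulfate")


@pytest.fixture
def ipd():
    return parse_structure(ISOPHORONE_DIAMINE, identifier="isophorone diamine")


def brute_force_fragments(mol: MolecularGraph, max_depth: int,
                          bde_of) -> dict[frozenset, float]:
    """Independent fragment oracle: exhaustive recursive cleavage.

    Tries removing every single bond of the current fragment; if that splits
    it, each side is a child of one event.  If not (the bond sits in a
    cycle), tries it together with every other non-splitting bond as a
    two-bond ring-opening event.  Returns {atom subset: minimal BDE sum}
    over everything reachable in at most ``max_depth`` events.
    """

    def edges_of(atoms):
        return [i for i, b in enumerate(mol.bonds)
                if b.i in atoms and b.j in atoms]

    def components(atoms, removed):
        adj = {a: [] for a in atoms}
        for i in edges_of(atoms):
            if i in removed:
                continue
            b = mol.bonds[i]
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        left = set(atoms)
        comps = []
        while left:
            stack = [next(iter(left))]
            comp = set()
            while stack:
                a = stack.pop()
                if a in comp:
                    continue
                comp.add(a)
                stack.extend(n for n in adj[a] if n not in comp)
            comps.append(frozenset(comp))
            left -= comp
        return comps

    best: dict[frozenset, float] = {}
    visited: dict[tuple[frozenset, int], float] = {}

    def visit(atoms: frozenset, bde: float, depth: int):
        # prune per (subset, depth) state so a cheap deep route cannot hide
        # children only reachable from a shallower occurrence
        prev = visited.get((atoms, depth))
        if prev is not None and prev <= bde:
            return
        visited[(atoms, depth)] = bde
        if atoms not in best or bde < best[atoms]:
            best[atoms] = bde
        if depth == max_depth:
            return
        eids = edges_of(atoms)
        single_splitters = []
        for i in eids:
            comps = components(atoms, {i})
            if len(comps) > 1:
                single_splitters.append(i)
                for c in comps:
                    visit(c, bde + bde_of(i), depth + 1)
        ring = [i for i in eids if i not in single_splitters]
        for i, j in combinations(ring, 2):
            comps = components(atoms, {i, j})
            if len(comps) > 1:
                for c in comps:
                    visit(c, bde + bde_of(i) + bde_of(j), depth + 1)

    visit(frozenset(range(mol.n_atoms)), 0.0, 0)
    return best
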