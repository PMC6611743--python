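"""Combinatorial bond-disconnection fragmenter with H/D-aware m/z hypotheses.

Fragments are connected heavy-atom subsets of the candidate, produced by a
sequence of cleavage *events*: each event either removes one acyclic bond
(splitting the current fragment in two) or removes a pair of ring bonds of
the same ring system (a ring opening).  The recursion depth is the number of
events; each fragment carries the cumulative bond-dissociation-energy (BDE)
sum of everything cleaved on the cheapest route to it, which later acts as a
penalty in the spectrum-explanation score.

Hydrogen bookkeeping is deliberately simple: a fragment keeps the hydrogens
(and deuterium labels) of its retained atoms; valence completion at the cut
bonds is expressed only through dynamic ±H/±D mass hypotheses, never through
explicit radical handling.  Deuterium is mobile in the collision cell, so in
deuterated mode the hypothesis space allows hydrogens and deuteriums to be
gained or lost independently (up to two units in total).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple

import networkx as nx

from .chem_core import (
    DELTA_HD,
    DEUTERON_MASS,
    EXCHANGEABLE_ELEMENTS,
    MASS,
    PROTON_MASS,
    Formula,
    MolecularGraph,
    monoisotopic_mass,
)
from .deuteration import DeuteratedVariant

__all__ = [
    "BDE_TABLE",
    "DEFAULT_BDE",
    "bond_dissociation_energy",
    "Fragment",
    "generate_fragments",
    "MzHypothesis",
    "fragment_mz_hypotheses",
]

# ---------------------------------------------------------------------------
# bond dissociation energies
# ---------------------------------------------------------------------------

#: Homolytic bond dissociation energies (kJ/mol scale) by element pair and
#: integer bond order.  Aromatic bonds use 1.5x the single-bond entry.
BDE_TABLE: dict[tuple[frozenset[str], int], float] = {
    (frozenset({"C"}), 1): 346.0,
    (frozenset({"C", "N"}), 1): 305.0,
    (frozenset({"C", "O"}), 1): 358.0,
    (frozenset({"C", "S"}), 1): 272.0,
    (frozenset({"C", "F"}), 1): 485.0,
    (frozenset({"C", "Cl"}), 1): 327.0,
    (frozenset({"C", "Br"}), 1): 285.0,
    (frozenset({"C", "I"}), 1): 213.0,
    (frozenset({"C", "P"}), 1): 264.0,
    (frozenset({"N"}), 1): 167.0,
    (frozenset({"N", "O"}), 1): 201.0,
    (frozenset({"O"}), 1): 146.0,
    (frozenset({"O", "S"}), 1): 265.0,
    (frozenset({"O", "P"}), 1): 335.0,
    (frozenset({"S"}), 1): 266.0,
    (frozenset({"N", "S"}), 1): 247.0,
    (frozenset({"C"}), 2): 602.0,
    (frozenset({"C", "N"}), 2): 615.0,
    (frozenset({"C", "O"}), 2): 749.0,
    (frozenset({"C", "S"}), 2): 573.0,
    (frozenset({"N"}), 2): 418.0,
    (frozenset({"N", "O"}), 2): 607.0,
    (frozenset({"O", "S"}), 2): 522.0,
    (frozenset({"O", "P"}), 2): 544.0,
    (frozenset({"C"}), 3): 835.0,
    (frozenset({"C", "N"}), 3): 887.0,
    (frozenset({"N"}), 3): 942.0,
}

#: Fallback for element pairs absent from the table.
DEFAULT_BDE = 348.0

#: Multiplier applied to the single-bond entry for aromatic bonds.
AROMATIC_FACTOR = 1.5


def bond_dissociation_energy(mol: MolecularGraph, bond_index: int,
                             table: dict | None = None,
                             default: float = DEFAULT_BDE) -> float:
    table = BDE_TABLE if table is None else table
    b = mol.bonds[bond_index]
    pair = frozenset({mol.atoms[b.i].element, mol.atoms[b.j].element})
    if b.order == 1.5:
        return AROMATIC_FACTOR * table.get((pair, 1), default)
    return table.get((pair, int(b.order)), default)


# ---------------------------------------------------------------------------
# fragment generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """Connected atom subset of a parent candidate.

    ``bde`` is the minimal cumulative dissociation energy over all cleavage
    routes producing this subset within the depth budget; ``depth`` is the
    event count of that cheapest route.
    """

    parent: MolecularGraph
    atoms: frozenset[int]
    bde: float
    depth: int

    @property
    def n_h(self) -> int:
        return sum(self.parent.atoms[i].n_h for i in self.atoms)

    @property
    def n_d(self) -> int:
        return sum(self.parent.atoms[i].n_d for i in self.atoms)

    def exchangeable_h(self) -> int:
        """Retained O/N/S-attached hydrogens (upper bound on exchanged sites)."""
        return sum(self.parent.atoms[i].n_h for i in self.atoms
                   if self.parent.atoms[i].element in EXCHANGEABLE_ELEMENTS)

    def nonexchangeable_h(self) -> int:
        """Retained C(etc.)-attached hydrogens — the variable-D capacity."""
        return self.n_h - self.exchangeable_h()

    def formula(self, charge: int = 0) -> Formula:
        return self.parent.formula(self.atoms, charge=charge)

    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula())


def _graph_of(mol: MolecularGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    for idx, b in enumerate(mol.bonds):
        g.add_edge(b.i, b.j, index=idx)
    return g


def generate_fragments(mol: MolecularGraph, max_depth: int = 2,
                       bde_table: dict | None = None) -> list[Fragment]:
    """All fragments reachable within ``max_depth`` cleavage events.

    Duplicate atom subsets keep the minimal BDE sum, which makes the output
    independent of cleavage order.  The intact molecule is always included
    (depth 0, BDE 0).
    """
    if mol.n_atoms == 0:
        raise ValueError("cannot fragment an empty molecule")
    if max_depth < 0:
        raise ValueError("max_depth must be non-negative")
    full_graph = _graph_of(mol)
    if not nx.is_connected(full_graph):
        raise ValueError("candidate structure must be connected")

    bde_of = [bond_dissociation_energy(mol, i, bde_table)
              for i in range(len(mol.bonds))]

    full = frozenset(range(mol.n_atoms))
    # best known (bde, depth) per atom subset
    best: dict[frozenset[int], tuple[float, int]] = {full: (0.0, 0)}
    frontier: dict[frozenset[int], float] = {full: 0.0}

    for depth in range(1, max_depth + 1):
        next_frontier: dict[frozenset[int], float] = {}
        for subset, base_bde in frontier.items():
            sub = full_graph.subgraph(subset)
            bridges = set(nx.bridges(sub)) if sub.number_of_edges() else set()
            ring_edges = [e for e in sub.edges
                          if (e not in bridges and (e[1], e[0]) not in bridges)]
            children: list[tuple[frozenset[int], float]] = []
            # acyclic cleavage: one bridge bond per event
            for u, v in bridges:
                cost = bde_of[sub.edges[u, v]["index"]]
                h = sub.copy()
                h.remove_edge(u, v)
                for comp in nx.connected_components(h):
                    children.append((frozenset(comp), base_bde + cost))
            # ring opening: a pair of ring bonds removed in one event
            for (u1, v1), (u2, v2) in combinations(ring_edges, 2):
                h = sub.copy()
                h.remove_edge(u1, v1)
                h.remove_edge(u2, v2)
                comps = list(nx.connected_components(h))
                if len(comps) < 2:
                    continue  # fused-ring pair that does not split
                cost = (bde_of[sub.edges[u1, v1]["index"]]
                        + bde_of[sub.edges[u2, v2]["index"]])
                for comp in comps:
                    children.append((frozenset(comp), base_bde + cost))
            for child, bde in children:
                prev = best.get(child)
                if prev is None or bde < prev[0]:
                    best[child] = (bde, depth)
                    next_frontier[child] = bde
        frontier = next_frontier
        if not frontier:
            break

    return [Fragment(mol, subset, bde, depth)
            for subset, (bde, depth) in best.items()]


# ---------------------------------------------------------------------------
# m/z hypotheses
# ---------------------------------------------------------------------------

class MzHypothesis(NamedTuple):
    """One explanation an ion peak can be matched against.

    ``h_shift``/``d_shift`` are the signed dynamic hydrogen/deuterium
    adjustments; ``k`` is the variable-deuterium count of Eq.-2 type
    exchanges; ``n_d`` the resulting deuterium count on the fragment ion.
    """

    mz: float
    h_shift: int
    d_shift: int
    k: int
    n_d: int
    fragment: Fragment


def _shift_combos(max_shift: int) -> list[tuple[int, int]]:
    """All (h_shift, d_shift) with |h| + |d| <= max_shift."""
    out = []
    for h in range(-max_shift, max_shift + 1):
        for d in range(-max_shift, max_shift + 1):
            if abs(h) + abs(d) <= max_shift:
                out.append((h, d))
    return out


def fragment_mz_hypotheses(frag: Fragment, mode: str = "+",
                           deuterated: bool = False,
                           variant: DeuteratedVariant | None = None,
                           max_shift: int = 2) -> list[MzHypothesis]:
    """m/z hypotheses for one fragment in one spectrum.

    Normal spectra: the fragment's neutral mass, shifted by up to
    ``max_shift`` hydrogens in either direction, ionised by proton transfer.

    Deuterated spectra: the retained exchanged positions of the variant add
    ``eH(frag) * (m(D)-m(H))``; where the variant carries variable deuteriums
    (vH > 0) each ``k`` up to the fragment's non-exchangeable-H capacity adds
    a further multiple; the dynamic shifts may then add or remove hydrogens
    *or* deuteriums (mobile D in the collision cell), and ionisation uses a
    deuteron.
    """
    if mode not in ("+", "-"):
        raise ValueError("mode must be '+' or '-'")
    base = frag.neutral_mass()
    sign = 1 if mode == "+" else -1
    out: list[MzHypothesis] = []
    if not deuterated:
        adduct = sign * PROTON_MASS
        for h in range(-max_shift, max_shift + 1):
            if frag.n_h + h < 0:
                continue
            out.append(MzHypothesis(base + h * MASS["H"] + adduct,
                                    h, 0, 0, frag.n_d, frag))
        return out

    if variant is None:
        raise ValueError("deuterated hypotheses require a DeuteratedVariant")
    adduct = sign * DEUTERON_MASS
    # exchanged positions retained by this fragment
    if variant.sites:
        eh_frag = sum(1 for (a, _s) in variant.sites if a in frag.atoms)
    else:
        # positional ambiguity: bounded by retained labile hydrogens
        eh_frag = min(variant.n_d - variant.vh, frag.exchangeable_h()) \
            if variant.n_d > variant.vh else 0
    k_max = min(variant.vh, frag.nonexchangeable_h())
    shift_combos = _shift_combos(max_shift)
    for k in range(0, k_max + 1):
        n_d_core = frag.n_d + eh_frag + k
        core = base + (eh_frag + k) * DELTA_HD
        for h, d in shift_combos:
            # a lost D may be the one delivered by the deuteron adduct
            if n_d_core + d + (1 if mode == "+" else 0) < 0:
                continue
            if frag.n_h + h < 0:
                continue
            mz = core + h * MASS["H"] + d * MASS["D"] + adduct
            out.append(MzHypothesis(mz, h, d, k, max(0, n_d_core + d), frag))
    return out


def all_hypotheses(fragments: Iterable[Fragment], mode: str = "+",
                   deuterated: bool = False,
                   variant: DeuteratedVariant | None = None,
                   max_shift: int = 2) -> list[MzHypothesis]:
    """Hypotheses for every fragment, concatenated."""
    out: list[MzHypothesis] = []
    for f in fragments:
        out.extend(fragment_mz_hypotheses(f, mode, deuterated, variant,
                                          max_shift))
    return out
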