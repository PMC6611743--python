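"""In silico deuteration of candidate structures.

Given the experimentally exchanged hydrogen count X (inferred from the
neutral-mass difference between the normal and deuterated precursors) and a
candidate with eH easily exchangeable hydrogens, three cases arise:

* ``eH == X`` — exactly one deuterated variant, all labile H exchanged;
* ``eH <  X`` — exactly one variant: all labile H exchanged plus
  ``vH = X - eH`` "variable" deuteriums whose position is unknown;
* ``eH >  X`` — one variant per distinct X-subset of the labile hydrogen
  sites, i.e. binomial(eH, X) variants.

A mismatch between eH and X is never grounds for eliminating a candidate;
it is penalised downstream by the exchanged-hydrogens score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, NamedTuple

import pandas as pd

from .chem_core import (
    C13_MASS,
    DELTA_HD,
    EXCHANGEABLE_ELEMENTS,
    MASS,
    MolecularGraph,
    count_exchangeable_hydrogens,
    ion_mz,
)

log = logging.getLogger(__name__)

__all__ = [
    "XResult",
    "PrecursorPair",
    "DeuteratedVariant",
    "determine_X",
    "deuterate_candidate",
    "predict_hdx_species",
    "predict_hdx_batch",
    "exchange_completeness_probability",
    "isotope_confusability",
]

#: Above this many labile hydrogens the combinatorial case is not enumerated.
MAX_COMBINATORIAL_EH = 20


class XResult(NamedTuple):
    """Exchanged-H count with the residual of the integer fit."""

    X: int
    residual_ppm: float
    flagged: bool


def determine_X(mass_h: float, mass_d: float,
                max_residual_ppm: float = 10.0) -> XResult:
    """Infer X from the neutral masses of a normal/deuterated precursor pair.

    ``X = round((mass_d - mass_h) / 1.006277)``.  The residual of the fit is
    reported in ppm of the deuterated mass; pairs whose residual exceeds
    ``max_residual_ppm`` are flagged (wrong isotopic-peak selection during
    acquisition is a known failure mode) but never rejected.
    """
    if mass_h <= 0 or mass_d <= 0:
        raise ValueError("precursor masses must be positive")
    diff = mass_d - mass_h
    tol = max_residual_ppm * mass_d / 1e6
    if diff < -tol:
        raise ValueError(
            f"invalid pair: deuterated mass {mass_d} below normal mass {mass_h}")
    x = max(0, round(diff / DELTA_HD))
    residual = abs(diff - x * DELTA_HD)
    residual_ppm = residual / mass_d * 1e6
    flagged = residual_ppm > max_residual_ppm
    if flagged:
        log.warning("X=%d fit residual %.2f ppm exceeds %.2f ppm for pair "
                    "(%.4f, %.4f)", x, residual_ppm, max_residual_ppm,
                    mass_h, mass_d)
    return XResult(x, residual_ppm, flagged)


@dataclass
class PrecursorPair:
    """Neutral precursor masses of the normal and deuterated acquisitions."""

    mass_h: float
    mass_d: float
    mode: str = "+"
    max_residual_ppm: float = 10.0
    X: int = field(init=False)
    residual_ppm: float = field(init=False)
    flagged: bool = field(init=False)

    def __post_init__(self) -> None:
        res = determine_X(self.mass_h, self.mass_d, self.max_residual_ppm)
        self.X, self.residual_ppm, self.flagged = res


@dataclass(frozen=True)
class DeuteratedVariant:
    """One in silico deuteration of a candidate.

    ``sites`` are the exchanged labile hydrogen sites as (atom index, slot)
    pairs; ``vh`` is the count of position-unknown deuteriums.  A variant
    always satisfies ``len(sites) + vh == X`` of the spectrum pair, except
    for the capped combinatorial case where all X deuteriums are carried as
    ``vh`` with no resolved positions.
    """

    parent: MolecularGraph
    sites: frozenset[tuple[int, int]]
    eh_parent: int
    vh: int = 0

    @property
    def n_d(self) -> int:
        return len(self.sites) + self.vh

    def d_count_on_atom(self, atom_idx: int) -> int:
        return sum(1 for (a, _slot) in self.sites if a == atom_idx)


def deuterate_candidate(mol: MolecularGraph, X: int,
                        max_eh: int = MAX_COMBINATORIAL_EH,
                        ) -> list[DeuteratedVariant]:
    """Generate the deuterated variant list for one candidate.

    See the module docstring for the three cases.  For ``eH > max_eh`` the
    binomial enumeration is not attempted; a single variant with full
    positional ambiguity (``vh = X``) stands in, with a warning.
    """
    if X < 0:
        raise ValueError("X must be non-negative")
    sites = mol.exchangeable_sites()
    eh = len(sites)
    if eh <= X:
        return [DeuteratedVariant(mol, frozenset(sites), eh, vh=X - eh)]
    if eh > max_eh:
        log.warning("candidate %s has eH=%d > cap %d; using one variant "
                    "with positional ambiguity", mol.identifier, eh, max_eh)
        return [DeuteratedVariant(mol, frozenset(), eh, vh=X)]
    return [DeuteratedVariant(mol, frozenset(subset), eh, vh=0)
            for subset in combinations(sites, X)]


def n_variants(eh: int, X: int) -> int:
    """Closed-form variant count: binomial(eH, X) if eH > X else 1."""
    return math.comb(eh, X) if eh > X else 1


class HdxSpecies(NamedTuple):
    """Fully exchanged structure with its deuteron-adduct ion masses."""

    graph: MolecularGraph
    n_d: int
    neutral_mass: float
    mz_pos: float    # [M+D]+
    mz_neg: float    # [M-D]-


def predict_hdx_species(mol: MolecularGraph) -> HdxSpecies:
    """Fully exchange every O/N/S-attached hydrogen and compute ion masses.

    Models the deuterium-flooded LC system where all labile hydrogens are
    replaced (SH -> SD, OH -> OD, NH2 -> ND2) and ionisation transfers a
    deuteron instead of a proton.
    """
    atoms = []
    for a in mol.atoms:
        if a.element in EXCHANGEABLE_ELEMENTS and a.n_h:
            atoms.append(type(a)(a.element, a.charge, 0, a.n_d + a.n_h,
                                 a.isotope))
        else:
            atoms.append(type(a)(a.element, a.charge, a.n_h, a.n_d, a.isotope))
    exchanged = MolecularGraph(atoms=atoms, bonds=list(mol.bonds),
                               identifier=mol.identifier, source=mol.source)
    n_d = count_exchangeable_hydrogens(mol)
    m = exchanged.neutral_mass()
    return HdxSpecies(exchanged, n_d, m, ion_mz(m, "M+D"), ion_mz(m, "M-D"))


def predict_hdx_batch(candidates: pd.DataFrame) -> pd.DataFrame:
    """Batch HDX prediction: (identifier, SMILES) -> deuterated table.

    Returns a frame with columns identifier, smiles, deuterated_smiles,
    n_d, mz_md_pos ([M+D]+) and mz_md_neg ([M-D]-).
    """
    from .chem_core import parse_structure

    cols = {c.lower(): c for c in candidates.columns}
    id_col = cols.get("identifier", candidates.columns[0])
    smi_col = cols.get("smiles", candidates.columns[1])
    rows = []
    for _, rec in candidates.iterrows():
        mol = parse_structure(str(rec[smi_col]), identifier=str(rec[id_col]))
        sp = predict_hdx_species(mol)
        rows.append({
            "identifier": rec[id_col],
            "smiles": rec[smi_col],
            "deuterated_smiles": sp.graph.to_smiles(),
            "n_d": sp.n_d,
            "mz_md_pos": round(sp.mz_pos, 6),
            "mz_md_neg": round(sp.mz_neg, 6),
        })
    return pd.DataFrame(rows)


def exchange_completeness_probability(atom_purity: float,
                                      n_labile: int) -> float:
    """Probability that all labile hydrogens of a molecule exchange.

    With deuterium atom purity ``p`` of the mobile phase and ``n`` labile
    hydrogens, complete exchange has probability ``p**n`` — e.g. 99% purity
    and 40 labile hydrogens leaves only ~66%.
    """
    if not 0.0 <= atom_purity <= 1.0:
        raise ValueError("purity must be a fraction in [0, 1]")
    if n_labile < 0:
        raise ValueError("n_labile must be non-negative")
    return atom_purity ** n_labile


class Confusability(NamedTuple):
    delta_da: float
    ppm: float


def isotope_confusability(mz: float) -> Confusability:
    """Mass separation between a 13C isotopologue and a monodeuterated ion.

    The 13C peak of the undeuterated species sits only
    ``(m(D)-m(H)) - (m(13C)-m(12C)) = 0.00292 Da`` below a potential
    monodeuterated species; resolving the two requires resolution of roughly
    ``mz / 0.00292``.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    delta = round(DELTA_HD - (C13_MASS - MASS["C"]), 5)
    return Confusability(delta, delta / mz * 1e6)
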