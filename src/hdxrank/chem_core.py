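"""Structure parsing, mass arithmetic and exchangeable-hydrogen detection.

Everything downstream (in silico deuteration, fragmentation, scoring) works on
the :class:`MolecularGraph` produced here: a heavy-atom graph in which
hydrogens and deuteriums are per-atom counts rather than graph nodes.  That
representation lets fragmentation operate on the unchanged skeleton while
deuterium labels ride along with their heavy atoms.

Masses are monoisotopic.  Deuterium is a first-class entry of the mass table
(symbol ``"D"``), distinct from hydrogen; the difference
``m(D) - m(H) = 1.006277 Da`` is the mass increment of one H/D exchange and
is exposed as :data:`DELTA_HD`.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "DEUTERON_MASS",
    "DELTA_HD",
    "C13_MASS",
    "EXCHANGEABLE_ELEMENTS",
    "Atom",
    "Bond",
    "MolecularGraph",
    "Formula",
    "ParseError",
    "parse_structure",
    "count_exchangeable_hydrogens",
    "monoisotopic_mass",
    "ion_mz",
]

# ---------------------------------------------------------------------------
# mass table
# ---------------------------------------------------------------------------

#: Monoisotopic masses in Da.  "D" is deuterium, kept separate from "H".
MASS: dict[str, float] = {
    "H": 1.007825,
    "D": 2.014102,
    "C": 12.0,
    "N": 14.003074,
    "O": 15.994915,
    "F": 18.998403,
    "Na": 22.989770,
    "Si": 27.976927,
    "P": 30.973762,
    "S": 31.972071,
    "Cl": 34.968853,
    "K": 38.963707,
    "Br": 78.918338,
    "I": 126.904473,
    "B": 11.009305,
    "Se": 79.916522,
}

ELECTRON_MASS = 0.00054858
#: m/z contribution of a proton / deuteron adduct (electron-corrected).
PROTON_MASS = MASS["H"] - ELECTRON_MASS      # 1.007276
DEUTERON_MASS = MASS["D"] - ELECTRON_MASS    # 2.013553
#: Mass increment of one hydrogen -> deuterium exchange.
DELTA_HD = MASS["D"] - MASS["H"]             # 1.006277
C13_MASS = 13.003355

#: Hydrogens on these elements are "easily exchangeable" on the LC timescale.
EXCHANGEABLE_ELEMENTS = frozenset({"O", "N", "S"})

_RDKIT_PT = Chem.GetPeriodicTable()


def _element_mass(symbol: str) -> float:
    """Monoisotopic mass of an element, falling back to rdkit's table."""
    try:
        return MASS[symbol]
    except KeyError:
        m = _RDKIT_PT.GetMostCommonIsotopeMass(symbol)
        if m <= 0:
            raise KeyError(f"unknown element symbol: {symbol!r}") from None
        MASS[symbol] = float(m)
        return MASS[symbol]


class ParseError(ValueError):
    """Raised when a structure or formula string cannot be parsed."""


# ---------------------------------------------------------------------------
# molecular graph
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    element: str
    charge: int = 0
    n_h: int = 0          # attached hydrogens (protium only)
    n_d: int = 0          # attached deuteriums
    isotope: int = 0      # non-zero for a non-standard heavy-atom isotope


@dataclass
class Bond:
    i: int
    j: int
    order: float          # 1, 2, 3 or 1.5 (aromatic)
    in_ring: bool = False


@dataclass
class MolecularGraph:
    """Heavy-atom graph with H/D bookkeeping.

    Deuterium is stored as a per-atom label count (``Atom.n_d``), never as a
    graph node, so fragmentation sees the same skeleton for a candidate and
    all of its deuterated variants.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    identifier: str = ""
    source: str = ""      # original SMILES/InChI text, for provenance

    def __post_init__(self) -> None:
        for a in self.atoms:
            if a.n_h < 0 or a.n_d < 0:
                raise ValueError("negative hydrogen count")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return out

    def total_hydrogens(self) -> int:
        """H + D count over the whole structure."""
        return sum(a.n_h + a.n_d for a in self.atoms)

    def exchangeable_sites(self) -> list[tuple[int, int]]:
        """All (atom index, slot) pairs of O/N/S-attached hydrogens.

        An atom carrying ``k`` labile hydrogens contributes ``k`` sites so
        that X-subset enumeration counts hydrogens, not heteroatoms.
        """
        sites = []
        for idx, a in enumerate(self.atoms):
            if a.element in EXCHANGEABLE_ELEMENTS:
                for slot in range(a.n_h):
                    sites.append((idx, slot))
        return sites

    def is_connected(self) -> bool:
        if not self.atoms:
            return False
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_atoms

    # -- formula / mass -----------------------------------------------------

    def formula(self, atom_subset: Iterable[int] | None = None,
                charge: int = 0) -> "Formula":
        counts: Counter[str] = Counter()
        indices = range(self.n_atoms) if atom_subset is None else atom_subset
        for idx in indices:
            a = self.atoms[idx]
            counts[a.element] += 1
            if a.n_h:
                counts["H"] += a.n_h
            if a.n_d:
                counts["D"] += a.n_d
        return Formula(dict(counts), charge=charge)

    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula())

    # -- conversion back to rdkit / SMILES ----------------------------------

    def to_rdkit(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for a in self.atoms:
            at = Chem.Atom(a.element)
            at.SetFormalCharge(a.charge)
            at.SetNoImplicit(True)
            at.SetNumExplicitHs(a.n_h)
            if a.isotope:
                at.SetIsotope(a.isotope)
            rw.AddAtom(at)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
        for b in self.bonds:
            rw.AddBond(b.i, b.j, order_map[b.order])
        # deuteriums are re-materialised as explicit [2H] nodes
        for idx, a in enumerate(self.atoms):
            for _ in range(a.n_d):
                h = Chem.Atom(1)
                h.SetIsotope(2)
                h.SetNoImplicit(True)
                hid = rw.AddAtom(h)
                rw.AddBond(idx, hid, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    def to_smiles(self) -> str:
        """Canonical SMILES; deuterium rendered as ``[2H]``."""
        return Chem.MolToSmiles(self.to_rdkit())

    def inchikey_block(self) -> str:
        """First (connectivity) block of the InChIKey, used for dedup."""
        key = Chem.MolToInchiKey(self.to_rdkit())
        return key.split("-")[0]


# ---------------------------------------------------------------------------
# formulas
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class Formula:
    """Element -> count map; deuterium ("D") counted separately from "H"."""

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        self.counts = {el: int(n) for el, n in self.counts.items() if n}
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("negative element count")

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string, e.g. ``"C4H3D6O+"``."""
        body = text.strip()
        charge = 0
        m = re.search(r"([+-]+)$", body)
        if m:
            # multiple charges render as repeated signs ("++"), never "2+",
            # so trailing digits always belong to an element count
            signs = m.group(1)
            if len(set(signs)) > 1:
                raise ParseError(f"mixed charge signs in {text!r}")
            charge = (1 if signs[0] == "+" else -1) * len(signs)
            body = body[: m.start()]
        counts: Counter[str] = Counter()
        pos = 0
        for match in _FORMULA_TOKEN.finditer(body):
            if match.start() != pos:
                raise ParseError(f"cannot parse formula {text!r}")
            el, num = match.group(1), match.group(2)
            if el != "D":
                try:
                    known = _RDKIT_PT.GetAtomicNumber(el) > 0
                except Exception:
                    known = False
                if not known:
                    raise ParseError(f"unknown element {el!r} in {text!r}")
            counts[el] += int(num) if num else 1
            pos = match.end()
        if pos != len(body):
            raise ParseError(f"cannot parse formula {text!r}")
        return cls(dict(counts), charge=charge)

    def render(self) -> str:
        """Hill order (C, H, D, then alphabetical); trailing charge sign."""
        parts = []
        order = [el for el in ("C", "H", "D") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H", "D"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        s = "".join(parts)
        if self.charge:
            s += ("+" if self.charge > 0 else "-") * abs(self.charge)
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def monoisotopic_mass(f: Formula | Mapping[str, int] | str) -> float:
    """Monoisotopic mass in Da; charged formulas are electron-corrected.

    A formula with charge ``z`` has ``z`` electron masses subtracted (added
    for negative charge); neutral formulas ignore the electron term.
    """
    if isinstance(f, str):
        f = Formula.parse(f)
    elif not isinstance(f, Formula):
        f = Formula(dict(f))
    mass = sum(_element_mass(el) * n for el, n in f.counts.items())
    return mass - f.charge * ELECTRON_MASS


# ---------------------------------------------------------------------------
# adduct arithmetic
# ---------------------------------------------------------------------------

_ADDUCT_OFFSET = {
    "M+H": PROTON_MASS,
    "M+D": DEUTERON_MASS,
    "M-H": -PROTON_MASS,
    "M-D": -DEUTERON_MASS,
}


def _normalize_adduct(adduct: str) -> str:
    a = adduct.strip().strip("[]")
    a = a.rstrip("+-").replace("−", "-")
    a = a.replace(" ", "")
    if a not in _ADDUCT_OFFSET:
        raise ValueError(f"unsupported adduct {adduct!r}; "
                         f"expected one of {sorted(_ADDUCT_OFFSET)}")
    return a


def adduct_mode(adduct: str) -> str:
    """Ion mode ('+' or '-') implied by an adduct label."""
    return "+" if "+" in _normalize_adduct(adduct) else "-"


def ion_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of the singly charged ion for the given adduct.

    M+H adds m(H) - m(e); M+D adds m(D) - m(e); the deprotonated /
    dedeuteronated forms subtract the same electron-corrected masses.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return neutral_mass + _ADDUCT_OFFSET[_normalize_adduct(adduct)]


def neutral_from_mz(mz: float, adduct: str) -> float:
    """Inverse of :func:`ion_mz`."""
    return mz - _ADDUCT_OFFSET[_normalize_adduct(adduct)]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_structure(text: str, identifier: str = "") -> MolecularGraph:
    """Parse a SMILES or InChI string into a :class:`MolecularGraph`.

    ``[2H]`` isotope labels are folded into per-atom deuterium counts on the
    attached heavy atom.  Raises :class:`ParseError` on malformed input,
    naming the offending string.
    """
    text = text.strip()
    if not text:
        raise ParseError("empty structure string")
    if text.startswith("InChI="):
        mol = Chem.MolFromInchi(text, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        raise ParseError(f"could not parse structure: {text!r}")
    return _from_rdkit(mol, identifier=identifier, source=text)


def _from_rdkit(mol: Chem.Mol, identifier: str = "",
                source: str = "") -> MolecularGraph:
    heavy_idx: dict[int, int] = {}
    atoms: list[Atom] = []
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 1:
            continue
        heavy_idx[a.GetIdx()] = len(atoms)
        atoms.append(Atom(
            element=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            n_h=a.GetTotalNumHs(),   # implicit + explicit, not neighbor nodes
            n_d=0,
            isotope=a.GetIsotope(),
        ))
    # fold explicit hydrogen nodes into their heavy neighbor's counts
    for a in mol.GetAtoms():
        if a.GetAtomicNum() != 1:
            continue
        nbrs = [n for n in a.GetNeighbors() if n.GetAtomicNum() != 1]
        if not nbrs:
            raise ParseError(f"free hydrogen atom in {source!r}")
        tgt = atoms[heavy_idx[nbrs[0].GetIdx()]]
        if a.GetIsotope() == 2:
            tgt.n_d += 1
        else:
            tgt.n_h += 1
    bonds: list[Bond] = []
    for b in mol.GetBonds():
        bi, bj = b.GetBeginAtom(), b.GetEndAtom()
        if bi.GetAtomicNum() == 1 or bj.GetAtomicNum() == 1:
            continue
        order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
        bonds.append(Bond(heavy_idx[bi.GetIdx()], heavy_idx[bj.GetIdx()],
                          order=order, in_ring=b.IsInRing()))
    return MolecularGraph(atoms=atoms, bonds=bonds,
                          identifier=identifier, source=source)


def count_exchangeable_hydrogens(mol: MolecularGraph) -> int:
    """Number of hydrogens attached to O, N or S atoms (eH).

    Deuteriums already sitting on those positions do not count: eH is the
    number of *remaining* labile protiums.
    """
    return sum(a.n_h for a in mol.atoms if a.element in EXCHANGEABLE_ELEMENTS)
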