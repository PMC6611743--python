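"""Synthetic spectrum pairs and formula-matched decoy candidates.

The generator stands in for paired LC-MS/MS acquisitions of reference
standards: it fragments a known structure in silico, turns a subset of the
fragments into peaks of a "normal" spectrum, shifts the retained labile
hydrogens of the fully exchanged species to build the "deuterated"
spectrum, assigns log-normal intensities and sprinkles seeded decoy peaks.
Because every signal peak is produced by the fragmenter itself, a zero-decoy
fixture is fully explainable by the true candidate (the closure property the
tests rely on).

Decoy candidates are built without any structure database: random
valence-constrained heavy-atom trees over the true molecule's element
multiset are constitutional isomers of it (same molecular formula by
construction for acyclic single-bonded skeletons), with labile-hydrogen
counts that vary with how many O/N/S atoms end up internal versus terminal.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem_core import (
    DELTA_HD,
    MolecularGraph,
    count_exchangeable_hydrogens,
    ion_mz,
    parse_structure,
)
from .deuteration import predict_hdx_species
from .fragmentation import generate_fragments
from .scoring import (
    ScoreVector,
    Spectrum,
    SpectrumPair,
    _normalize_columns,
    score_candidates,
)
from .weights_opt import TrainingInstance

log = logging.getLogger(__name__)

__all__ = [
    "random_tree_molecule",
    "decoy_candidates",
    "FixtureTruth",
    "generate_fixture_pair",
    "make_training_instances",
]

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}


def random_tree_molecule(composition: dict[str, int],
                         rng: np.random.Generator) -> str:
    """Random acyclic molecule over a fixed heavy-atom multiset.

    Atoms are attached one by one to a uniformly chosen existing atom with
    spare valence; all bonds are single and remaining valences are filled
    with hydrogen, so every tree over the same multiset shares one molecular
    formula.
    """
    from rdkit import Chem

    elements = [el for el, n in sorted(composition.items()) for _ in range(n)]
    if not elements:
        raise ValueError("empty composition")
    order = rng.permutation(len(elements))
    rw = Chem.RWMol()
    degree: list[int] = []
    placed: list[int] = []
    for pos in order:
        el = elements[pos]
        idx = rw.AddAtom(Chem.Atom(el))
        if placed:
            open_atoms = [a for a in placed if degree[a] < _VALENCE[rw.GetAtomWithIdx(a).GetSymbol()]]
            if not open_atoms:
                raise ValueError("composition cannot form a connected tree")
            parent = int(open_atoms[rng.integers(len(open_atoms))])
            rw.AddBond(parent, idx, Chem.BondType.SINGLE)
            degree[parent] += 1
            degree.append(1)
        else:
            degree.append(0)
        placed.append(idx)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def decoy_candidates(truth_smiles: str, n_decoys: int,
                     rng: np.random.Generator,
                     max_attempts: int = 2000) -> list[str]:
    """Formula-matched decoys for a (preferably acyclic) true structure.

    Random isomeric trees over the truth's heavy-atom multiset, deduplicated
    by InChIKey first block and excluding the truth itself.  For ring-bearing
    targets the decoys share heavy-atom composition but not hydrogen count;
    they remain useful rank competitors and are logged as approximate.
    """
    truth = parse_structure(truth_smiles)
    composition = Counter(a.element for a in truth.atoms)
    unsupported = set(composition) - set(_VALENCE)
    if unsupported:
        raise ValueError(f"unsupported elements for decoy trees: {unsupported}")
    if any(b.order != 1 for b in truth.bonds):
        log.info("truth %s is not a simple acyclic skeleton; decoys match "
                 "heavy-atom composition only", truth_smiles)
    truth_block = truth.inchikey_block()
    seen = {truth_block}
    out: list[str] = []
    for _ in range(max_attempts):
        if len(out) >= n_decoys:
            break
        try:
            smi = random_tree_molecule(dict(composition), rng)
        except ValueError:
            continue
        g = parse_structure(smi)
        block = g.inchikey_block()
        if block in seen:
            continue
        seen.add(block)
        out.append(smi)
    if len(out) < n_decoys:
        log.warning("only %d/%d distinct decoys found for %s", len(out),
                    n_decoys, truth_smiles)
    return out


@dataclass
class FixtureTruth:
    """Ground truth record emitted alongside a synthetic spectrum pair."""

    smiles: str
    x: int
    mass_h: float
    mass_d: float
    fragment_atoms: list[frozenset[int]] = field(default_factory=list)
    fragment_mz_normal: list[float] = field(default_factory=list)
    fragment_mz_deuterated: list[float] = field(default_factory=list)


def generate_fixture_pair(mol: MolecularGraph | str, mode: str = "+",
                          n_decoy_peaks: int = 3,
                          seed: int | np.random.Generator | None = None,
                          max_peaks: int = 10, max_depth: int = 2,
                          intensity_sigma: float = 1.0,
                          ) -> tuple[SpectrumPair, FixtureTruth]:
    """Simulate a normal/deuterated MS/MS pair from a known structure.

    Fragments (lowest cumulative BDE first) become peaks: the normal
    spectrum at the proton-adduct fragment masses, the deuterated spectrum
    at the same fragments shifted by their retained labile hydrogens times
    1.006277 Da and ionised by deuteron transfer.  Intensities are
    log-normal; ``n_decoy_peaks`` unexplained peaks of low intensity are
    added to each spectrum.  Byte-identical under a fixed seed.
    """
    if isinstance(mol, str):
        mol = parse_structure(mol)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    x = count_exchangeable_hydrogens(mol)
    mass_h = mol.neutral_mass()
    species = predict_hdx_species(mol)
    mass_d = species.neutral_mass

    adduct_h = "M+H" if mode == "+" else "M-H"
    adduct_d = "M+D" if mode == "+" else "M-D"
    prec_h = ion_mz(mass_h, adduct_h)
    prec_d = ion_mz(mass_d, adduct_d)

    frags = generate_fragments(mol, max_depth=max_depth)
    full = frozenset(range(mol.n_atoms))
    # proper fragments only, cheapest explanations first
    frags = sorted((f for f in frags if f.atoms != full and len(f.atoms) >= 2),
                   key=lambda f: (f.bde, -len(f.atoms)))
    truth = FixtureTruth(mol.to_smiles(), x, mass_h, mass_d)
    mz_h: list[float] = []
    mz_d: list[float] = []
    seen_masses: set[float] = set()
    for f in frags:
        if len(mz_h) >= max_peaks:
            break
        m_n = ion_mz(f.neutral_mass(), adduct_h)
        key = round(m_n, 4)
        if key in seen_masses or m_n >= prec_h - 1.0 or m_n < 40.0:
            continue
        seen_masses.add(key)
        eh_frag = f.exchangeable_h()
        m_d = ion_mz(f.neutral_mass() + eh_frag * DELTA_HD, adduct_d)
        mz_h.append(m_n)
        mz_d.append(m_d)
        truth.fragment_atoms.append(f.atoms)
        truth.fragment_mz_normal.append(m_n)
        truth.fragment_mz_deuterated.append(m_d)

    inten = rng.lognormal(mean=0.0, sigma=intensity_sigma, size=len(mz_h))
    inten_d = inten * rng.lognormal(0.0, 0.2, size=len(mz_h))

    def with_decoys(mzs, intens, upper):
        mzs, intens = list(mzs), list(intens)
        for _ in range(n_decoy_peaks):
            mzs.append(float(rng.uniform(45.0, max(60.0, upper - 2.0))))
            intens.append(float(rng.lognormal(-2.0, 0.5)))
        return np.array(mzs), np.array(intens)

    pk_h, in_h = with_decoys(mz_h, inten, prec_h)
    pk_d, in_d = with_decoys(mz_d, inten_d, prec_d)
    normal = Spectrum(pk_h, in_h, precursor_mz=prec_h, adduct=adduct_h,
                      mode=mode, label="normal")
    deuterated = Spectrum(pk_d, in_d, precursor_mz=prec_d, adduct=adduct_d,
                          mode=mode, label="deuterated")
    pair = SpectrumPair(normal, deuterated, mass_h, mass_d, X=x)
    return pair, truth


#: Heavy-atom compositions cycled through by the instance builder; chosen to
#: resemble small CHNOS metabolites (7-10 heavy atoms, 1-3 heteroatoms).
DEFAULT_COMPOSITIONS: tuple[dict[str, int], ...] = (
    {"C": 6, "O": 2},
    {"C": 6, "N": 1, "O": 1},
    {"C": 7, "O": 2},
    {"C": 6, "N": 2},
    {"C": 7, "N": 1, "O": 1},
    {"C": 6, "O": 3},
    {"C": 7, "N": 2},
    {"C": 6, "N": 1, "O": 2},
    {"C": 7, "O": 1, "S": 1},
    {"C": 8, "O": 2},
)


def make_training_instances(n_instances: int = 50, n_decoys: int = 20,
                            seed: int | None = None,
                            n_decoy_peaks: int = 3,
                            compositions: Sequence[dict[str, int]] | None = None,
                            rel_ppm: float = 5.0, abs_da: float = 0.001,
                            max_depth: int = 2,
                            ) -> tuple[list[TrainingInstance], list[dict]]:
    """Build a seeded training set of scored synthetic spectrum pairs.

    Each instance is one synthetic pair with its true structure plus
    ``n_decoys`` formula-matched decoys, scored by the full pipeline and
    max-normalised.  Returns the instances and a per-instance record
    (truth SMILES, X, candidate count) for reporting.
    """
    rng = np.random.default_rng(seed)
    comps = list(compositions or DEFAULT_COMPOSITIONS)
    instances: list[TrainingInstance] = []
    records: list[dict] = []
    made = 0
    attempts = 0
    while made < n_instances and attempts < n_instances * 10:
        attempts += 1
        comp = comps[made % len(comps)]
        truth_smiles = random_tree_molecule(dict(comp), rng)
        truth = parse_structure(truth_smiles, identifier="truth")
        if count_exchangeable_hydrogens(truth) == 0:
            continue  # want an actual exchange signal in the pair
        decoys = decoy_candidates(truth_smiles, n_decoys, rng)
        if len(decoys) < n_decoys:
            continue
        pair, _ = generate_fixture_pair(truth, n_decoy_peaks=n_decoy_peaks,
                                        seed=rng, max_depth=max_depth)
        cands = [truth] + [parse_structure(s, identifier=f"decoy{i}")
                           for i, s in enumerate(decoys)]
        vectors: list[ScoreVector] = score_candidates(
            cands, pair, rel_ppm=rel_ppm, abs_da=abs_da,
            max_depth=max_depth, dedupe=False)
        raw = np.vstack([v.raw for v in vectors])
        instances.append(TrainingInstance(_normalize_columns(raw), 0,
                                          identifier=truth_smiles))
        records.append({"smiles": truth_smiles, "x": pair.X,
                        "n_candidates": len(vectors)})
        made += 1
    if made < n_instances:
        raise RuntimeError(f"could only build {made}/{n_instances} instances")
    return instances, records
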