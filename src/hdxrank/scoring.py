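"""Per-candidate scoring of a normal/deuterated spectrum pair and ranking.

Four terms are computed for each candidate:

* ``S_MetFrag`` — the plain spectrum-explanation score on the normal
  spectrum (matched-peak intensity, m/z and cleaved-bond BDE penalty);
* ``S_MetFragHD`` — the same rule on the deuterated spectrum using the
  deuterium-adapted fragment masses of the candidate's variants;
* ``S_PairHD`` — the count of fragments that explain a peak in *both*
  spectra with a consistent deuterium count k (k = 0 pairs included);
* ``S_OSN`` — 1 / (|X - eH| + 1), rewarding agreement between the
  candidate's labile-hydrogen count and the observed exchange count.

Each raw term is normalised by its maximum over the candidate list and the
consensus is the weighted sum; ties receive the average rank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    MolecularGraph,
    count_exchangeable_hydrogens,
    parse_structure,
)
from .deuteration import DeuteratedVariant, deuterate_candidate
from .fragmentation import (
    Fragment,
    MzHypothesis,
    all_hypotheses,
    generate_fragments,
)

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "SpectrumPair",
    "PeakMatch",
    "MatchResult",
    "Weights",
    "ScoreVector",
    "match_fragments",
    "score_fragmenter",
    "score_hd_fragmenter",
    "score_pair_hd",
    "score_osn",
    "score_candidates",
    "consensus_rank",
    "filter_candidates",
    "average_ranks",
]

SCORE_NAMES = ("MetFrag", "MetFragHD", "PairHD", "OSN")

#: FragmenterScore constants: intensity exponent, m/z exponent, BDE scale.
INTENSITY_EXP = 0.6
MZ_EXP = 3.0
BDE_SCALE = 500.0


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """A peak list with precursor metadata.

    ``label`` is ``"normal"`` or ``"deuterated"``; peaks are kept sorted by
    m/z.  Missing intensities (centroid-only lists) degenerate to equal
    weights.
    """

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    adduct: str = "M+H"
    mode: str = "+"
    label: str = "normal"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        if self.intensity is None or len(self.intensity) == 0:
            self.intensity = np.ones_like(self.mz)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity lengths differ")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if (self.precursor_mz is not None and len(self.mz)
                and self.precursor_mz > self.mz[-1]):
            log.debug("precursor m/z %.4f above highest peak %.4f",
                      self.precursor_mz, self.mz[-1])

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class SpectrumPair:
    """Normal and deuterated MS/MS spectra of the same compound."""

    normal: Spectrum
    deuterated: Spectrum
    mass_h: float       # neutral precursor mass from the normal run
    mass_d: float       # neutral precursor mass from the deuterated run
    X: int
    residual_ppm: float = 0.0

    @classmethod
    def from_spectra(cls, normal: Spectrum, deuterated: Spectrum,
                     max_residual_ppm: float = 10.0) -> "SpectrumPair":
        from .chem_core import neutral_from_mz
        from .deuteration import determine_X

        if normal.precursor_mz is None or deuterated.precursor_mz is None:
            raise ValueError("both spectra need a precursor m/z")
        mass_h = neutral_from_mz(normal.precursor_mz, normal.adduct)
        adduct_d = deuterated.adduct
        if adduct_d in ("M+H", "M-H"):  # assume deuteron adduct in HDX run
            adduct_d = "M+D" if deuterated.mode == "+" else "M-D"
        mass_d = neutral_from_mz(deuterated.precursor_mz, adduct_d)
        res = determine_X(mass_h, mass_d, max_residual_ppm)
        return cls(normal, deuterated, mass_h, mass_d, res.X,
                   res.residual_ppm)


# ---------------------------------------------------------------------------
# peak matching
# ---------------------------------------------------------------------------

class PeakMatch:
    __slots__ = ("peak_index", "peak_mz", "peak_intensity", "hypothesis",
                 "deviation")

    def __init__(self, peak_index: int, peak_mz: float, peak_intensity: float,
                 hypothesis: MzHypothesis, deviation: float):
        self.peak_index = peak_index
        self.peak_mz = peak_mz
        self.peak_intensity = peak_intensity
        self.hypothesis = hypothesis
        self.deviation = deviation


@dataclass
class MatchResult:
    """Peak-to-fragment assignments for one spectrum.

    ``matches`` holds the single best explanation per matched peak (lowest
    BDE, then smallest deviation) and drives the fragmenter scores;
    ``all_matches`` holds every in-tolerance explanation and drives the
    fragment-pair count, where competing equal-cost explanations must not
    shadow each other.
    """

    matches: list[PeakMatch]
    n_peaks_considered: int
    all_matches: list[PeakMatch] = field(default_factory=list)

    @property
    def matched_indices(self) -> set[int]:
        return {m.peak_index for m in self.matches}


def match_fragments(hypotheses: Sequence[MzHypothesis], spec: Spectrum,
                    rel_ppm: float = 5.0, abs_da: float = 0.001,
                    exclude_precursor: bool = True) -> MatchResult:
    """Match m/z hypotheses against a spectrum.

    A peak matches when ``|m(hyp) - m(peak)| <= max(rel_ppm * m(peak)/1e6,
    abs_da)``.  Among competing hypotheses for one peak the lowest BDE wins,
    then the smallest deviation.  Peaks at or above the precursor m/z are
    excluded (pure precursor signal carries no fragmentation information).
    """
    if rel_ppm <= 0 or abs_da <= 0:
        raise ValueError("tolerances must be positive")
    hyp_mz = np.array([h.mz for h in hypotheses])
    order = np.argsort(hyp_mz)
    hyp_mz_sorted = hyp_mz[order]
    matches: list[PeakMatch] = []
    all_matches: list[PeakMatch] = []
    n_considered = 0
    for i, (mz, inten) in enumerate(zip(spec.mz, spec.intensity)):
        if exclude_precursor and spec.precursor_mz is not None:
            tol_pre = max(rel_ppm * spec.precursor_mz / 1e6, abs_da)
            if mz >= spec.precursor_mz - tol_pre:
                continue
        n_considered += 1
        if len(hyp_mz_sorted) == 0:
            continue
        tol = max(rel_ppm * mz / 1e6, abs_da)
        lo = np.searchsorted(hyp_mz_sorted, mz - tol, side="left")
        hi = np.searchsorted(hyp_mz_sorted, mz + tol, side="right")
        best = None
        best_key = None
        for j in range(lo, hi):
            h = hypotheses[order[j]]
            dev = abs(h.mz - mz)
            all_matches.append(PeakMatch(i, mz, inten, h, dev))
            key = (h.fragment.bde, dev)
            if best is None or key < best_key:
                best, best_key = h, key
        if best is not None:
            matches.append(PeakMatch(i, mz, inten, best, best_key[1]))
    return MatchResult(matches, n_considered, all_matches)


# ---------------------------------------------------------------------------
# scoring terms
# ---------------------------------------------------------------------------

def score_fragmenter(match: MatchResult, spec: Spectrum,
                     intensity_exp: float = INTENSITY_EXP,
                     mz_exp: float = MZ_EXP,
                     bde_scale: float = BDE_SCALE) -> float:
    """Spectrum-explanation score on matched peaks.

    ``sum I_rel^a * mz^b * exp(-BDE/E0)`` over matched peaks, with relative
    intensity so the score is invariant to intensity rescaling.
    """
    if not match.matches:
        return 0.0
    max_i = float(np.max(spec.intensity)) if len(spec) else 1.0
    if max_i <= 0:
        max_i = 1.0
    total = 0.0
    for m in match.matches:
        i_rel = m.peak_intensity / max_i
        total += (i_rel ** intensity_exp) * (m.peak_mz ** mz_exp) \
            * math.exp(-m.hypothesis.fragment.bde / bde_scale)
    return total


#: The deuterated-spectrum score uses the identical calculation rule; the
#: difference lives entirely in the hypothesis masses fed to the matcher.
score_hd_fragmenter = score_fragmenter


def score_pair_hd(match_h: MatchResult, match_d: MatchResult, X: int,
                  eps: float = 0.001) -> int:
    """Count fragments explaining a peak in both spectra consistently.

    A fragment (atom subset) counts once when some normal-spectrum match
    and some deuterated-spectrum match of it agree: the observed peak-mass
    difference m(dP) - m(P) must equal the hypothesis-mass difference —
    k·(m(D)-m(H)) plus the deuteron/proton adduct swap and any dynamic
    H/D shifts — within ``eps``, where ``k``, the deuterium count of the
    deuterated fragment ion, satisfies ``0 <= k <= X``.  A k = 0 pair
    (fragment retains no deuterium) counts too.  Pairing is one-to-one:
    each fragment and each peak contributes to at most one counted pair,
    so the count never exceeds min(|S_H|, |S_D|, #fragments).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    pool_h = match_h.all_matches or match_h.matches
    pool_d = match_d.all_matches or match_d.matches
    by_frag_h: dict[frozenset, list[PeakMatch]] = {}
    for m in sorted(pool_h, key=lambda m: (m.hypothesis.fragment.bde,
                                           m.deviation, m.peak_index)):
        by_frag_h.setdefault(m.hypothesis.fragment.atoms, []).append(m)
    # greedy one-to-one assignment: each fragment and each peak of either
    # spectrum contributes to at most one counted pair
    counted: set[frozenset] = set()
    used_h: set[int] = set()
    used_d: set[int] = set()
    for m in sorted(pool_d, key=lambda m: (m.hypothesis.fragment.bde,
                                           m.deviation, m.peak_index)):
        atoms = m.hypothesis.fragment.atoms
        if (atoms in counted or atoms not in by_frag_h
                or m.peak_index in used_d):
            continue
        if m.hypothesis.n_d > X:
            continue
        for mh in by_frag_h[atoms]:
            if mh.peak_index in used_h:
                continue
            expected = m.hypothesis.mz - mh.hypothesis.mz
            if abs((m.peak_mz - mh.peak_mz) - expected) <= eps:
                counted.add(atoms)
                used_h.add(mh.peak_index)
                used_d.add(m.peak_index)
                break
    return len(counted)


def score_osn(X: int, eh: int) -> float:
    """Exchanged-hydrogens agreement score, ``1 / (|X - eH| + 1)``."""
    if X < 0 or eh < 0:
        raise ValueError("X and eH must be non-negative")
    return 1.0 / (abs(X - eh) + 1)


# ---------------------------------------------------------------------------
# weights and score vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Weights:
    """Consensus weights on the 4-simplex.

    Defaults are the cross-validated values for the four-term consensus
    (~0.109, ~0.004, 0.497, ~0.390).
    """

    metfrag: float = 0.109
    metfrag_hd: float = 0.004
    pair_hd: float = 0.497
    osn: float = 0.390

    def __post_init__(self) -> None:
        v = self.as_array()
        if np.any(v < 0):
            raise ValueError("weights must be non-negative")
        if abs(float(v.sum()) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {v.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.metfrag, self.metfrag_hd, self.pair_hd,
                         self.osn])

    @classmethod
    def from_array(cls, v: Sequence[float]) -> "Weights":
        return cls(*(float(x) for x in v))


@dataclass
class ScoreVector:
    """Raw and normalised scores of one candidate, plus the consensus."""

    identifier: str
    smiles: str
    eh: int
    n_variants: int
    raw: np.ndarray                      # (MetFrag, MetFragHD, PairHD, OSN)
    normalized: np.ndarray | None = None
    consensus: float | None = None
    rank: float | None = None


# ---------------------------------------------------------------------------
# candidate filtering and the ranking pipeline
# ---------------------------------------------------------------------------

def filter_candidates(smiles_list: Sequence[str],
                      identifiers: Sequence[str] | None = None,
                      ) -> list[tuple[str, str]]:
    """Drop salts/mixtures and isotope-labelled structures.

    Multi-component SMILES (non-covalently bound substructures) and
    structures carrying isotope labels other than this package's own
    deuterium marking are removed; removal counts are logged.
    """
    from rdkit import Chem

    if identifiers is None:
        identifiers = [str(i) for i in range(len(smiles_list))]
    kept: list[tuple[str, str]] = []
    n_multi = n_iso = n_bad = 0
    for ident, smi in zip(identifiers, smiles_list):
        mol = Chem.MolFromSmiles(str(smi))
        if mol is None:
            n_bad += 1
            continue
        if len(Chem.GetMolFrags(mol)) > 1:
            n_multi += 1
            continue
        nonstandard = any(
            a.GetIsotope() not in (0, 2 if a.GetAtomicNum() == 1 else 0)
            for a in mol.GetAtoms())
        if nonstandard:
            n_iso += 1
            continue
        kept.append((str(ident), str(smi)))
    if n_multi or n_iso or n_bad:
        log.info("filtered candidates: %d multi-component, %d isotope-"
                 "labelled, %d unparsable", n_multi, n_iso, n_bad)
    return kept


def average_ranks(consensus: np.ndarray) -> np.ndarray:
    """Descending ranks with ties averaged (rank 1 = best)."""
    consensus = np.asarray(consensus, dtype=float)
    n = len(consensus)
    ranks = np.empty(n)
    for i, v in enumerate(consensus):
        greater = int(np.sum(consensus > v))
        ties = int(np.sum(consensus == v))
        ranks[i] = greater + (ties + 1) / 2.0
    return ranks


def _normalize_columns(raw: np.ndarray) -> np.ndarray:
    """Max-normalise each score column; an all-zero column stays zero."""
    norm = raw.astype(float).copy()
    for c in range(norm.shape[1]):
        m = norm[:, c].max()
        if m > 0:
            norm[:, c] /= m
        else:
            norm[:, c] = 0.0
    return norm


def score_candidates(candidates: Sequence[MolecularGraph | str],
                     pair: SpectrumPair,
                     rel_ppm: float = 5.0, abs_da: float = 0.001,
                     eps: float | None = None,
                     max_depth: int = 2, max_shift: int = 2,
                     dedupe: bool = True) -> list[ScoreVector]:
    """Raw score vectors for every candidate against one spectrum pair.

    For candidates with several deuterated variants, the deuterated-spectrum
    scores take the maximum over the variants.  Duplicate structures are
    collapsed by InChIKey first block before scoring when ``dedupe`` is set.
    """
    mols: list[MolecularGraph] = []
    for c in candidates:
        mols.append(parse_structure(c) if isinstance(c, str) else c)
    if not mols:
        raise ValueError("empty candidate list")
    if dedupe:
        seen: set[str] = set()
        unique = []
        for m in mols:
            block = m.inchikey_block()
            if block not in seen:
                seen.add(block)
                unique.append(m)
        mols = unique
    if eps is None:
        eps = max(rel_ppm * (pair.mass_d + 2.0) / 1e6, abs_da)

    vectors: list[ScoreVector] = []
    for mol in mols:
        frags = generate_fragments(mol, max_depth=max_depth)
        eh = count_exchangeable_hydrogens(mol)
        hyps_h = all_hypotheses(frags, mode=pair.normal.mode,
                                deuterated=False, max_shift=max_shift)
        match_h = match_fragments(hyps_h, pair.normal, rel_ppm, abs_da)
        s_metfrag = score_fragmenter(match_h, pair.normal)

        variants = deuterate_candidate(mol, pair.X)
        best_hd = 0.0
        best_pair = 0
        for var in variants:
            hyps_d = all_hypotheses(frags, mode=pair.deuterated.mode,
                                    deuterated=True, variant=var,
                                    max_shift=max_shift)
            match_d = match_fragments(hyps_d, pair.deuterated, rel_ppm,
                                      abs_da)
            best_hd = max(best_hd,
                          score_hd_fragmenter(match_d, pair.deuterated))
            best_pair = max(best_pair,
                            score_pair_hd(match_h, match_d, pair.X, eps))
        s_osn = score_osn(pair.X, eh)
        vectors.append(ScoreVector(
            identifier=mol.identifier or mol.source,
            smiles=mol.source or mol.to_smiles(),
            eh=eh, n_variants=len(variants),
            raw=np.array([s_metfrag, best_hd, float(best_pair), s_osn]),
        ))
    return vectors


def consensus_rank(vectors: Iterable[ScoreVector],
                   weights: Weights | None = None) -> pd.DataFrame:
    """Normalise, combine and rank a scored candidate list.

    Returns a DataFrame sorted by descending consensus with all raw and
    normalised terms exposed (the full results export).
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("empty candidate list")
    w = (weights or Weights()).as_array()
    raw = np.vstack([v.raw for v in vectors])
    norm = _normalize_columns(raw)
    consensus = norm @ w
    ranks = average_ranks(consensus)
    for v, nr, c, r in zip(vectors, norm, consensus, ranks):
        v.normalized, v.consensus, v.rank = nr, float(c), float(r)
    rows = []
    for v in vectors:
        row = {"identifier": v.identifier, "smiles": v.smiles, "eh": v.eh,
               "n_variants": v.n_variants}
        for name, x in zip(SCORE_NAMES, v.raw):
            row[f"raw_{name}"] = x
        for name, x in zip(SCORE_NAMES, v.normalized):
            row[f"norm_{name}"] = x
        row["consensus"] = v.consensus
        row["rank"] = v.rank
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["consensus", "identifier"], ascending=[False, True])
    return df.reset_index(drop=True)
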