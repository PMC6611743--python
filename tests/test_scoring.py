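"""Scoring terms, normalisation, consensus ranking and candidate filtering."""

import numpy as np
import pytest

from hdxrank.chem_core import PROTON_MASS, parse_structure
from hdxrank.deuteration import deuterate_candidate
from hdxrank.fixtures import generate_fixture_pair
from hdxrank.fragmentation import all_hypotheses, generate_fragments
from hdxrank.scoring import (
    MatchResult,
    ScoreVector,
    Spectrum,
    SpectrumPair,
    Weights,
    average_ranks,
    consensus_rank,
    filter_candidates,
    match_fragments,
    score_candidates,
    score_fragmenter,
    score_osn,
    score_pair_hd,
)

MU_SULFATE = "Cc1cc(=O)oc2cc(OS(=O)(=O)O)ccc12"
ISOMER_EH2 = "Cc1cc(=O)oc2cc(O)c(S(=O)(=O)O)cc12"
ISOMER_EH0 = "COS(=O)(=O)Oc1ccc2ccc(=O)oc2c1"


def _hyps(mol, deuterated=False, variant=None, depth=2):
    frags = generate_fragments(mol, depth)
    return all_hypotheses(frags, "+", deuterated, variant)


class TestMatchFragments:
    def test_intact_molecule_matches_at_depth0(self, gallic):
        peak = gallic.neutral_mass() + PROTON_MASS
        spec = Spectrum(np.array([peak]), np.array([1.0]), precursor_mz=None)
        res = match_fragments(_hyps(gallic, depth=0), spec)
        assert len(res.matches) == 1
        assert res.matches[0].hypothesis.fragment.bde == 0.0
        assert res.matches[0].hypothesis.fragment.depth == 0

    def test_peak_outside_tolerance_unmatched(self, gallic):
        abs_da = 0.001
        peak = gallic.neutral_mass() + PROTON_MASS + 1.5 * abs_da
        spec = Spectrum(np.array([peak]), np.array([1.0]), precursor_mz=None)
        res = match_fragments(_hyps(gallic, depth=0), spec,
                              rel_ppm=1.0, abs_da=abs_da)
        assert not res.matches

    def test_fixture_closure_all_peaks_matched(self):
        """Every peak of a zero-decoy synthetic spectrum is explained."""
        pair, _ = generate_fixture_pair(MU_SULFATE, n_decoy_peaks=0, seed=11)
        mol = parse_structure(MU_SULFATE)
        res = match_fragments(_hyps(mol), pair.normal)
        assert len(res.matches) == res.n_peaks_considered == len(pair.normal)

    def test_precursor_region_excluded(self, gallic):
        mz = gallic.neutral_mass() + PROTON_MASS
        spec = Spectrum(np.array([mz]), np.array([1.0]), precursor_mz=mz)
        res = match_fragments(_hyps(gallic, depth=0), spec)
        assert res.n_peaks_considered == 0

    def test_bad_tolerances(self, gallic):
        spec = Spectrum(np.array([100.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            match_fragments([], spec, rel_ppm=0.0)


class TestFragmenterScore:
    def test_no_matches_scores_zero(self):
        spec = Spectrum(np.array([100.0]), np.array([1.0]))
        assert score_fragmenter(MatchResult([], 1), spec) == 0.0

    def test_intensity_scale_invariance(self, gallic):
        pair, _ = generate_fixture_pair(MU_SULFATE, n_decoy_peaks=0, seed=3)
        mol = parse_structure(MU_SULFATE)
        hyps = _hyps(mol)
        s1 = score_fragmenter(match_fragments(hyps, pair.normal), pair.normal)
        doubled = Spectrum(pair.normal.mz, pair.normal.intensity * 2,
                           precursor_mz=pair.normal.precursor_mz)
        s2 = score_fragmenter(match_fragments(hyps, doubled), doubled)
        assert s1 == pytest.approx(s2)
        assert s1 > 0

    def test_superset_of_explained_peaks_scores_higher(self):
        """With equal BDEs, explaining strictly more peaks wins."""
        mol = parse_structure("CCO")
        frag = generate_fragments(mol, 0)[0]
        spec = Spectrum(np.array([80.0, 120.0]), np.array([1.0, 1.0]),
                        precursor_mz=None)
        from hdxrank.fragmentation import MzHypothesis

        h1 = MzHypothesis(80.0, 0, 0, 0, 0, frag)
        h2 = MzHypothesis(120.0, 0, 0, 0, 0, frag)
        small = match_fragments([h1], spec)
        big = match_fragments([h1, h2], spec)
        assert score_fragmenter(big, spec) > score_fragmenter(small, spec)

    def test_hd_score_equals_plain_for_undeuterated_candidate(self):
        """With no deuterium anywhere and S_D = S_H the two scores agree."""
        mol = parse_structure("CCOC", "ether")  # eH = 0
        pair, _ = generate_fixture_pair(mol, n_decoy_peaks=0, seed=7)
        assert pair.X == 0
        spec = pair.normal
        match_n = match_fragments(_hyps(mol), spec)
        var = deuterate_candidate(mol, 0)[0]
        match_d = match_fragments(_hyps(mol, True, var), spec)
        s_plain = score_fragmenter(match_n, spec)
        s_hd = score_fragmenter(match_d, spec)
        assert s_plain > 0
        assert s_hd == pytest.approx(s_plain)

    def test_empty_deuterated_spectrum_scores_zero(self, gallic):
        var = deuterate_candidate(gallic, 4)[0]
        spec = Spectrum(np.array([]), np.array([]), precursor_mz=None,
                        label="deuterated")
        res = match_fragments(_hyps(gallic, True, var), spec)
        assert score_fragmenter(res, spec) == 0.0


class TestPairScore:
    def test_disjoint_spectra_count_zero(self, gallic):
        s_h = Spectrum(np.array([60.0]), np.array([1.0]), precursor_mz=None)
        s_d = Spectrum(np.array([500.0]), np.array([1.0]), precursor_mz=None)
        var = deuterate_candidate(gallic, 4)[0]
        mh = match_fragments(_hyps(gallic), s_h)
        md = match_fragments(_hyps(gallic, True, var), s_d)
        assert score_pair_hd(mh, md, 4) == 0

    def test_worked_example_pairs(self, ipd):
        """Precursor, ND3-loss and fully H/D-stripped fragment all pair."""
        from hdxrank.chem_core import DELTA_HD, MASS, ion_mz

        M = ipd.neutral_mass()
        p1 = M + PROTON_MASS
        p2 = p1 - (MASS["N"] + 3 * MASS["H"])             # - NH3
        p3 = (M - 2 * MASS["N"] - 4 * MASS["H"]) + PROTON_MASS  # C10H17+
        d1 = ion_mz(M + 4 * DELTA_HD, "M+D")
        d2 = d1 - (MASS["N"] + 3 * MASS["D"])             # - ND3
        s_h = Spectrum(np.array([p1, p2, p3]), np.ones(3), precursor_mz=None)
        s_d = Spectrum(np.array([d1, d2, p3]), np.ones(3), precursor_mz=None)
        var = deuterate_candidate(ipd, 4)[0]
        mh = match_fragments(_hyps(ipd), s_h)
        md = match_fragments(_hyps(ipd, True, var), s_d)
        assert score_pair_hd(mh, md, X=4, eps=0.002) >= 3

    def test_k_exceeding_x_not_counted(self, ipd):
        from hdxrank.chem_core import DELTA_HD, ion_mz

        M = ipd.neutral_mass()
        s_h = Spectrum(np.array([M + PROTON_MASS]), np.ones(1),
                       precursor_mz=None)
        s_d = Spectrum(np.array([ion_mz(M + 4 * DELTA_HD, "M+D")]),
                       np.ones(1), precursor_mz=None)
        var = deuterate_candidate(ipd, 4)[0]
        mh = match_fragments(_hyps(ipd), s_h)
        md = match_fragments(_hyps(ipd, True, var), s_d)
        assert score_pair_hd(mh, md, X=4, eps=0.002) >= 1
        # the same deuterated ion carries 4 D, inadmissible when X < 4
        assert score_pair_hd(mh, md, X=3, eps=0.002) == 0

    def test_count_bounded_by_peaks(self):
        pair, _ = generate_fixture_pair(MU_SULFATE, n_decoy_peaks=0, seed=2)
        mol = parse_structure(MU_SULFATE)
        var = deuterate_candidate(mol, pair.X)[0]
        mh = match_fragments(_hyps(mol), pair.normal)
        md = match_fragments(_hyps(mol, True, var), pair.deuterated)
        n_frag = len(generate_fragments(mol, 2))
        count = score_pair_hd(mh, md, pair.X)
        assert 0 < count <= min(len(pair.normal), len(pair.deuterated),
                                n_frag)


class TestOsnScore:
    @pytest.mark.parametrize("x,eh,expected", [
        (4, 4, 1.0), (1, 3, 1 / 3), (0, 0, 1.0), (2, 0, 1 / 3), (5, 1, 0.2),
    ])
    def test_values(self, x, eh, expected):
        assert score_osn(x, eh) == pytest.approx(expected)

    def test_strictly_decreasing_in_deviation(self):
        vals = [score_osn(3, eh) for eh in range(10)]
        assert vals[3] == 1.0
        assert all(vals[i] > vals[i + 1] for i in range(3, 9))
        assert all(0 < v <= 1 for v in vals)


class TestConsensusRank:
    def _vectors(self, raw):
        return [ScoreVector(str(i), "", 0, 1, np.asarray(r, float))
                for i, r in enumerate(raw)]

    def test_single_candidate(self):
        df = consensus_rank(self._vectors([[5.0, 2.0, 3.0, 1.0]]))
        assert df["rank"][0] == 1.0
        assert df["consensus"][0] == pytest.approx(1.0)

    def test_rescaling_raw_column_is_invariant(self):
        raw = [[5.0, 2.0, 3.0, 1.0], [2.0, 8.0, 1.0, 0.5]]
        df1 = consensus_rank(self._vectors(raw))
        scaled = [[r[0] * 100, r[1], r[2] * 0.01, r[3]] for r in raw]
        df2 = consensus_rank(self._vectors(scaled))
        assert np.allclose(df1["consensus"], df2["consensus"])

    def test_metfrag_only_weights_reduce_to_plain_ranking(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(size=(8, 4))
        vecs = self._vectors(raw)
        df = consensus_rank(vecs, Weights(1, 0, 0, 0))
        plain_order = np.argsort(-raw[:, 0])
        assert [int(i) for i in df["identifier"]] == list(plain_order)

    def test_ties_share_average_rank(self):
        raw = [[1.0, 1.0, 1.0, 1.0]] * 3
        df = consensus_rank(self._vectors(raw))
        assert set(df["rank"]) == {2.0}  # (3 + 1) / 2

    def test_zero_column_stays_zero(self):
        raw = [[0.0, 0.0, 1.0, 1.0], [0.0, 0.0, 0.5, 0.5]]
        df = consensus_rank(self._vectors(raw))
        assert (df["norm_MetFrag"] == 0).all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            consensus_rank([])

    def test_consensus_rescues_truth_from_plain_score_loss(self):
        """A decoy winning the plain fragmenter score is outranked once the
        HDX terms enter the weighted consensus (the workflow's key benefit)."""
        raw = np.array([
            #  MetFrag  MetFragHD  PairHD  OSN
            [8.0, 9.0, 20.0, 1.0],    # truth: eH matches X
            [10.0, 10.0, 14.0, 0.5],  # decoy with the best plain score
            [6.0, 7.0, 10.0, 0.5],
        ])
        vecs = self._vectors(raw)
        plain = consensus_rank(vecs, Weights(1, 0, 0, 0))
        assert plain["identifier"][0] == "1"
        full = consensus_rank(vecs, Weights(0.109, 0.004, 0.497, 0.390))
        assert full["identifier"][0] == "0"
        assert full[full["identifier"] == "0"]["rank"].iloc[0] == 1.0


class TestPipeline:
    def test_sulfate_scenario_correct_candidate_top1(self):
        """Structure-level reconstruction: the sulfate ester with eH = 1
        outranks its eH = 2 and eH = 0 constitutional isomers at X = 1."""
        pair, _ = generate_fixture_pair(MU_SULFATE, n_decoy_peaks=0, seed=5)
        assert pair.X == 1
        cands = [parse_structure(MU_SULFATE, "truth"),
                 parse_structure(ISOMER_EH2, "isomer_eh2"),
                 parse_structure(ISOMER_EH0, "isomer_eh0")]
        vecs = score_candidates(cands, pair)
        df = consensus_rank(vecs, Weights(0.109, 0.004, 0.497, 0.390))
        assert df["identifier"][0] == "truth"
        assert df["rank"][0] == 1.0
        osn = {r.identifier: r.raw_OSN for r in df.itertuples()}
        assert osn == {"truth": 1.0, "isomer_eh2": 0.5, "isomer_eh0": 0.5}

    def test_duplicate_structures_collapsed(self):
        pair, _ = generate_fixture_pair(MU_SULFATE, n_decoy_peaks=0, seed=5)
        vecs = score_candidates([MU_SULFATE, MU_SULFATE, ISOMER_EH0], pair)
        assert len(vecs) == 2


class TestFilterCandidates:
    def test_salt_removed(self):
        kept = filter_candidates(["[Na+].CC(=O)[O-]", "CCO"])
        assert [s for _, s in kept] == ["CCO"]

    def test_isotope_labelled_removed(self):
        kept = filter_candidates(["[13CH4]", "CCO", "[2H]OCC"])
        assert {s for _, s in kept} == {"CCO", "[2H]OCC"}

    def test_ordinary_organic_retained(self):
        assert len(filter_candidates(["CC(N)C(=O)O"])) == 1


def test_average_ranks():
    assert list(average_ranks(np.array([3.0, 1.0, 2.0]))) == [1.0, 3.0, 2.0]
    assert list(average_ranks(np.array([2.0, 2.0, 1.0]))) == [1.5, 1.5, 3.0]
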