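"""Combinatorial fragmenter and H/D-aware m/z hypotheses."""

import pytest

from hdxrank.chem_core import DELTA_HD, MASS, monoisotopic_mass, parse_structure
from hdxrank.deuteration import DeuteratedVariant, deuterate_candidate
from hdxrank.fragmentation import (
    bond_dissociation_energy,
    fragment_mz_hypotheses,
    generate_fragments,
)

from conftest import brute_force_fragments


def _subsets(frags):
    return {f.atoms for f in frags}


class TestGenerateFragments:
    def test_ethanol_depth1(self):
        mol = parse_structure("CCO")
        frags = generate_fragments(mol, max_depth=1)
        formulas = sorted(f.formula().render() for f in frags)
        # two acyclic cleavages: {CH3 | CH2OH} and {CH3CH2 | OH}
        assert formulas == ["C2H5", "C2H6O", "CH3", "CH3O", "HO"]

    def test_depth0_only_intact(self, gallic):
        frags = generate_fragments(gallic, max_depth=0)
        assert len(frags) == 1
        assert frags[0].bde == 0.0
        assert frags[0].atoms == frozenset(range(gallic.n_atoms))

    def test_benzene_ring_opening(self):
        mol = parse_structure("c1ccccc1")
        frags = generate_fragments(mol, max_depth=1)
        # each of the 15 ring-bond pairs splits the ring into two chains
        sizes = sorted(len(f.atoms) for f in frags if len(f.atoms) < 6)
        assert sizes == sorted(
            s for k in range(1, 6) for s in (k,) * 6)

    def test_empty_molecule_rejected(self):
        from hdxrank.chem_core import MolecularGraph

        with pytest.raises(ValueError):
            generate_fragments(MolecularGraph([], []), 1)

    @pytest.mark.parametrize("smiles", [
        "CCO", "CC(N)C(=O)O", "c1ccccc1", "c1ccncc1", "CC1CCC1",
        "OC(=O)c1ccccc1", "CN(C)C(=N)NC(=N)N", "CC(C)CC(=O)O",
        "C1CC1CCO", "OCC1OC(O)C(O)C1O",
    ])
    @pytest.mark.parametrize("depth", [1, 2])
    def test_oracle_equivalence(self, smiles, depth):
        """Fragments match exhaustive cleavage enumeration, subsets and BDE."""
        mol = parse_structure(smiles)
        assert mol.n_atoms <= 12
        frags = generate_fragments(mol, max_depth=depth)
        oracle = brute_force_fragments(
            mol, depth, lambda i: bond_dissociation_energy(mol, i))
        assert _subsets(frags) == set(oracle)
        for f in frags:
            assert f.bde == pytest.approx(oracle[f.atoms])

    def test_bde_additive_and_nonnegative(self, ipd):
        frags = generate_fragments(ipd, max_depth=2)
        intact = frozenset(range(ipd.n_atoms))
        for f in frags:
            assert f.bde >= 0.0
            if f.atoms != intact:
                assert f.bde > 0.0
                assert f.depth >= 1

    def test_aromatic_bde_scaled(self):
        mol = parse_structure("c1ccccc1")
        assert bond_dissociation_energy(mol, 0) == pytest.approx(1.5 * 346.0)


class TestMzHypotheses:
    def test_normal_mode_h_shifts(self):
        mol = parse_structure("CCO")
        frag = [f for f in generate_fragments(mol, 1)
                if f.formula().render() == "C2H5"][0]
        hyps = fragment_mz_hypotheses(frag, mode="+", deuterated=False)
        shifts = sorted(h.h_shift for h in hyps)
        assert shifts == [-2, -1, 0, 1, 2]
        base = [h for h in hyps if h.h_shift == 0][0]
        plus1 = [h for h in hyps if h.h_shift == 1][0]
        assert plus1.mz - base.mz == pytest.approx(MASS["H"], abs=1e-9)

    def test_metolachlor_d6_fragment_shift(self):
        """The methoxypropyl fragment carrying all six parent deuteriums."""
        frag_h = monoisotopic_mass("C4H9O+")
        frag_d = monoisotopic_mass("C4H3D6O+")
        assert frag_h == pytest.approx(73.0648, abs=5e-5)
        assert frag_d - frag_h == pytest.approx(6 * DELTA_HD, abs=1e-5)

    def test_full_exchange_shifts_by_retained_sites(self, gallic):
        frags = generate_fragments(gallic, 1)
        var = deuterate_candidate(gallic, 4)[0]
        for f in frags:
            hyps_n = fragment_mz_hypotheses(f, "+", deuterated=False)
            hyps_d = fragment_mz_hypotheses(f, "+", deuterated=True,
                                            variant=var)
            base_n = [h for h in hyps_n if h.h_shift == 0][0]
            eh_frag = sum(1 for a, _ in var.sites if a in f.atoms)
            base_d = [h for h in hyps_d
                      if h.h_shift == 0 and h.d_shift == 0 and h.k == 0][0]
            # retained exchanges plus the deuteron-for-proton adduct swap
            assert base_d.mz - base_n.mz == pytest.approx(
                (eh_frag + 1) * DELTA_HD, abs=1e-9)

    def test_no_deuterium_fragment_coincides_with_normal(self):
        """A fragment retaining no deuterium can appear at its normal m/z."""
        mol = parse_structure("NCCCC")  # one amine
        frags = generate_fragments(mol, 1)
        frag = [f for f in frags if all(
            mol.atoms[i].element == "C" for i in f.atoms)][0]
        var = deuterate_candidate(mol, 2)[0]
        hyps_n = {round(h.mz, 6) for h in
                  fragment_mz_hypotheses(frag, "+", deuterated=False)}
        hyps_d = fragment_mz_hypotheses(frag, "+", deuterated=True,
                                        variant=var)
        coincident = [h for h in hyps_d if round(h.mz, 6) in hyps_n
                      and h.n_d == 0]
        assert coincident

    def test_variable_deuterium_ladder(self):
        mol = parse_structure("CCOC")  # eH = 0, variable exchange only
        var = deuterate_candidate(mol, 2)[0]
        assert var.vh == 2
        frags = generate_fragments(mol, 1)
        intact = [f for f in frags
                  if f.atoms == frozenset(range(mol.n_atoms))][0]
        ks = {h.k for h in fragment_mz_hypotheses(intact, "+", True, var)}
        assert ks == {0, 1, 2}

    def test_deuterated_minus_normal_lattice(self, gallic):
        """HDX hypothesis masses differ from normal ones by integer
        combinations of the exchange increment and H/D unit masses."""
        frags = generate_fragments(gallic, 1)
        var = deuterate_candidate(gallic, 4)[0]
        for f in frags[:5]:
            normal0 = [h for h in
                       fragment_mz_hypotheses(f, "+", deuterated=False)
                       if h.h_shift == 0][0]
            for h in fragment_mz_hypotheses(f, "+", True, var):
                diff = h.mz - normal0.mz
                eh_frag = sum(1 for a, _ in var.sites if a in f.atoms)
                expected = ((eh_frag + h.k + 1) * DELTA_HD
                            + h.h_shift * MASS["H"] + h.d_shift * MASS["D"])
                assert diff == pytest.approx(expected, abs=1e-9)

    def test_mode_validation(self, gallic):
        frag = generate_fragments(gallic, 0)[0]
        with pytest.raises(ValueError):
            fragment_mz_hypotheses(frag, mode="x")
        with pytest.raises(ValueError):
            fragment_mz_hypotheses(frag, mode="+", deuterated=True)
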