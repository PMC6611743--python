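# Methods

## Model and assumptions

The package models hydrogen-deuterium exchange (HDX) in LC-MS/MS as a
purely topological process: every hydrogen bound to O, N or S ("easily
exchangeable", eH) is assumed to exchange completely on the LC timescale,
and no other hydrogen exchanges in solution. Deviations seen in practice —
keto-enol tautomerism, gas-phase exchange in the source, sterically
hindered or intramolecularly H-bonded labile protons, wrong isotopic-peak
selection during acquisition — are handled by *scoring*, never by hard
elimination of candidates. Amide and amine N–H are treated identically;
there is no pKa- or kinetics-based refinement, and back-exchange is not
modelled.

Deuterium is represented as a per-atom label count on the heavy-atom graph
rather than as an explicit graph node. Fragmentation therefore operates on
an identical skeleton for a candidate and all of its deuterated variants,
and a variant is fully described by its set of exchanged labile-H sites
plus a count vH of position-unknown deuteriums.

Masses are monoisotopic: H = 1.007825, D = 2.014102 (ΔHD = 1.006277 Da),
electron = 0.00054858 Da, so the proton and deuteron adducts are 1.007276
and 2.013553 Da. Supported adducts are [M+H]⁺/[M+D]⁺/[M−H]⁻/[M−D]⁻ only —
positive HDX features are interpreted as deuteron adducts, negative ones as
deuteron abstractions. ¹³C = 13.003355 Da, giving the 0.00292 Da
separation between a ¹³C isotopologue and a monodeuterated ion that limits
untargeted pairing at low resolving power.

## Exchange count and deuterated variants

X = round((m_D − m_H)/ΔHD) from the neutral precursor masses. The integer
fit's residual is reported in ppm of the deuterated mass; above a
configurable threshold (default 10 ppm) the pair is flagged but kept,
because a wrong isotopic-peak pick corrupts X without invalidating the
spectra. Variant generation follows the three cases (exact / deficit /
surplus): surplus enumerates binomial(eH, X) site subsets, counting
hydrogen sites rather than heteroatoms so an NH₂ contributes two sites. A
cap (default eH ≤ 20) guards the combinatorial case; above it a single
variant carrying all X deuteriums as position-unknown is used and a warning
logged.

## Fragmentation

Fragments are connected heavy-atom subsets produced by recursive cleavage
events — one acyclic (bridge) bond, or one pair of ring bonds that actually
splits the current fragment — to a default depth of two events. Each subset
keeps the minimal cumulative BDE over all routes, which makes the output
independent of cleavage order (verified against an exhaustive enumeration
oracle in the tests). The BDE table is a compact built-in list of homolytic
bond energies on the kJ/mol scale (C–C 346, C–N 305, C–O 358, C–S 272,
doubles/triples accordingly), aromatic bonds 1.5× the single-bond entry and
348 for missing pairs; since the fragmenter score is max-normalised within
a candidate list, these values act only as a relative penalty and their
absolute calibration is uncritical.

Hydrogen bookkeeping at a cut is deliberately naive: a fragment keeps the
hydrogens and deuterium labels of its retained atoms, and valence
completion is expressed through dynamic mass shifts instead of radical
chemistry. In normal spectra a fragment may gain or lose up to two
hydrogens. In deuterated spectra the retained exchanged sites add
eH(frag)·ΔHD, variable deuteriums add k·ΔHD up to the fragment's
non-exchangeable-H capacity, ionisation transfers a deuteron, and the
dynamic shifts may add or remove hydrogens *or* deuteriums independently
(|h| + |d| ≤ 2). Allowing mixed-sign H/D shifts is a deliberate design
choice: deuterium is mobile in the collision cell, and a fragment ion that
lost all its deuteriums (e.g. a terminal C₁₀H₁₇⁺ after two ND₂/ND₃ losses)
must be able to appear at exactly its normal-spectrum m/z even though the
charging particle was a deuteron. Both shift components are recorded on
every hypothesis so each explanation remains auditable.

## Scoring

The fragmenter score is Σ I_rel^0.6 · (m/z)³ · exp(−BDE/E₀) over matched
peaks with E₀ = 500 (all three constants configurable); only ordering
properties of this rule are relied on, not its absolute value. A peak
matches a hypothesis within max(rel_ppm·m/z, abs_Da) — defaults 5 ppm /
0.001 Da, with 10 ppm / 0.01 Da as the documented lower-resolution setting.
Among competing explanations the lowest BDE wins, then the smallest
deviation. Peaks at or above the precursor m/z are excluded; missing
intensities degenerate to equal weights.

The fragment-pair score counts fragments that explain one peak in each
spectrum consistently. Consistency is checked as *deviation agreement*: the
observed peak-mass difference must equal the hypothesis-mass difference —
k·ΔHD plus the deuteron/proton adduct swap plus any dynamic shifts — within
ε (default: the combined matching tolerance). The deuterium count k of the
deuterated fragment ion must satisfy k ≤ X, and k = 0 pairs count.
Formulating the check on hypothesis differences rather than directly on
k·ΔHD is required for the precursor pair (whose ions differ by (X+1)·ΔHD
because of the adduct swap) and for deuterium-stripped fragments (which
need a −D/+H swap); it reduces to the plain k·ΔHD relation whenever adduct
and shifts cancel. Pairing is one-to-one — each fragment and each peak
contributes at most once — so the count is bounded by
min(|S_H|, |S_D|, #fragments). Pairs are not intensity-weighted.

S_OSN = 1/(|X − eH| + 1) uses the pair-level X unchanged. Each raw term is
divided by its maximum over the (InChIKey-first-block-deduplicated)
candidate list, an all-zero column staying zero; the deuterated-spectrum
terms take the maximum over a candidate's variants before normalisation.
The consensus is the weighted sum under weights on the 4-simplex; default
weights (0.109, 0.004, 0.497, 0.390). Tied consensus values share the
average rank.

## Weight fitting

Weight candidates are drawn uniformly from the simplex via normalised
i.i.d. exponential variates (exact Dirichlet(1,1,1,1)); 1000 draws by
default. The draw maximising the training top-1 count wins, ties broken by
top-3 and then draw order, which makes the search deterministic under a
seed. Cross-validation randomises the fold assignment under the same seed;
restricting the search to a subset of terms pins excluded weights to
exactly zero. Held-out top-k counts are pooled over folds (not averaged per
fold) and reported with percentages.

## Synthetic data

The fixture generator emulates paired acquisitions of a known standard: it
fragments the true structure, turns the cheapest (lowest-BDE) proper
fragments into peaks — the normal spectrum at proton-adduct masses, the
deuterated spectrum shifted by each fragment's retained labile hydrogens
and ionised by deuteron — draws log-normal intensities (σ = 1, with a small
σ = 0.2 perturbation between runs) and adds a few low-intensity unexplained
decoy peaks (default 3 per spectrum). Decoy *candidates* are random
valence-constrained heavy-atom trees over the true molecule's element
multiset: every such tree is a constitutional isomer with the same
molecular formula, while its labile-H count varies with how many
heteroatoms end up internal (ether/tertiary amine) versus terminal
(hydroxyl/primary amine) — exactly the ambiguity the HDX terms are meant to
resolve. The standard benchmark uses 50 pairs with 20 decoys each over
small CHNOS compositions (7–10 heavy atoms), sizes chosen to represent a
realistic per-formula candidate load while keeping the benchmark
desk-scale.

What passing on fixtures does *not* show: real spectra contain
rearrangement fragments, isotope peaks, co-isolated contaminants,
intensity-dependent noise and retention-time shifts between the normal and
deuterated runs; decoy trees are acyclic and single-bonded, so
ring-isomerism is not probed; and the generator's peaks are exactly
explainable by construction, which flatters absolute match rates. The
benchmark therefore supports relative claims (the HDX terms do not degrade,
and typically improve, top-1 identification) rather than absolute
identification rates on real data.

## Numerical choices and degenerate inputs

Exact integer arithmetic is used for variant counting; mass comparisons use
absolute tolerances stated per test (1e−9 to 1e−5 Da). A zero maximum in a
score column normalises to zero rather than NaN. An empty candidate list,
empty molecule, non-positive tolerance or negative X raises immediately.
Duplicate fragment subsets keep the minimal BDE; duplicate candidates
collapse by InChIKey connectivity block before scoring. File outputs are
written atomically (temp file + rename), so a failed run never leaves a
partial results file.

## Known limitations

Kinetic/partial exchange and back-exchange are out of scope; adducts other
than protonation/deuteronation are unsupported; fragmentation is purely
combinatorial (no mechanistic or rearrangement rules, scrambling handled
only through the ±H/±D tolerance); retention-time behaviour of the
deuterated run is exposed only as a pairing window parameter; and the
built-in BDE table is approximate by design.
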