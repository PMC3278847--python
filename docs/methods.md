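# Methods

## Binding-site annotation from hydrogen-bond geometry

A protein residue is annotated RNA-binding when at least one hydrogen bond
links it to the partner RNA chain. Candidate bonds are every donor–acceptor
pairing in both directions (protein donor → RNA acceptor and RNA donor →
protein acceptor); a bond is accepted when all four criteria hold as strict
inequalities: d(D–A) < 3.9 Å, d(H–A) < 2.5 Å, ∠D–H–A > 90° (at H) and
∠H–A–AA > 90° (at A, AA the acceptor antecedent). Angles are measured at
the middle-named atom, in degrees. Donor/acceptor assignments come from a
fixed internal dictionary: protein backbone N (except proline) and the
side-chain N/O/S donors of R, N, Q, H, K, S, T, W, Y, C; backbone O and the
side-chain acceptors of D, E, N, Q, H, S, T, Y; RNA base amino/imino
nitrogens plus sugar O2′/O3′ as donors; base N/O sites plus OP1, OP2, O2′,
O3′, O4′, O5′ as acceptors. Each acceptor carries one canonical antecedent
atom; acceptors whose antecedent is missing from the coordinates are
skipped because the H–A–AA angle cannot be measured.

**Hydrogen placement.** Crystal structures usually lack hydrogens, and the
placement used by the original annotation software cannot be recovered.
Two modes are provided. `explicit` uses deposited hydrogens (atoms of
element H within 1.3 Å of the donor heavy atom); when a donor–acceptor pair
qualifies through more than one hydrogen, the bond records the hydrogen with
the smallest H–A distance. `toward_acceptor` places H at 1.0 Å from the
donor along the donor→acceptor direction, which makes ∠D–H–A exactly 180°
(the criterion becomes vacuous) and d(H–A) = d(D–A) − 1; it is deterministic
and conservative. The default is `toward_acceptor`; synthetic fixtures
carry explicit hydrogens and are analysed with `explicit`.

**Parsing.** PDB fixed-column records, model 1 only; alternate locations
keep the highest-occupancy conformer (ties: altloc A, then first); legacy
RNA atom spellings (O2\*, O1P) are canonicalised. Residues outside the 20
standard amino acids or A/C/G/U (modified nucleotides, ligands, water) are
typed `other` and excluded from sequences and detection, because the
20+4-letter alphabet of the propensity statistic admits nothing else.
Water-mediated bridges are not considered. Candidate pairs are pruned with
a k-d tree on the donor–acceptor distance; tests verify equality with an
unpruned all-pairs scan.

## Interaction propensity of amino-acid triplets

For triplet *t* and nucleotide *b*,

IP_tb = [ S_tb / N_PR ] / [ (N_t/N_P) · (N_b/N_R) ],

with S_tb the sum over hydrogen bonds between *t* and *b* of 1/d_proj,
where d_proj = d(H–A)·cos∠D–A–H is the projection of the H–A separation on
the D–A axis. Bonds whose hydrogen projects behind the acceptor
(∠D–A–H ≥ 90°) are excluded with a warning. Counts are *instance* counts:
N_t and N_P count triplet occurrences across all protein sequences of the
input pairs (a protein appearing with several RNA partners contributes each
time), N_b and N_R count nucleotide occurrences, and N_PR counts triplet
instances with at least one qualifying contact, once each regardless of
bond multiplicity. A contact is attributed to the triplet centred on the
bonded residue; contacts on terminal residues (no complete centred triplet)
are skipped and counted. If one triplet instance contacts two nucleotides
of the same type, both 1/d_proj terms accumulate — the statistic is a sum
over bonds. The table always materializes all 32,000 keys, zero-filled.

The exact normalization order (divide by N_PR before or after the marginal
ratio) is a design choice; the observed-over-expected form above uses each
named count exactly once and is isolated in `build_table` for easy
revision. Note that the normalization rewards *specificity*: a rare
triplet with one close contact can out-score a frequent, moderately
enriched one, which is why parameter-recovery tests compare an enriched
triplet against a frequency-matched control rather than the top of the
table.

## Feature encoding

Vector layout for an odd window w ≥ 3 (length 9w + 17):

* L = min(n/1000, 1) — protein length with a cap of 1000 residues, chosen
  so typical chains map into (0, 1] without saturating;
* C = 20 composition frequencies (count/n; the sentinel X is excluded from
  numerators, so the block sums to 1 for X-free sequences);
* R_b = (Σ_{j: rna[j]=b} j/n) / Σ_b′ raw_b′ — per-nucleotide positional
  mass of the partner RNA, normalized to sum to 1 so identical proteins
  bound to different RNAs encode differently;
* per window slot: N = i/n (1-based normalized position), Kyte–Doolittle
  hydropathy, theoretical maximum accessible surface area (Tien et al.
  2013 values), monoisotopic residue mass — each min–max normalized over
  the 20-residue alphabet — and side-chain pKa/14 (non-ionizable → 0);
* for the w − 2 internal slots additionally IP_A..IP_U of the triplet
  centred on the slot, divided by the table maximum and clipped to [0, 1].

The two outermost window positions are "terminal slots" without IP
elements (no complete centred triplet fits). Window positions beyond the
sequence are padded with X and all-zero local elements, so a length-n
protein always yields exactly n vectors. The label is +1 iff the window's
middle residue is binding. Even windows and w = 1 are rejected: the
blockwise layout (21 + 4 + 5·2 = 30 elements minimum) is inconsistent with
9·1 + 17 = 26, so no w = 1 encoding is defined.

## Redundancy reduction

Vectors are keyed by (values rounded to 6 decimals, label); the first
occurrence per key is kept, making runs reproducible given deterministic
upstream ordering. `n_common` counts distinct value keys observed with both
labels — these common vectors are all retained. Rounding before comparison
makes equality platform-independent and matches the 6-decimal TSV
serialization.

## Classification and evaluation

scikit-learn `SVC`, RBF kernel (implied by the γ parameterization), C = 10,
γ = 1/#features, class weights {+1: n_neg/n_pos, −1: 1} recomputed per
training fold. Cross-validation is stratified by label (fold construction
is otherwise unspecified; grouping by protein chain would be an
alternative) with a fixed seed, and metrics are computed on the pooled
(micro-averaged) held-out confusion. Predictions are hard ±1 labels; no
probability calibration.

Metrics: Sn, Sp, Pr, Ac as percentages; NP = (Sn+Sp)/2;
Fm = 2·Sn·Sp/(Sn+Sp) — the harmonic mean of sensitivity and specificity,
*not* the classic F1 of precision and recall, which is inconsistent with
the reference evaluation rows the formulas were validated against; CC is
the Matthews correlation. Zero denominators yield `None`, never division
faults. Printed percentages are quantized in decimal at one decimal with
binary-float noise cleaned at nine decimals first and ties rounded toward
zero; averages of one-decimal percentages frequently land exactly on the
half-unit boundary, and the reference tables (computed from unrounded
inputs) are not uniformly recoverable from printed values under any tie
rule — tie-toward-zero reproduces every row used for validation.

## Synthetic data

`synth_complex` realizes each requested bond geometry analytically: the
acceptor (OP1) at the requested d(D–A) from the donor (backbone N), the
hydrogen placed by the law of cosines so ∠D–H–A is exact, and the
antecedent (P) by in-plane rotation so ∠H–A–AA is exact. Accept/reject
under the criteria is therefore known in closed form and the generator
returns the expected label vector. Residues sit 30 Å apart so no unplanned
pairing can pass the distance thresholds; a nucleotide hosts at most one
bond; a residue at most two, in orthogonal directions (a hydrogen planted
for one bond then always misses the other bond's acceptor by more than
2.5 Å since √(1 + d²) > 2.5 for d > 2.4); angle-invalid bonds get an
exclusive residue because an extra hydrogen on a shared donor could rescue
the geometry. Decoy contacts are distance-invalid placements (4.0–4.8 Å)
on unused residue/nucleotide pairs. Chains are backbone-only (N/CA and
P/OP1): the generator emulates contact geometry and label structure, not
stereochemistry, so passing tests demonstrate correctness of detection and
bookkeeping — not performance on real, fully atomistic complexes, where
side-chain donors dominate and hydrogens must be inferred.

`synth_pairs` generates random sequences (protein 30–80 residues, RNA
15–40 nucleotides by default) with per-residue contact probability
min(1, base_rate·multiplier(triplet)), base rate 0.02, enriched triplets
implanted once per sequence, and d_proj ~ U(1.5, 3.0) Å — the typical
range of projected H-bond distances. Real data differ in sequence
composition bias, contact clustering along interfaces, and shared
propensity structure across complexes; tests on these pairs validate the
counting statistics, not biological signal strength.

All randomness flows from one integer seed per spec through
`numpy.random.default_rng`; generators are pure functions of their specs.

## Problem sizes and numerical notes

The test suite runs at desk scale: 100-complex detection sweeps with 8–20
residues per chain, propensity sets of ≤200 pairs, redundancy oracles on
≤500 vectors, and classifier fixtures of 100–300 points — sizes chosen so
each oracle comparison is exhaustive and the whole suite completes in a few
seconds. Headline performance numbers from the original full-scale
structure-derived datasets (thousands of interacting pairs) are not
reproducible from synthetic data and are not claimed; the package validates
formulas, layouts and algorithmic equivalences instead.

Degenerate inputs: empty sequences, single-class training sets, zero-contact
pair sets and coincident atoms raise `ValueError` with a message naming the
problem; detection of angles at coincident points skips the candidate.
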