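# Methods

## Structural model and mass arithmetic

All oxylipins are modeled as substituted straight-chain fatty acids with
carbon numbering from the carboxyl carbon (C1). The precursor is fixed to
EPA (20:5; Δ5Z,8Z,11Z,14Z,17Z); C16/C18 oxylipins are out of scope because
the genus modeled here does not oxidize C16 PUFAs. A species carries
exactly the positional fields its class requires (hydroxyl for HEPE,
hydroperoxide for HpEPE, hydroxyl + vicinal epoxide for HEpETE, ketone for
keto acids), validated at construction. Elemental formulas are derived
from the species' own chain (length and alkene count give CnH(2n−2d)O₂ for
the acid) plus group deltas: +O per hydroxyl or ketone oxygen, +2O per
hydroperoxide, +O−2H per epoxide ring closure or ketone, +CH₂ for the
methyl ester. The chain-shortened terminal oxo acid
(15-oxo-5Z,9E,11E,13E-pentadecatetraenoic acid) follows the same
bookkeeping on a C15 chain with four alkenes, giving C15H20O3.

Monoisotopic atomic masses (C 12, H 1.00782503, O 15.99491462,
Na 22.98976928; electron 0.00054858 Da) are pinned in one constants table;
adduct m/z = m(M) + m(cation) − m(e⁻) for singly charged M+H and M+Na.
Nominal m/z is the monoisotopic value rounded to the nearest integer,
matching how the field reports low-resolution ions (the sodiated keto-EPA
methyl ester, C21H30O3 + Na⁺, computes to 353.2087 → nominal 353).
Double-bond geometry is stored only for naming fidelity and plays no role
in any mass. Stereochemistry and chromatographic RT prediction are
deliberately absent.

The two m/z 353 markers (Mk353#1, Mk353#2) are structurally undetermined;
they are modeled as mass-and-UV-only records whose expected precursor is
the sodiated keto-EPA methyl ester (the structure their mass and keto-type
UV suggest), with no diagnostic fragments.

## Diagnostic fragmentation

The positional information of a LOX lives in its epoxy-alcohol: for each
supported position p ∈ {5, 8, 12, 14, 15} the package generates the
observed rearrangement (15→13,14-; 14→16,14-; 12→10,11-; 8→10,8-;
5→7,5-HEpETE; short names cite hydroxyl then the lower epoxide carbon).
Only the observed isomer per position is generated and flagged primary;
whether the complementary epoxide-direction isomer also occurs is not
resolvable from the data modeled here.

Diagnostic ions come from cleaving the C–C bond between the carbinol
carbon and its epoxide-adjacent neighbour. Fragment formulas are obtained
by per-carbon hydrogen bookkeeping (homolytic split; the two sides sum
exactly to the precursor formula — asserted as a test invariant), and both
charge-retention variants are emitted with a configurable even-electron
hydrogen transfer to the charged fragment (+1 H by default; 0 and −1
supported so users can match their instrument without code changes).
H₂O and, for methyl esters, CH₃OH neutral losses of the precursor are
appended; they are shared across isomers and therefore never
position-discriminating on their own. Position inference counts matched
theoretical ions per position within a fragment tolerance and reports the
full ranking; a unique top count yields a LOX call, equal top counts are
reported as a tie and produce no call. Intensities are never used:
matching is presence-based.

Default tolerances are q-ToF-plausible and configurable: 0.02 Da
(precursor), 0.05 Da (fragments), ±5 nm (UV), ±0.5 min (RT). The
diagnostic-ion map over the compound panel is injective at 0.01 Da, so the
0.05 Da matching tolerance cannot confuse two epoxy-alcohols.

## Identification and quantification

Matching follows the PAI hierarchy: a precursor match (best adduct within
tolerance) is required; fragments, UV class and RT add indicators; the
best entry maximizes (indicators, matched fragments, −|precursor error|),
with library order as the final deterministic tie-break. Confidence tiers:
*identified* (precursor + ≥1 fragment), *putative* (precursor without
fragment evidence — e.g. the oxo acid, which has no diagnostic ions),
*unknown_marker* (keto-UV m/z 353 without fragment identification;
assigned to a marker group by nearest isomer RT when the run declares the
reference RT scale, else "353-unresolved"), *unassigned*. RT is never a
sole basis for identification, and the reference RT table (apart from the
markers' observed isomer pairs) is a package convention, meaningful only
for data simulated on, or aligned to, that scale.

Quantification divides each compound's summed peak area (marker isomer
pairs collapse to one row) by the internal-standard area of the same run —
semi-quantitative by design; no response factors or absolute amounts.
Profiles without a usable internal standard are flagged and left
non-quantified. The matrix places compounds in first-seen row order,
preserves input column order, suffixes replicates with "/r\<n\>", and fills
absences with 0 (a config flag switches to NA). The heat map renders
log(1 + ratio) with the viridis scale; the scale is a rendering
convention of this package.

## Parsimony on chemotype characters

`fitch_min_changes` is unit-cost dynamic programming over the given
topology (any arity, any small state alphabet). The classic two-set
intersection/union rule undercounts on polytomies (four children with
states {0},{0},{1},{1} need two changes, not one), so the DP formulation
is used and verified against exhaustive enumeration of ancestral labelings
on all trees of ≤8 tips.

`dollo_min_gains` counts the minimum number of independent acquisitions of
a binary character when the ancestral state is absence and a lineage that
lost the character never regains it. Taken with unrestricted losses this
minimum degenerates (one gain above the root explains anything), so the
reported quantity is the loss-free minimum: the number of maximal
all-present clades, minimized over binary resolutions of polytomies — at a
mixed node, all all-present children can be grouped under a single gain in
some resolution, which gives a closed-form exact count. The unresolved
count (each present child its own gain) is reported alongside as the upper
end of the supported range; on binary trees the two coincide, and the
binary-tree value is verified against brute force. The alternative
single-gain history is quantified by `single_gain_min_losses`: one
acquisition at the MRCA of the present tips and one loss per maximal
all-absent clade below it. On the bundled topology the Mk353#2 marker
(present in *P. pseudodelicatissima*, the new *P.* cf. *delicatissima*
genotype, and *P. multiseries*) yields a gain range of 2–3 versus 7 losses
under a single gain — the basis for reading it as independently acquired.

Species-level chemotypes are unions over strains; intra-strain variation
is preserved in the per-strain table rather than resolved. Marker-only
chemotypes are counted separately from LOX chemotypes in the census.

## The bundled topology

`data/rbcl_topology_text_derived.nwk` is a synthetic transcription of the
published rbcL topology from its textual description: basal
*P. turgiduloides*; three main clades (fraudulenta; multistriata sister to
multiseries + pungens; galaxiae sister to the delicatissima superclade
whose apical trio groups pseudodelicatissima, the new genotype and
delicatissima). Arrangements the text leaves open — including the apical
trio — are kept as polytomies, and the relationship among the three main
clades is a polytomy. It approximates the published figure and is labeled
as a transcription; analyses of real data should supply their own Newick.

## Synthetic data

The simulator emits, per strain: the HEPE + primary epoxy-alcohol feature
pair of every LOX position in its chemotype (14-LOX contributes only its
epoxy-alcohol, as no 14-HEPE is in the compound panel), marker isomer
pairs at their observed RTs with keto UV, optionally the oxo acid, one
internal standard, and Poisson-distributed uniform-m/z decoys. Noise
defaults are the conditions the analysis assumes: 10 ppm Gaussian m/z
noise on precursors and fragments, 0.15 min RT jitter, ln-areas
N(13, 0.8²), fragment dropout 0.1, decoy rate 2 per strain; a `noiseless()`
constructor zeroes all of it. Randomness uses NumPy PCG64 generators keyed
by (seed, SHA-256 of strain id), so output is reproducible per strain
across platforms and insertion orders. What the simulator does **not**
emulate: chromatographic peak shapes, isotope envelopes, co-elution,
intensity-dependent fragment detection, matrix effects — so passing
recovery tests demonstrates the matcher's logic under the declared noise
model, not performance on raw instrument data.

`simulate_tree` builds random binary topologies by seeded pair-joining and
plants a binary character with a known number of independent gains,
choosing gain clades that are disjoint and leave each parent a fully
absent child, which makes the planted count equal the irreversible-gain
minimum by construction.

## Problem sizes and numerical choices

The recovery experiment uses 120 strains (24 per single-position
chemotype) at the default noise; recovery of the configured chemotype runs
at ≈99%, against an acceptance convention of ≥95%. Parsimony equality is
checked on 200 random instances of ≤8 tips (brute force enumerates ≤2⁷
labelings per instance). Ties anywhere — position ranking, best-entry
selection — are resolved deterministically or reported, never broken
randomly. Degenerate inputs (empty fragment lists, empty libraries,
non-positive tolerances, missing tips, unrooted trees without an outgroup,
non-positive internal-standard areas) raise typed errors that the CLI maps
to distinct exit codes.

## Known limitations

* Fragment m/z values of the epoxy-alcohol ions are validated by
  conservation and injectivity properties, not against published spectra;
  the ±1 H transfer convention may need adjustment per instrument.
* Marker-group RT windows are instrument-dependent; without a declared RT
  reference the two groups cannot be told apart and are reported
  unresolved. The two groups' isomer RTs partially interleave, so heavy RT
  jitter can swap a marker assignment.
* The Dollo count assumes irreversible gains; the single-gain loss count
  brackets the other extreme, but intermediate gain/loss trade-offs are
  not enumerated.
* Negative-mode ionization, C16/C18 oxylipins, absolute quantification and
  phylogeny inference are out of scope.
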