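# loxotype

Oxylipin chemotyping of diatom LC-MS/MS profiles: in-silico modeling of
EPA-derived oxylipins and their diagnostic MS/MS ions, identification of
oxylipins in feature tables by primary analytical indicators, inference of
lipoxygenase (LOX) positional specificity per strain, assembly of the
internal-standard-normalized strain × oxylipin matrix, and parsimony mapping
of chemotypes onto phylogenies.

## The scientific problem

Diatoms of the genus *Pseudo-nitzschia* convert eicosapentaenoic acid
(EPA, 20:5 *n*-3) into oxygenated derivatives — oxylipins — through
lipoxygenase pathways. A LOX inserts O₂ at one of five carbons of EPA
(C5, C8, C12, C14 or C15, numbered from the carboxyl carbon), and the
resulting hydroperoxide (HpEPE) is either reduced to a hydroxy acid (HEPE)
or rearranged to a hydroxy-epoxide (HEpETE). Because different species
harbor LOXs of different positional specificity, the set of positions a
strain uses — its **chemotype** — is a taxonomic character that can be
compared with molecular phylogenies.

The catch is that position is invisible to MS1: every HEPE is isobaric with
every other HEPE, and likewise for the HEpETEs. What does encode the
position is MS/MS fragmentation of the epoxy-alcohols: the C–C bond between
the carbinol carbon and its epoxide-adjacent neighbour cleaves at a
position-specific carbon, so the two charged fragments have m/z values
unique to each hydroxyl/epoxide combination. `loxotype` models this
chemistry with exact elemental bookkeeping:

* formulas follow the class rules HEPE = EPA + O, HpEPE = HEpETE = EPA + 2O,
  keto-EPA = EPA + O − 2H, methyl ester = +CH₂;
* m/z = M + m(cation) − m(e⁻) for singly charged M+H / M+Na adducts,
  from a single pinned table of monoisotopic atomic masses;
* each epoxy-alcohol's diagnostic ion set is generated by homolytic
  cleavage bookkeeping (with a configurable ±1 H transfer) plus H₂O/CH₃OH
  neutral losses, and the inverse mapping ranks LOX positions by
  matched-ion count, reporting ties as ties.

Identification follows the *primary analytical indicator* (PAI) logic:
precursor m/z is required, MS/MS fragments upgrade a match to *identified*,
UV λ_max and retention time act as soft supporting indicators. Features at
nominal m/z 353 (M+Na⁺) with keto-type UV (248 nm) and no fragment
identification are classed as the structurally undetermined marker groups
Mk353#1/Mk353#2, disambiguated by their isomer retention-time pairs.
Peak areas are normalized to the spiked internal standard
(16-hydroxyhexadecanoic acid methyl ester) and assembled into a
compounds × strains matrix. Chemotypes are finally mapped on a Newick
phylogeny with Fitch parsimony (minimum state changes; exact on
polytomies) and an irreversible-gain Dollo count (minimum independent
acquisitions, minimized over binary resolutions of polytomies), with the
complementary single-gain/multiple-loss scenario also reported.

## Worked example

```python
from loxotype import chem, fragmentation
from loxotype.chem import Derivatization

ME = Derivatization.METHYL_ESTER
h = fragmentation.pathway_products(8).primary_epoxy_alcohol
print(h.name, chem.adduct_mz(h, ME, "M+Na"))
for ion in fragmentation.diagnostic_ions(h):
    print(f"  {ion.mz:9.4f}  {ion.formula.hill():10s}  {ion.label}")
print(fragmentation.lox_position_from_ions(
    [ion.mz for ion in fragmentation.diagnostic_ions(h)]))
```

prints

```
10,8-HEpETE (371.21928014, 371)
   207.0992  C10H15O3    10,8-HEpETE C9-C10 carboxyl [M+Na]+
   189.1250  C11H17O     10,8-HEpETE C9-C10 methyl [M+Na]+
   353.2087  C21H30O3    10,8-HEpETE [M+Na-H2O]+
   339.1931  C20H28O3    10,8-HEpETE [M+Na-CH3OH]+
[(8, 4), (5, 2), (12, 2), (14, 2), (15, 2)]
```

The 8-LOX epoxy-alcohol 10,8-HEpETE (hydroxyl C10, epoxide C8–C9) ionizes
as a sodiated methyl ester at m/z 371; cleaving the C9–C10 bond yields a
207.0992 carboxyl-side and a 189.1250 methyl-side ion. Fed back to the
ranker, those ions match all four predicted ions of position 8 but only the
(shared) neutral losses of the other positions — a unique call for 8-LOX.

The same round trip at pipeline level, from a command shell:

```sh
loxotype simulate --seed 1 --out run/          # synthetic panel strains
loxotype identify --features run/features_P_arenysensis-S1.csv \
    --spectra run/spectra_P_arenysensis-S1.mgf --rt-reference --out run/ids
loxotype profile --profiles run/ids/profile_P_arenysensis-S1.json \
    --out run/matrix.tsv
loxotype map --characters chars.csv --name Mk353_2 --outgroup P_turgiduloides \
    --out run/map
```

`identify` prints the per-strain compound count and LOX set (for
*P. arenysensis*: `LOX [12, 15]`); `map` reports
`"min_gains_dollo": 2` for the Mk353#2 marker on the bundled
text-derived rbcL topology — the marker's scattered distribution cannot be
explained by a single acquisition.

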