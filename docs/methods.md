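# Methods

## The classifier

The egg model reduces passive membrane permeation to two molecular
coordinates: polarity, measured by the Ertl topological polar surface area
(tPSA, Å², a fragment-additive sum over polar atoms), and lipophilicity,
measured by the Wildman–Crippen octanol/water partition coefficient (WLogP,
an atom-contribution sum over the published 68-type table, implicit
hydrogens included). Two elliptical regions of the (tPSA, WLogP) plane,
fitted originally on human absorption and brain-penetration data for drugs,
define the predictions: membership in the large "white" ellipse predicts a
fraction absorbed Fa ≥ 0.30 after oral dosing (GI label *high*), membership
in the "yolk" predicts a brain/blood concentration ratio ≥ 1, i.e.
LogBB ≥ 0 (BBB label *yes*). The two tests are evaluated independently; the
yolk protrudes slightly from the white at near-zero tPSA, which is why a
compound can be brain-permeant yet poorly absorbed (lindane is the
archetype).

Membership is the rotated-normalised quadratic form
`(u/a)² + (v/b)² ≤ 1` with `(u, v)` the point's coordinates in the
ellipse's principal frame. The boundary counts as inside by default
("included in" the region reads inclusively); the convention is a config
flag, and flipping it can only matter for points exactly on the boundary.

### Ellipse geometry

The geometry lives in `src/boiledegg/data/boiled_egg.yaml`, never in code:

| ellipse    | center (tPSA, WLogP) | semi-axes (tPSA, WLogP) | tilt (°)  |
|------------|----------------------|--------------------------|-----------|
| intestinal | (71.051, 2.292)      | (71.0405, 4.3700)        | −1.031325 |
| brain      | (38.117, 3.177)      | (41.0305, 2.7785)        | −0.14458  |

These are the published best-fit ellipses of the original egg model,
transcribed from its distributed plotting code. The white region thus spans
tPSA ≈ 0–142 Å² and WLogP ≈ −2.1–6.7; the yolk tPSA ≈ 0–79 Å² and WLogP
≈ 0.4–6.0. A sha256 checksum of the config travels with every prediction
frame for provenance. Geometry is computed directly in (Å², log units)
without rescaling, tPSA on the abscissa as in the standard egg plot.

### tPSA and the S/P contributions

The Ertl scheme exists with and without extended sulfur/phosphorus
fragment contributions. The choice is material for organophosphorus
pesticides: the thiophosphoryl head (P=S plus three ester oxygens)
contributes ≈ 42 Å² under the extended scheme and 0 without it. The
package default *includes* S and P, which is the calibrated setting: with
it, every P=S parent sits above the yolk's tPSA range (BBB *no*) while the
three least polar oxons fall inside, reproducing the curated parent/oxon
panel exactly; without it, P=S parents collapse onto the yolk and the
panel's pattern is destroyed. The flag is surfaced everywhere
(`include_sp`, CLI `--no-sp`) and recorded in output metadata, and the
reproduction script reports both settings side by side.

## Descriptor panel

Beyond tPSA/WLogP the panel carries molecular weight, heavy-atom and
aromatic-heavy-atom counts, rotatable bonds (non-ring single bonds between
non-terminal heavy atoms, amide C–N excluded), Lipinski-style N/O-based
H-bond acceptor/donor counts, the Csp3 carbon fraction (defined 0 for
carbon-free molecules), Wildman–Crippen molar refractivity, and the N+O
atom count. The acceptor/donor and rotatable-bond perception rules of the
original web tool are not published; the package fixes the documented RDKit
conventions instead, so absolute HBA/HBD counts may differ slightly from
that tool's output while tPSA/WLogP — the classifying pair — are exact
reimplementations of the published methods. Slots exist for externally
computed XLogP3 and LogS(Silicos-IT) values, which are deliberately not
reimplemented. The carbon-scaled mean atomic van der Waals volume and
polarizability are simple atomic-constant surrogates (handbook tables,
mean over all atoms including H, element without a constant excluded with
a warning) for values originally produced by commercial software; they are
flagged as surrogates and nothing downstream depends on them.

All descriptors are topological: no 3D geometry, conformers, pKa or logD.
Structures are standardized before computation — largest organic fragment
of multi-fragment inputs retained (pesticide salts are rare; descriptor
panels are defined per covalent unit), formal charges preserved,
stereochemistry dropped (no implemented descriptor is stereo-dependent) —
and every molecule is round-tripped through its canonical SMILES so that
contribution sums are bit-identical across input dialects (Kekulé vs
aromatic), an exactness the test suite relies on.

## Statistics

Group comparisons between predicted permeant and non-permeant compounds
use the classical pooled-variance two-sided Student's *t* test at
significance p < 0.05, with no multiple-testing correction — the
convention of the analysis this package reproduces; a Welch option exists
for sensitivity analysis. The degenerate all-constant case returns t = 0,
p = 1 flagged rather than NaN. Class-level percentages are reported
unrounded, with printed forms following the reporting convention (integer
for single classes, one decimal for the whole-corpus row). The measured-Fa
curation collapses a range reported for one dose to its midpoint, averages
multiple studies, and dichotomises at Fa ≥ 0.30 (boundary high);
inequality-only literature values are accepted exactly when the bound
alone decides the label, which every bundled bound does — an indecisive
bound is a curation error, not a silent guess.

## Bundled data

The parent/oxon panel (15 thiophosphoryl organophosphorus insecticides and
their P=S → P=O metabolites) and the measured-Fa panel (25 pesticides,
curated human Fa values with their qualifiers) ship as plain CSV. Fa
values and qualifiers are transcribed from published human
pharmacokinetics curation; structures are the standard public structures
of these well-characterised compounds, curated offline and each checked
against its known molecular formula. No live database lookups occur at
run time.

## Synthetic data

The descriptor-cloud generator samples (tPSA, WLogP) points with exact
per-region counts — inside both ellipses, white-only, yolk-only, outside
both — using parametric uniform sampling inside the relevant ellipse
followed by membership filtering (the yolk-only sliver is far too thin for
box rejection), with a bounded proposal budget so an infeasible request
fails loudly. Points carry their construction labels, so label recovery
and class-summary percentages have exact counting oracles. The SMILES
generator assembles structures from a fragment grammar of halogenated
rings, phosphorothioate/phosphate heads, carbamate, triazine,
cyclopropanecarboxylate-ester and phenoxy-acid cores, with class labels in
the corpus-like 30:99:42:74:31:62 proportions by default and optional
parent/oxon pairs. It emulates the class structure and descriptor ranges
of a pesticide corpus, not its exact chemistry: passing tests demonstrate
pipeline correctness on realistic inputs, not predictive validity for any
real compound. A single seeded generator drives all sampling; identical
spec + seed reproduces identical bytes after serialization.

## Problem sizes and numerical choices

The reproduction script and acceptance-level property checks use a
200×200 membership grid per ellipse, a 1000-point descriptor cloud
(400/300/20/280 across the four regions), ten 5-vs-5 *t*-test replicates
checked against the closed-form pooled formula to 10⁻¹⁰, and a
200-compound synthetic library for dialect-invariance checks — sizes at
which every check is exact and the whole run completes in seconds.
Floating-point membership is evaluated as an exact `<=` on the quadratic
form; no tolerance band is applied at the boundary.

## Known limitations

* The classifier addresses passive permeation only: carrier-mediated
  influx/efflux (P-gp, BCRP), first-pass metabolism, formulation and
  mixture effects are out of scope, and discordances like TCDD's
  (micelle-mediated uptake of a lipophilic non-polar compound) are
  expected failure modes of the underlying model.
* The corpus-wide survey figures (the 338-pesticide counts and the
  descriptor-association tables) require the original published compound
  list, which this repository does not redistribute; the corresponding
  checks in `tests/test_acceptance.py` document that requirement and run
  as soon as `data/full_corpus.csv` is supplied with `id`, `chem_class`
  and `smiles` columns.
* HBA/HBD counts follow a fixed documented convention that may deviate
  from other tools' perception rules; comparisons of those columns across
  tools should be made with care.
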