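# Methods

This note records the models behind `xylopat`, their assumptions, the
parameters that matter, and the package's own design choices where the
underlying science left the design open.

## Chains, positions and decoration states

A xylan chain is an ordered list of xylosyl residue states indexed 1..DP
**from the reducing end** (so a report of acetyls "at −2 and −4 from the
reducing end" of a tetraose corresponds to positions 2 and 4 here, with the
sign dropped).  Each residue carries two acetyl flags (O2, O3) and a GlcA
state (none / GlcA / MeGlcA); the NMR-style type (X, X2, X3, X23) is always
derived from the flags.  GlcA and 2-O-acetyl are mutually exclusive because
both occupy the O2 hydroxyl — the chemistry forces this even where
measurements do not state it.

## Synthetic decoration hypotheses

The generator emulates the three decoration laws the analyses compare:

- **alternating** — acetyl on exactly the odd or even positions (phase
  selectable), the patterning inferred for Arabidopsis secondary-wall xylan;
- **bernoulli** — i.i.d. acetylation with probability `p_ac` (default 0.5,
  the measured overall acetylation level of dicot xylan), the random null;
- **composition** — residue types drawn i.i.d. from a four-probability law
  (X, X2, X3, X23); the shipped reference values are the HSQC-integration
  compositions of GlcA-less mutant (55.6/15.3/26.6/2.5 %) and wild-type
  (46.8/26.7/22.2/4.3 %) xylan.

Each acetylation event is split between 2-O, 3-O and 2,3-di-O placement by
the fractions (`o2_fraction`, `o3_fraction`, `di_fraction`), default
(0.4, 0.5, 0.1), chosen to roughly echo the measured mono/di ratios and
overridable everywhere.  GlcA placement is either evenly spaced (default
spacing 6, random seeded offset — the "major domain" hypothesis) or i.i.d.
("minor domain"); whether the minor domain is also alternately acetylated is
not settled experimentally, so the generator exposes both combinations
rather than hard-wiring one.  O2↔O3 acetyl migration is applied as an
independent per-residue swap on singly acetylated residues; X and X23 are
untouched so acetyl counts are conserved.

Reproducibility: one ensemble seed spawns an independent `numpy` Generator
per chain (`default_rng([seed, k])`), so ensembles are order-independent
and byte-stable; the pipeline derives per-stage streams the same way.

## Enzyme subsite models

Glycoside-hydrolase subsites are numbered from the scissile bond, −n toward
the non-reducing end; the residue at −1 contributes the anomeric carbon and
becomes the new reducing end of the released product.  With reducing-end
residue numbering, bond *b* joins residues *b*+1 and *b*; subsite −n maps to
residue *b*+n, +n to residue *b*−n+1.  A bond is cleavable iff every
required subsite (−2, −1, +1 in both presets) is occupied by a real residue
— terminal bonds whose −2 falls off the chain are non-cleavable, a
conservative reading — and every mapped residue passes its tolerance
predicate:

- **GH10 preset (CmXyn10B)**: −1 fully undecorated; −2 rejects 2-O
  substituents (acetyl or GlcA) but accepts 3-O-acetyl; +1 unrestricted.
- **GH30 preset (EcXyn30)**: −1 undecorated; −2 *requires* a 2-O substituent
  (GlcA, MeGlcA, or acetyl — the observed cleavage of GlcA-free acetylxylan
  shows the acid group is not essential).  Whether the 2-O decoration is
  strictly required or merely preferred is unresolved; both behaviours ship
  (`EC_XYN30` strict, `EC_XYN30_TOLERANT`).

Digestion evaluates all permissible bonds on the intact parent and cuts
simultaneously — complete mode cuts all, partial mode cuts each
independently with `site_prob` (the low-enzyme-load analogue).  Because each
rule reads only the decorations of residues around one bond, and digestion
never alters decorations, a product can expose no site absent from its
parent; simultaneous cutting therefore equals iterated re-digestion
(tested as a fixed-point property).  Product summaries count by
(DP, n_acetyl, n_GlcA); modal acetyl counts break ties toward the smaller
count for deterministic reporting.

The even-DP null test formalizes the ladder argument: the even-DP fraction
of *released* products (an uncut chain is not a digestion product) is
compared against `n_sims` simulations under a user-supplied null law, with
the add-one Monte-Carlo p-value (1 + #{null ≥ observed}) / (n_sims + 1).

## Mass spectrometry model

Neutral monoisotopic masses are assembled from anhydro-residue increments
(pentose C₅H₈O₄ = 132.0423, acetyl C₂H₂O = 42.0106, hexuronate C₆H₈O₆ =
176.0321, methyl CH₂) plus one water per molecule; elemental masses come
from `pyteomics`.  2-AA labelling by reductive amination adds C₇H₇NO
(= 121.0528: anthranilic acid − H₂O + H₂).  The default adduct is [M+Na]⁺
(standard for 2-AA glycans in DHB); peak comparison is nominal
(nearest integer, configurable 0.3 Da matcher tolerance) because MALDI-ToF
ladders are read at unit resolution.  Spectra are count-based: relative
abundance is the product-count fraction, with no ionization-efficiency or
isotope-envelope model.  Only the reducing-end-retaining Y-type fragment
series is modelled; successive ladder steps equal one pentose, plus one
acetyl exactly when the added residue is acetylated, which is what
localizes the substituents.

## NMR-observable statistics

Peak integration is emulated by direct residue counting (composition
percentages), NOESY adjacency by neighbor-pair tallies over every bond, and
the four assignable triads X2–X–X2 / X2–X–X3 / X3–X–X2 / X3–X–X3 by
classifying each *interior* non-acetylated residue by its two neighbors,
read non-reducing → reducing.  Triads involving X23, GlcA-bearing residues
or non-acetylated neighbors go to an "other" bucket (experimentally those
species were too weak or overlapped to assign); chain ends are excluded
from triads but included in adjacency.  For i.i.d. types the closed form
P(a–X–b | scanned) = p_a·p_b (the unconditional p_a·p_X·p_b divided by the
scan probability p_X) serves as the analytic cross-check, itself verified
against exhaustive DP3 enumeration in the tests.  Reports expose raw
fractions — e.g. the residual Ac–Ac rate — rather than a verdict, since the
acceptable residual under "largely alternating" is not quantified.

## Helical ribbons and torsion analysis

Residues are rigid idealized ⁴C₁ pyranose templates: a perfect chair
(ring bond ≈ 1.53 Å, pucker ±0.25 Å) with all exocyclic oxygens equatorial
(the all-equatorial arrangement of β-D-xylopyranose; glucose adds C6/O6 at
C5).  Chains are grown by natural-extension-reference-frame placement of
each residue's C1/O5 against the previous residue's O4/C4/C5 with the
glycosidic angle fixed at 117°, followed by an exact three-point rigid fit
of the full template — so the built torsions are exact by construction and
the build→measure round trip is a genuine test of the torsion analyzer,
not of a shared code path.

Torsion convention (used consistently; the analyses depend only on the
round trip): Φ = O5′–C1′–O4–C4, Ψ = C1′–O4–C4–C5, primed atoms on the
non-reducing side, right-handed sign.  The screw rule is: Φ+Ψ = 120° ⇒
twofold (2₁); 50° ⇒ threefold right-handed; 190° ⇒ threefold left-handed;
classification windows are inclusive with half-width `tol` (default 30°,
capped below 35° so windows cannot overlap).

Only the *sum* is physically constrained; the split is a free choice along
the constant-sum line.  Two findings fixed the defaults:

1. The residue-to-residue screw-rotation angle depends on the sum alone
   (measured: 179.7° / 121.1° / 238.2° for sums 120/50/190, independent of
   the split), so no split is "more helical".
2. The split selects the conformer branch: Φ = Ψ = sum/2 gives a compact
   coil (rise 3.85 Å) with rings nearly perpendicular to the axis, whereas
   Φ = Ψ = sum/2 + 180° (mod 360) gives the extended flat ribbon with
   rise 5.38 Å — the fiber-repeat regime of real β-(1,4) glycans (~5.2 Å
   per residue).  The extended balanced split is the default; `phi`
   overrides it.

The template enantiomer was chosen so that the handedness of the built
threefold screws matches the conventional assignment (sum 50° → +121°
rotation, right-handed; 190° → −122°, left-handed).

`screw_symmetry_rmsd` fits the unconstrained best residue-i→i+1 screw
(Kabsch + axis/angle/rise decomposition), then forces the rotation to
360/n° about the same axis and measures the residual RMSD: an ideal helix
scores 0.006–0.04 Å against its own fold and ~1.1–1.8 Å against the wrong
fold.  The small nonzero own-fold values reflect the ~0.3–1.8° offset
between the idealized-template screw angles and exact 360/n; they are
reported honestly rather than absorbed into the builder.

Substituents are attached in the template frame before posing.  Acetyl
esters use the rotamer that points the group along the ring normal: the
O→C(ester) bond makes the C–O–C angle (117°) with the ring C–O bond, and
the sp2 carbonyl carbon places CH₃ and =O at ±60° (the trans-ester zigzag),
giving the ~2.5 Å perpendicular protrusion seen for substituents of a flat
2₁ ribbon.  Because a 2₁ screw maps a residue onto its neighbor by a 180°
rotation, all substituents of same-parity residues land on the same ribbon
face — the geometric heart of the even/odd asymmetry.  GlcA side chains are
simplified six-atom ring markers standing edge-on along the same direction;
they are steric placeholders, not sugar geometry.

## Cellulose face models and docking

Faces are reduced to what the steric and H-bond arguments need: twofold
glucan ribbons (built by the same machinery) running along z, laid flat in
sheets.  Defaults: 8.2 Å chain spacing within a sheet, 3.9 Å between sheets
(Iβ-like values, all in `LatticeParams`).  Hydrophilic faces (010)/(020)
(and the (110) family) are modelled as a surface sheet with one chain
*vacancy* — the missing-chain groove proposed as the xylan adsorption site —
above a second sheet directly below; the xylan ribbon occupies the vacancy
with its axis parallel to the cellulose chains, decorated face rotated
toward the solvent, raised by `dock_lift` (default 0.4 Å).  Hydrophobic
faces (100)/(200) are one intact sheet with the ribbon stacked above it at
`stack_height` (default 6.5 Å, room for substituents on the lower face —
these faces tolerate decoration on either side precisely because there is
no groove).

Clash scoring counts xylan↔cellulose heavy-atom pairs closer than
`scale × (r_vdw,i + r_vdw,j)` with scale 0.7 (a common soft-contact
criterion; radii C 1.70 Å, O 1.52 Å), monotone in `scale` by construction.
On these defaults the alternate-decorated ribbon docks into the (010)
vacancy with zero clashes (closest approach 2.75 Å, 16 % above threshold)
while an odd-spaced pattern clashes through its buried acetyl methyl; both
stack cleanly on (100).

Hydrogen bonds are detected geometrically on heavy atoms only (the models
carry no hydrogens): oxygen pairs within `d_max` (default 3.5 Å) where at
least one partner is a hydroxyl.  Esterified and glucuronosylated oxygens
are excluded as hydroxyls; interior O4 and ring O5 are acceptor-only.  Each
xylan oxygen is credited with at most one bond — its closest partner —
because a hydroxyl has a single proton; without this rule the numerous
marginal ~3.4 Å lateral contacts would outvote the true ~2.8 Å bonds.  Mode
labels record the two oxygen identities symmetrically (`xylO2<->gluO6`), so
heavy-atom-only detection is invariant under donor/acceptor relabeling.  On
the docked alternate-pattern pose the dominant mode is xylosyl O2 ↔ glucosyl
O6 (9 of ~17 bonds at defaults).  The `angle_min` criterion (default 120°)
applies only when hydrogens are present, i.e. never in the shipped builders.

## Jitter ensembles

`synthetic_trajectory` produces frames by adding i.i.d. Gaussian noise
(default studies use 0.1–0.2 Å) to every coordinate.  It reproduces what
the torsion-histogram and separation analyses need — a unimodal Φ+Ψ
distribution centred on the built sum, and docked-vs-desorbed d_O–O
contrasts — but models no correlated backbone motion, no solvent, and no
transitions between screw states, so a passing histogram test says the
*analysis* is correct, not that the 2₁/3₁ equilibrium of real xylan is
reproduced.  d_O–O is defined here as the per-residue minimum distance
between xylan backbone oxygens (O4/O5) and any cellulose backbone oxygen;
the measured quantity behind the published scatter is not specified
precisely, so this definition is a documented package choice.

## Pipeline

`RunConfig` (strict-keyed YAML) drives `generate → digest → spectrum /
nmr_stats / structure`; unmet stage dependencies fail with the missing
stage named.  Outputs are text (chain strings, residue TSV, product TSV,
spectrum TSV, linkage TSV, PDB via biotite, JSON summaries) plus a manifest
with a config hash; identical config+seed reproduces byte-identical
outputs, and `io_roundtrips` re-reads and re-writes every recognized output
to verify lossless round trips.

## Problem sizes

Default study sizes — DP 50 chains, 50–200-chain ensembles, 10,000–40,000
residues for composition estimates, 500 Monte-Carlo null simulations,
DP 10 ribbons on 5-chain face models, a few hundred jitter frames — were
chosen so every statistical check sits at ≥3σ from its pass boundary while
the whole suite and the acceptance script each run in well under a minute.

## Known limitations

- Idealized rigid templates: no ring flexibility, no hydrogens, no energy
  model; clash and H-bond results are geometric demonstrations on
  constructed poses, not predictions of binding strength.
- The GlcA marker is not a real sugar; do not read its contacts chemically.
- Enzyme models are local tolerance rules: no kinetics, processivity, or
  time courses; abundances are count-based, with no ionization model.
- Arabinosyl/feruloyl decorations (grass xylans) are out of scope.
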