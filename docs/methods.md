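# Methods

This note documents the models, parameters and numerical choices behind
`tmimpact`, what the synthetic test structures do and do not emulate, and
the package's known limitations.

## Membrane placement

The bilayer is an implicit slab: hydrophobic core |z| ≤ T/2 with
T = 30 Å by default, flanked by a headgroup belt of 2 Å. The protein is
rigid; the search recentres the Cα centroid at the origin and enumerates
rotation about x, rotation about y (both [0°, 360°) in 18° steps — the
half-open interval avoids double-counting 0° = 360°) and a z translation
on the inclusive lattice −30, −27, …, +30 Å. That is 20 × 20 × 21 = 8,400
grid points; rotation about z and x/y translations are irrelevant by the
slab's symmetry.

Each orientation is scored by the transfer energy: the sum over
amino-acid residues of a depth-dependent pseudo-energy of the residue
type, evaluated at the |z| of the residue's representative atom (Cα by
default, configurable). The per-type curves are sigmoidal,
E(z) = E₀ / (1 + (|z|/z_mid)ⁿ), except Trp and Tyr, whose preference for
the interface region is captured by a Gaussian
E(z) = E₀·exp(−(|z|−z_mid)²/2σ²). Hydrophobic types have E₀ < 0
(favourable inside the slab), charged/polar types E₀ > 0. The parameter
table ships as `data/ez_params.csv` and is deliberately swappable
(`EzParameterTable.from_file`, `tmimpact place --ez-table`): the numbers
are transcriptions of a published depth-dependent insertion potential of
this functional form, and any table with the same schema can be
substituted without code changes.

Numerical choices:

* **Minimum selection.** Ties within 10⁻⁹ (relative) of the minimum are
  broken towards the lexicographically smallest (|z|, rot_x, rot_y), so
  symmetric structures give a reproducible placement. The vectorised
  search is property-tested against a naive triple-loop implementation.
* **Region boundaries.** CORE is inclusive (depth ≤ T/2); HEAD is the
  half-open belt (T/2, T/2 + 2]. A residue's region follows its
  representative atom even when side-chain atoms straddle the boundary.
* **Missing representative atoms.** Residues without a Cα are excluded
  from the energy sum and labelled from the nearest backbone atom's
  depth, with a warning. HET groups (waters, ligands, non-mappable
  modified residues) never enter the energy.

Residues of chemically modified types with a clear parent (MSE→MET,
HYP→PRO, SEC→CYS, PYL→LYS) are treated as the parent.

## Variant modelling

The repack protocol strips the target side chain and the side chains of
every residue with any heavy atom strictly closer than 5 Å to a target
heavy atom, grafts the mutant side chain, and rebuilds all stripped side
chains greedily, nearest residue first. For each residue the packer
enumerates a packaged χ-angle rotamer set (all combinations of
180°/±60°; planar groups and the proline ring are fixed templates),
scores each rotamer by its summed positive van der Waals overlap with the
current context (pairs up to three covalent bonds apart are exempt), and
keeps the lowest-scoring rotamer, ties to the lowest rotamer index. The
procedure is deterministic: identical input gives bit-identical output.

This internal packer is intentionally lower-fidelity than a dedicated
side-chain prediction program — it exists so the pipeline has no hard
dependency on a proprietary external binary. Its contract (fixed
backbone, correct atom inventory, locality outside the 5 Å shell) is what
the damage detectors actually require, because every detector is a
distance-threshold test with a built-in +1 Å slack. An adapter that
shells out to an SCWRL4 executable is available
(`repacker: external_scwrl4`, `scwrl4_path`); it enforces the same
invariants on the returned coordinates.

Backbone coordinates are never modified; Gly targets are graft-only; the
X→X "substitution" is rejected.

## Geometric features

* **SASA** is computed by Shrake–Rupley sphere sampling on heavy atoms:
  960 quasi-uniform points (golden spiral) per atom, probe 1.4 Å, radii
  C 1.70 / N 1.55 / O 1.52 / S 1.80 Å. 960 points keep the isolated-atom
  error well under 1% and the two-sphere closed-form error under 2%.
  Relative accessibility (RSA) divides the residue total by a packaged
  maximum computed with the same code and radii on an extended
  Gly-X-Gly tripeptide, so RSA ≈ 1 for the reference state by
  construction. *Buried* means RSA < 9% (configurable), a conventional
  threshold in structure-based variant analysis.
* **Contacts.** Hydrogen-bond candidates are heavy-atom N/O/S donor to
  N/O acceptor pairs under 3.5 + 1.0 Å, excluding pairs within two
  covalent bonds; when explicit hydrogens exist a donor-angle test is
  applied, otherwise geometry is heavy-atom only (most inputs lack
  hydrogens). Salt bridges are Asp/Glu carboxylate O to Lys/Arg basic N
  under 4.0 + 1.0 Å (His optionally counts as basic; off by default
  because of its ambiguous pKa), reported once per residue pair at the
  minimal atom distance. Disulphides are SG–SG under 2.3 + 1.0 Å. All
  cutoffs are strict inequalities; the base values are standard
  structural-biology distances and the +1 Å slack absorbs model
  coordinate error. Increasing slack can only add contacts
  (property-tested monotonicity).
* **Secondary structure** is a simplified assignment sufficient for the
  detectors: H from runs of i→i+4 backbone N···O bonds (< 3.5 Å), E from
  long-range backbone ladder partners, B where the Cα-trace direction
  over five residues turns by more than 70°, else C; priority H > E > B.
  It is invariant under rigid motion and is not a DSSP replacement.
* **ω angles** are the CA(i−1)–C(i−1)–N(i)–CA(i) torsion; |ω| < 30° is
  cis.

## Damage categories and verdict

The verdict is the disjunction of independent detectors (see the README
for the list); `damaging ⇔ at least one triggered`. Decisions resolved
while fixing the category semantics:

* "Exposed to the transmembrane region" means region CORE and RSA at or
  above the buried threshold; "buried" means RSA below the threshold
  regardless of region. CORE charge rules fire for buried *and* exposed
  targets — inside the bilayer an unpaired charge is unfavourable either
  way.
* A broken salt bridge / inter-helix hydrogen bond requires the wild-type
  contact to lie within the CORE (both partner residues CORE-labelled)
  and to be absent, with no replacement to the same partner, in the
  rebuilt mutant under the slacked cutoff. Sub-criterion hydrogen-bond
  gains and losses at the target are reported separately as borderline
  changes rather than silently dropped.
* Inter-helix means distinct maximal helix runs (different chains count
  as different helices).
* The category table is a registry; unlisted globular-protein categories
  (cavity volume, buried Pro introduced, …) are deliberate plug-in slots,
  not implemented.
* Features are computed on the full input complex by default; a
  `single_chain` flag restricts the context to the target's chain.
* A target OUTSIDE the membrane produces an explicit refusal (CLI exit
  2), not a silent "tolerated": the TM criteria are simply not the right
  instrument there.

## Synthetic structures and what the tests show

`tmimpact.fixtures` builds all test inputs from ideal internal
coordinates (NeRF): α-helices at φ = −57°, ψ = −47°, ω = 180° (measured
rise ≈ 1.56 Å/residue), extended chains, cis-peptides, two-residue
contact motifs posed with the defining atom pair at an exact distance,
helix bundles on an 8 Å circle, and a buried-glycine hairpin wrapped in
an occluding shell. The default TM sequence is a leucine core with
two lysine anchors at each terminus — the charged flanks are what makes
the transfer-energy minimum a membrane-spanning orientation, as in
natural single-pass helices; an unflanked poly-Leu helix genuinely
prefers lying in the midplane under any depth potential of this shape.
Generators are deterministic for a fixed spec; the seed only drives
optional Gaussian jitter.

Ground truth (region labels, contact distances, ω values, tilt) comes
from the generator, so detector and placement tests assert against
construction, not against a second opinion. Passing these tests shows the
algorithm is implemented as specified on idealised, noise-free (or mildly
jittered) geometry; it does not certify accuracy on real structures,
which have irregular helices, lipids, cofactors and coordinate error.
The SASA implementation is additionally cross-checked against an
independent Shrake–Rupley implementation (biotite) on a helix.

Problem sizes in the test suite and acceptance script (20-residue
helices, bundles up to 7 × 20 residues, 1,000-trial property checks) were
chosen as the smallest sizes at which every property is non-trivially
exercised; all scale linearly if enlarged.

## Known limitations

* Single fixed slab thickness and composition; no per-membrane-type
  libraries, no curved or deformed bilayers.
* Grid-only orientation search (18°/3 Å); no continuous refinement.
* The internal repacker optimises sterics only — no rotamer priors or
  energy model; χ-angle accuracy is not a goal.
* Not suitable for beta-barrel membrane proteins.
* Purely structural: functional, binding, post-translational or
  allosteric effects of a variant are invisible, so structurally silent
  pathogenic variants will be called tolerated.
* Binary verdict by design; no probabilistic score.
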