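# tmimpact

Structure-based assessment of missense variants inside helical
transmembrane (TM) protein regions.

Most variant-effect predictors — including structure-based ones — assume a
globular protein in water. A substitution buried in a lipid bilayer lives
in the opposite chemical environment: introducing an unpaired charge into
the hydrophobic core is destabilising, while losing one at an aqueous
surface often is not. `tmimpact` evaluates a missense variant in the
context of an explicit membrane placement and reports an interpretable,
binary verdict with geometric evidence, for structural biologists and
variant analysts working on membrane proteins (GPCRs, transporters,
channels) from experimental coordinates or homology/AlphaFold models.

## Method

**1. Membrane placement.** The protein is recentred on the centroid of its
Cα atoms and oriented against a dummy bilayer slab of hydrophobic
thickness 30 Å (normal along *z*) by an exhaustive grid search over three
degrees of freedom: rotation about *x* and *y* in 18° steps over [0°, 360°)
and translation along *z* from −30 to +30 Å in 3 Å steps — 20 × 20 × 21 =
8,400 orientations. Each orientation is scored by the transfer energy

&nbsp;&nbsp;&nbsp;&nbsp;E = Σᵢ E_aa(i)(|zᵢ|)

where E_aa(z) is a depth-dependent per-residue-type pseudo-energy:
sigmoidal E₀ / (1 + (|z|/z_mid)ⁿ) for most residue types and Gaussian
E₀·exp(−(|z|−z_mid)²/2σ²) for the interface-seeking aromatics Trp/Tyr.
The parameters live in a packaged, swappable table
(`src/tmimpact/data/ez_params.csv`). The minimum-energy grid point is the
placement; residues are labelled **CORE** (|z| ≤ 15 Å), **HEAD** (the 2 Å
lipid-headgroup belt beyond the slab) or **OUTSIDE**.

**2. Variant modelling.** The target side chain and every side chain with
a heavy atom within 5 Å of the target are stripped, the mutant side chain
is grafted onto the fixed backbone, and the stripped side chains are
rebuilt by a deterministic rotamer repacker (greedy minimal-clash over a
packaged χ-angle set; an external SCWRL4 adapter is available behind a
config flag).

**3. Damage detection.** A bank of TM-specific stereochemical detectors
compares wild type and mutant: charge introduced or switched in the CORE
(whether buried or lipid-exposed), charged residue lost or switched in the
HEAD belt, salt bridge or inter-helix hydrogen bond broken in the CORE,
buried charge switch, buried glycine in a backbone bend replaced,
cis-proline replaced, disulphide broken. Contact criteria use standard
atom–atom distances plus a deliberate +1 Å slack so the calls are robust
on modelled coordinates. **The variant is called damaging iff at least one
detector triggers**; everything analysed, including sub-threshold
hydrogen-bond changes, is reported.

Targets placed OUTSIDE the membrane are refused with a pointer to use a
globular-protein predictor instead. Beta-barrel membrane proteins are out
of scope.

## Worked example

Generate a synthetic single-pass TM helix (16 leucines flanked by lysine
anchors) and score the mid-helix substitution Leu10→Arg:

```sh
$ tmimpact fixtures fx.yaml --outdir .      # fx.yaml: {helix20: {kind: ideal_helix, length: 20}}
$ tmimpact predict helix20.pdb A 10 L R --out-prefix l10r
Variant LEU->ARG at A/10
Membrane region: CORE (depth 0.8 A)
Verdict: DAMAGING

Structural features identified as damaging:
  - TM_Charge_Introduced: LEU->ARG introduces a charged residue in the
    hydrophobic core (depth 0.8 A, RSA 0.76, lipid-exposed)
...
$ echo $?
1
```

The placement put the residue 0.8 Å from the bilayer midplane (CORE); its
relative solvent accessibility of 0.76 means it faces lipid, and the
introduced arginine charge triggers `TM_Charge_Introduced`, so the verdict
is damaging (exit code 1; 0 = tolerated, 2 = error/refusal). The
conservative Leu10→Ile on the same helix exits 0 with no detector fired.
`tmimpact predict` also writes `*.report.json`, `*.report.txt` and a
membrane-aligned PDB (with optional bilayer dummy atoms for display).

The standalone placement report:

```sh
$ tmimpact place helix20.pdb
grid points evaluated: 8400
minimum transfer energy: -7.647 at rot_x=0 deg, rot_y=0 deg, z=+0.0 A
regions: CORE=20
```

`tmimpact metrics counts.csv` computes accuracy, sensitivity, specificity,
MCC and the TPR/FPR ratio from a confusion table.

## Library use

```python
import tmimpact as tm

s = tm.read_structure("protein.pdb")
placement = tm.place(s)                       # grid search, 8,400 points
pred = tm.predict(s, tm.ResidueSelector("A", 458), "I", "R",
                  placement=placement)
print(pred.verdict, [o.category for o in pred.outcomes if o.triggered])
```

See `docs/methods.md` for model details, parameter provenance, numerical
choices and known limitations.
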