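# betalayer

Detection and modelling of **β-layers** — a triangular supersecondary
element inside trimeric α-helical coiled coils — together with the
coiled-coil periodicity analysis and sequence-motif scanning that go with
it.

## The problem

Coiled coils accommodate their sequence repeats by supercoiling: a repeat
of *r* residues over *t* helical turns runs at *r/t* residues per turn
relative to the bundle axis, and only periodicities within roughly
[10/3, 3.9] — centered on the ~3.63 residues/turn of the unperturbed
α-helix — are accessible (heptads 7/2 supercoil left-handed, hendecads
11/3 and pentadecads 15/4 right-handed). Insertions of 2 or 6 residues
into a heptad background reach no accessible periodicity at moderate
delocalization. Parallel trimers resolve them with a β-layer: each chain
turns three residues into a short β-strand, the three strands cross in a
plane perpendicular to the bundle axis, hydrogen-bond through their
central residues (backbone N–O ≤ 3.5 Å), and move each chain's path 120°
around the trimer axis, counterclockwise viewed from the N terminus. The
element sits in place of a heptad *d* position with register
a-b-c-β₁-β₂-β₃-e-f-g (nonads) or e-f-g/c-β₁-β₂-β₃-e-f-g (hexads).

The package is for structural bioinformaticians annotating coiled-coil
fibers (trimeric autotransporter adhesin stalks, phage fibers and related
families): it finds β-layers in PDB/mmCIF structures, assigns local
periodicity and heptad register from coordinates, computes the
periodicity algebra of heptad insertions, scans sequences for the family
consensus motifs ([aliphatic]-A-T-K-[polar]-[DE] and the tandem
LxxKADKxxVYTKxE), and generates the synthetic parametric bundles used to
validate all of it.

## The method

Detection is a two-step search. Backbone (φ, ψ) torsions are classified
into an α box (−70° ≤ ψ ≤ −10°, −180° ≤ φ ≤ −40°) and a β box
(20° ≤ ψ ≤ 180°, −180° ≤ φ ≤ −40°), and each chain is scanned with
seven-residue windows **βββαααα** and **ααααβββ**; every match nominates
its βββ triplet as a candidate strand. Candidates whose central (β₂)
residues share a backbone N–O contact ≤ 3.5 Å within the biological
assembly are joined, and connected components of ≥ 2 strands are reported
as β-layers (3 strands = canonical). Local periodicity is measured
TWISTER-style from Cα geometry as 360/(twist − bundle-azimuth advance)
per residue, and register labels come from Crick angles against the seven
ideal heptad positions. Details and design choices are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic C3-symmetric stalk with a planted nonad β-layer and
detect it:

```sh
$ betalayer simulate --kind fixture --spacing nonad --out stalk.pdb
wrote stalk.pdb
$ betalayer detect stalk.pdb
layer_id  chains  strand_residues          sequence  n_strands  canonical  capping  transition_type  register
1         A,B,C   A:18-20;B:18-20;C:18-20  MAT       3          True       N-cap    cc-to-cc         a-b-c-β1-β2-β3-e-f-g
```

One canonical layer: the MAT strand of each chain at residues 18–20,
hydrogen-bonded cyclically across the trimer. The hydrophobic β₁ (M)
marks an N-capping interaction network, the flanks are coiled coil on
both sides (`cc-to-cc`), and the register shows the element in place of a
*d* position. The companion `stalk.pdb.json` records the planted ground
truth.

Why a 2-residue insertion needs a β-layer at all:

```sh
$ betalayer theory --insert 2
# insertion of 2 residues has no accessible periodicity within 2 heptads: requires a β-layer
insert  heptads  residues  turns  periodicity  handedness  accessible
2       1        9         3      3.0          left        False
2       2        16        4      4.0          right       False
```

Neither 9/3 nor 16/4 falls in the accessible band [3.33, 3.90] — the
insertion cannot be absorbed by supercoiling.

From Python:

```python
from betalayer import read_structure, select_assembly, detect_beta_layers

model = select_assembly(read_structure("structure.pdb"), "1")
for layer in detect_beta_layers(model):
    print(layer.sequence, layer.n_strands, layer.capping)
```

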