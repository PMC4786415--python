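# Methods

## The element and the model

A parallel α-helical coiled coil accommodates its sequence repeat by
supercoiling: relative to the bundle axis, a repeat of *r* residues over
*t* helical turns runs at a local periodicity of *r/t* residues per turn.
The unperturbed α-helix sits near 3.63 residues/turn, so repeats below
that value (the heptad, 7/2 = 3.5) supercoil left-handed and repeats
above it (hendecads 11/3, pentadecads 15/4) right-handed. Supercoiling
strains the helices; the stammer periodicity 10/3 ≈ 3.33 marks the
practical lower edge and, by symmetry of the strain around 3.63, ~3.9 the
upper one. The package stores this band exactly as [10/3, 39/10],
inclusive, as overridable module constants (`theory.ACCESSIBLE_BAND`),
because the edge case 10/3 itself is attainable.

Insertions of 1–6 residues into a heptad background can be delocalized
over neighbouring heptads; each choice of delocalization and added turns
yields a rational periodicity (`theory.insertion_periodicity`). Insertions
of 2 or 6 residues reach no accessible periodicity at moderate
delocalization. Trimeric coiled coils resolve them instead by a
**β-layer**: the three chains each turn three residues into a short
β-strand; the strands cross in a plane perpendicular to the bundle axis,
hydrogen-bond through their central residues, and shift each chain's path
120° around the axis (counterclockwise viewed from the N terminus). The
element replaces a heptad *d* position: in nonads the register reads
a-b-c-β₁-β₂-β₃-e-f-g; in hexads the residue before β₁ is a *g* whose
Crick angle is biased ~15° toward *c* (the hybrid g/c position) and the
register reads e-f-g/c-β₁-β₂-β₃-e-f-g. Downstream of a β-layer the
register always restarts at *e*.

## Detection

Detection follows a two-step procedure. First, backbone (φ, ψ) torsions
are classified into two inclusive rectangular regions — α: −70° ≤ ψ ≤
−10°, −180° ≤ φ ≤ −40°; β: 20° ≤ ψ ≤ 180°, −180° ≤ φ ≤ −40° — and each
chain's class string is scanned with seven-residue windows βββαααα and
ααααβββ. Every match nominates its βββ triplet as a candidate strand; a
triplet hit by both windows is one candidate. Second, candidates are
joined when their central (β₂) residues share a backbone N–O contact of
at most 3.5 Å (inclusive, heavy atoms only, either direction, no angular
term) within the biological assembly; connected components of ≥ 2 strands
are reported, with 3 strands the canonical case. Torsions are never
computed across chain breaks (C–N ≥ 2.5 Å) or incomplete residues, and
windows shorter than seven residues at chain termini are not matched.

Reported layers are annotated by rule: a lysine in β₁ marks a C-capping
interaction network of the upstream helices, a hydrophobic β₁
({A,V,L,I,M,F}) an N-capping network of the downstream ones; the
transition type (cc-to-cc, cc-to-β, β-to-cc, Nterm-to-cc, cc-to-coil)
comes from the four residues flanking the strand on each side. These are
sequence/class rules, not re-measured sidechain networks.

## Periodicity and register analysis

Per-residue local helix frames are built from four consecutive Cα by the
bisector construction: the bisectors of the virtual Cα angles at i and
i+1 both point at the local axis; their cross product gives the axis
direction and a least-squares radius puts both offset points on one
line. From the frames come twist (deg/residue), rise and radius. The
bundle axis is the smoothed pointwise centroid of all chains' axis
points, with a straight line fitted through it; for a C3-symmetric
bundle this is the symmetry axis to well under 0.05 Å.

Local periodicity relative to the bundle axis corrects the twist by the
advance of the local axis point around the bundle axis:

    periodicity(i) = 360 / (twist(i) − azimuth_advance(i))

A straight helix therefore measures 360/twist (3.63 at canonical twist)
and a heptad coiled coil 3.5. Traces are smoothed for plotting with a
centered width-3 moving average that shrinks at ends and skips invalid
entries. The Crick angle of a residue is the signed azimuth of its Cα
about the local axis measured from the direction toward the bundle axis;
ideal heptad positions sit at seven angles spaced 720/7° in sequence
order with a and d straddling the core direction. Register labels are
nearest-ideal-angle assignments, with three exceptions: strand residues
are β₁β₂β₃; the residue after β₃ is forced to *e*; and a residue
directly before β₁ displaced from ideal *g* toward *c* by more than 10°
(default, configurable) — but by less than half the g–c separation, so
that it is still nearest to g — is labelled g/c. Near segment edges
(including the two residues flanking a strand, whose four-residue frame
windows would cross into it) Crick angles are measured about the axis
line of the nearest interior frame rather than the residue's own frame.

Equivalence with established periodicity-plot tools is claimed at the
level of recovered parameters on ideal geometry (see below), not
per-residue numeric identity.

## Synthetic structures

`build_backbone_from_torsions` grows N/CA/C/O from ideal bond lengths
and angles (N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, C-O 1.231 Å;
N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°) by natural-extension
reference frames; measured torsions reproduce the inputs to < 1e-3°.

`generate_crick_coil` places Cα on the two-level helix parameterization:
a local helix of radius 2.26 Å wound on a superhelix of radius 6.5 Å
(default) rising 1.5 Å/residue. The axis azimuth advance per residue is
w0 = twist − 360/P for target periodicity P; the minor-helix phase
advance is 360/P + w0(1 − cos α), where α is the superhelix pitch angle
— the correction accounts for the tangent frame itself rotating about
the local axis at w0·cos α, and without it a 10/3 coil measures ≈ 3.28
instead of 3.33. The full backbone is placed by expressing an ideal
helix residue's N/C/O offsets in a Cα-trace frame (tangent, angle
bisector, normal) and re-applying them in the generated trace's frames;
for gently supercoiled traces the torsion error stays far inside the α
box. Chains are exact n-fold rotation copies about the z axis. The
generator↔analyzer loop recovers every nominal periodicity in
{3.33, 3.5, 3.6, 3.67, 3.75, 3.8} within 0.005 (tested at 0.03).

Planted β-layer fixtures are grown as α…α-βββ-α…α torsion chains (twice
for the tandem) and placed with the upstream helix axis on the bundle
radius parallel to z; 120° rotation copies complete the C3 trimer. The
junction torsions (the ψ before β₁, the three strand (φ, ψ) pairs, the φ
after β₃, plus the roll and default radius of the placement) were tuned
once against the element's geometric contract — cyclic central N–O
≈ 2.9 Å after assembly, downstream helix parallel to the bundle axis at
−120° azimuth from the upstream one, flank Crick angles on the dictated
register — and are frozen as named constants. For the nonad and tandem
variants the tuning was constrained to keep every torsion ≥ ~18° inside
its Ramachandran box; the hexad uses the unconstrained optimum because
the g/c bias genuinely requires near-edge torsions. The default
`bundle_radius="auto"` scans the radial placement on a 0.1 Å grid around
the tuned default and refines by bisection until the worst cyclic
central N–O distance reaches ~2.9 Å (at most 3.2 Å — deliberately inside
the 3.5 Å criterion so tests never ride the cutoff boundary); for tandem
fixtures the two layers pull the radius in opposite directions and the
search finds the valley between them.

What the fixtures emulate: torsion-class patterns, the cross-chain
central hydrogen bonds, the 120° path shift, register-consistent flank
geometry, C3 symmetry, and PDB-representable coordinates. What they do
not: sidechains beyond the residue identity, solvent and packing
context, crystallographic disorder, deviations from ideal bond geometry,
and the water-widened non-canonical layer variants seen in some real
structures. Passing the fixture battery therefore demonstrates the
correctness of the detection logic and geometry pipeline, not its
sensitivity on noisy experimental coordinates.

## Noise and robustness

`perturb` adds iid isotropic Gaussian noise per atom. At σ = 0.1 Å this
produces backbone-torsion swings of ±15–25°, enough to occasionally flip
a residue class out of its box; since the window patterns are strict,
detection of a planted layer survives in ~19/20 seeds (asserted as
≥ 16/20), with failures coming from flank class flips, never from the
hydrogen-bond contact (2.9 Å against a 3.5 Å cutoff). The per-seed
battery variation instead jitters flank torsions by ±0.5°, which leaves
classes and junction geometry intact; larger jitter is not correctable
for tandem fixtures because their two junctions share a single rigid
placement correction.

## Numerical choices and degenerate inputs

Dihedrals follow the IUPAC sign convention and return NaN (not an
exception) for degenerate geometry; box boundaries are inclusive; the
α and β boxes are disjoint in ψ. Helix frames need four Cα and are
invalid on collinear traces. Layers are reported sorted by (chain id,
first residue). Alternate locations resolve to blank/'A', highest
occupancy on ties. Assembly "1" is the default expansion when the file
defines it, else the asymmetric unit (logged); re-expanding an expanded
model is an error. The residue-class sets of the motif scanner
(aliphatic {A,V,L,I,M}, polar {S,T,N,Q,D,E,K,R,H,Y}) admit all family
instances discussed in the package documentation and are module
constants. All stochastic operations take explicit integer seeds.

Problem sizes throughout the test suite and the reproduction script —
28-residue coils, fixtures with 12–16-residue flanks, a 21-fixture
battery — were chosen as the smallest sizes at which the measured
quantities are stable to well inside their test tolerances.

## Known limitations

* Terminal windows (< 7 residues) are not matched, so β-layers within
  three residues of a chain end escape the scan by design.
* The hydrogen-bond test is distance-only; no angular or energetic term.
* Register assignment assumes locally straight helical flanks when
  extrapolating Crick angles at segment edges; strongly supercoiled
  segments near a junction would bias the g/c call.
* The detector reports two-strand components as non-canonical layers;
  real non-canonical β-layers whose flanks do not match the two window
  patterns (e.g. strand-swapped or water-invaded variants) are out of
  scope.
* The synthetic fixtures use a single idealized junction geometry per
  spacing; real β-layers show modest structural spread around it.
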