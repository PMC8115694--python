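# Methods

This note documents the models behind `filapole`, the choices made where the
design was genuinely open, and what the synthetic benchmarks do and do not
demonstrate.

## Scope and representation

The package studies how homologous death-domain-fold protomers (pyrin-domain
like) assemble into helical filaments bidirectionally yet recognize a partner
filament at only one axial pole. All structure is handled at residue-bead
resolution: one CA and one CB bead per residue (CB = CA for glycine), with a
coarse physicochemical class per residue — hydrophobic {A,V,L,I,M,F,W},
positive {K,R,H; formal charge +1 for K,R}, negative {D,E; −1}, polar
{S,T,N,Q,C,Y} and special {G,P} — fixed in `io_model` and configurable. This
resolution is sufficient for the interface-level questions the package asks;
it is not a substitute for all-atom modelling of real structures, where the
package's outputs are qualitative.

## Helical lattices

A lattice is (twist, rise, Cn): placement *(level k, copy c)* applies a
rotation of `k·twist + c·360/cn` degrees about +z followed by a translation
of `k·rise` along z. Positive twist is right-handed; "top" is +z. The
reference lattice is twist 53.3°, rise 14 Å, C3 — a six-per-turn,
three-start geometry characteristic of pyrin-domain filaments (about 6.75
subunits per turn). Published analyses of such filaments also quote an
effective twist near 54.4° from power-spectrum indexing; the package treats
twist purely as an input/fit quantity and takes no side.

Fitting inverts construction: the consensus screw transform between axially
consecutive subunits is estimated per pair by Kabsch superposition, the
rotation angle about the screw axis gives the twist and the axial translation
component the rise. The axis comes from the rotation matrix itself (exact for
noiseless helices), not from a PCA of centroids, which is only the degenerate
fallback for twist-free stacks; below 1e-4° of rotation the axis direction is
numerically undetermined and the transform is treated as a pure translation.
The reported residual is the RMS deviation of per-pair estimates from the
consensus (degrees and Ångströms pooled 1:1).

## Interface classification

Contacts are CB–CB pairs under 8 Å (the bead model's resolution). Each
subunit pair in contact carries the screw decomposition of its relative
transform — signed rotation angle and translation along the screw axis —
which is invariant under any global rigid motion of the filament. Edges are
single-linkage clustered on those two features with tolerances of 5° and
2 Å, far below the inter-class separation of the reference lattice (53.3° /
14 Å vs −66.7° / 14 Å vs −13.4° / 28 Å). Type ids are assigned by axial
offset rank — smallest → 1, middle → 3, largest → 2 — with ties (the two
one-level lateral classes share a 14 Å offset) broken by rotation-angle
magnitude ascending. This reproduces the field's convention that type 2 is
the predominantly axial contact; mapping the package's geometric labels onto
residue-level death-domain surface definitions of a particular deposited
structure is a one-time annotation, not derivable from geometry alone. In
each edge the lower-z subunit contributes the `a` surface (a-surfaces face
+z).

The honeycomb around an interior subunit is its six contacting neighbors;
the six ligand–pocket subsections are the cyclically consecutive neighbor
trios in the unrolled (azimuth, z) sheet. A subsection is *top* when the
pocket's mean height is below the ligand (the ligand docks onto the top
surface of the pocket), giving three top and three bottom subsections.

## Energy model

The score is a transparent stand-in for an all-atom interface energy, chosen
to be hand-checkable rather than physical:

```
E(i,j) = [eps(cls_i, cls_j) + w_elec · q_i · q_j] · S(d_ij) + clash
S(d)   = 1 for d ≤ 6 Å, linear to 0 at 8 Å, 0 beyond;  clash = +2 if d < 3.5 Å
```

with the class-pair well depths: hydrophobic–hydrophobic −1.0,
opposite-charge −1.5, like-charge +1.5, polar–polar −0.5, polar–charged
−0.25, hydrophobic–charged +0.25, hydrophobic–polar 0, anything involving
special 0; `w_elec` = 1. A Lys–Glu contact at 5 Å scores −2.5. Absolute
values have no physical meaning and are never compared with published
kcal/mol or Rosetta numbers; only orderings and designed contrasts are
interpreted.

## Local docking

`local_dock` perturbs the ligand from its native pose (half-normal rotation
angle, default scale 10°, uniform axis; isotropic normal translation,
default 2 Å) and then minimizes greedily: 20 iterations, each probing three
random orthonormal directions in both signs as translations and as rotations
about the ligand COM, with steps halving from (2°, 1 Å) whenever no move
improves. Two locality restraints keep this a *local* docking protocol: the
ligand COM may not leave a 4 Å sphere around its native position and the
orientation may not exceed 30° from native. Without them greedy descent
slides off the pocket onto neighboring interfaces (cross-patch superminima
7–9 Å from native), which neither a local docking protocol nor the bound
state it probes should visit. Random probe directions matter: a fixed
lab-frame move set is not equivariant under the filament's dihedral symmetry
and produced a systematic top/bottom artifact. RMSD is the ligand CA RMSD
from the native pose without superposition. Each call consumes one RNG
stream seeded explicitly; results are bit-stable within a release.

## Recognition polarity

`polarity_score` docks each of the six subsections independently and sums a
per-subsection "best docked energy" over the top and the bottom faces;
`delta = E_top − E_bottom`. The per-subsection summary is the mean of the
best half of the samples: a bare minimum is an extreme statistic whose
bootstrap is inconsistent (observed ~50–60% interval coverage on an exactly
symmetric construction), and a 10–25% tail still undercovered (~87%); the
best-half mean restored nominal coverage while remaining dominated by the
funnel bottom. The bootstrap resamples dock energies within each subsection
(1000 replicates, percentile 2.5/97.5). Verdicts: `polarized_top` when the
interval is entirely below zero (top face more favorable), `polarized_bottom`
when entirely above, `bidirectional` exactly when the interval covers zero.

Dissociation energetics come as a deterministic rigid-body separation scan
(`separation_pmf`): the ligand is translated along the pocket→ligand COM
axis, the interface energy is recorded per step, the profile is anchored to
zero at full separation, and the dissociation barrier is the maximum along
the exit path out of the global minimum (zero for repulsive complexes). Both
this scan and the metadynamics engine below are surrogates: neither replaces
all-atom molecular dynamics, and their outputs say so.

## Well-tempered metadynamics (1-D)

`wt_metad_1d` runs an overdamped Langevin walker (Euler–Maruyama, reflecting
domain bounds) on a user potential plus a history-dependent bias. Every
`pace` steps a Gaussian hill of width σ and height `w0·exp(−V(s)/((γ−1)kT))`
is deposited (bias accumulated on a grid, default bin 0.01 CV units); the
free-energy estimate is `F = −(γ/(γ−1))·V` at the end, min-anchored, and
the hills log records (step, center, height). Default parameters follow the
standard protocol for a COM-separation CV in nm with energies in kJ/mol:
hill 1 kJ/mol, σ 0.05 nm, bias factor 4, termination when the CV exceeds
5 nm. Validation uses kT = 1 units: a 5 kT double-well barrier is recovered
within 15% and a flat potential stays within 1 kT, both averaged over five
walkers of 150,000 steps (hill 0.5 kT, σ 0.08, pace 100, γ 8 — a larger
bias factor than the production default because the validation wells are
only a few kT deep and γ controls how much of the well depth the bias
ultimately fills). Integrator defaults (dt 1e-3, friction 1) were chosen so
the flat-potential diffusion test passes.

## Saturation mutagenesis and selectivity

Every pocket residue touching the ligand in any subsection is substituted to
the 19 other amino acids, with the ligand kept wild type, in a homotypic
context (ligand = filament species) and a heterotypic context (ligand =
partner species). A context's ΔG is the sum of the six subsection interface
energies, and **ΔΔG = ΔG(mutant) − ΔG(wild type), positive =
destabilizing**. The classical presentation of this screen prints the
subtraction in the opposite order while still plotting deleterious mutations
at positive ΔΔG; the package adopts the sign convention consistent with the
plots. Substitutions change only a bead's class and charge — coordinates are
frozen (rigid model; sterics only via the clash term) — so ΔΔG is computed
exactly from precomputed switch matrices. The >2 SD outlier filter operates
on raw mutant-complex energies by default (switchable to ΔΔG), with mean and
SD taken over the full scan before any removal and an audit list of removed
records.

Quadrant classification at threshold T: homo-disrupting (ΔΔG_homo > T,
ΔΔG_hetero < T), hetero-disrupting (the reverse), both, neutral. A
position's call is the plurality class over its 19 substitutions with ties
resolved to neutral. The default T = 5.0 package units sits between the
score's cross-term noise (|ΔΔG| ≲ 3 on the reference scenario) and its
weakest designed signal (≳ 15); recovery on the reference scenario is
threshold-insensitive across T ∈ [3, 14]. The rule "T = 2× median |ΔΔG| at
neutral positions" is available as `calibrate_threshold`, but degenerates to
zero on the reference scenario, whose designed-neutral positions are exactly
inert. The literature threshold of 10 is in Rosetta energy units and does
not transfer.

## Synthetic scenarios (the ground truth)

Toy protomers are rigid coarse bodies: a glycine core around a centroid
placed 33 Å from the helix axis, plus six 4-bead surface patches positioned
from the lattice itself so that patch pairs (1a:1b), (2a:2b), (3a:3b) of
neighboring subunits meet at a designed 4.2 Å CB–CB gap and *nothing else*
comes within the 8 Å interaction cutoff (verified by an exhaustive offset
scan at construction time; the 33 Å radius is the smallest round value that
clears every off-design approach by ≥ 8 Å). Patch geometry, not fold,
carries the interaction code.

Two properties make the homotypic benchmarks exact rather than statistical:

1. **Conjugate C2 symmetry.** The centroid lies on an axis perpendicular to
   the filament axis; every bead has a partner at its 180°-image about that
   axis carrying the charge-conjugate residue (K↔E, R↔D, N↔Q, S↔T). The
   energy function is invariant under charge conjugation, so the filament is
   exactly dihedral and top and bottom docking landscapes are congruent by
   construction — any measured homotypic asymmetry is sampling noise.
2. **Per-edge-type energies.** Species A pairs K⁴:E⁴ at type 1 (strongest,
   as lateral type-1 contacts dominate in the filaments emulated), K₂N₂:E₂Q₂
   at type 3, and inert glycine pads at the axial type 2, so homotypic axial
   contacts exist geometrically (three contact classes) but carry no energy.

Heterotypic recognition is a separate, deliberately asymmetric device: A
carries a retracted arginine "recognition arm" behind its 2a pad (C2 forces
the conjugate aspartate image behind the 2b pad), laterally offset and deep
enough to touch nothing in the homotypic lattice; species B carries a
protruding aspartate "reach arm" on its 2b face that meets the retracted
arginines of the A subunit *below* it. Docking B onto an A-filament pocket
is therefore favorable only from the top (the B arm points down), B's
lateral patches are charge-reversed with respect to A (mismatched in hetero
contacts, weakly self-complementary in B–B), and the designed ground truth
is clean: the 12 charged lateral positions of A are homo-critical with
hetero ΔΔG ≤ 0, the 4 arm arginines are hetero-critical with homo ΔΔG
exactly 0, and the pads are exactly neutral. The `homo_bidirectional`
scenario omits the arms entirely (pure self-assembly code); the arms'
cross-patch attractions, though symmetric, create legitimate secondary
basins that belong to the recognition system, not to the cognate funnel
benchmark. Stability ordering follows the emulated system: homotypic A
complexes bind tighter than heterotypic B-on-A, which bind tighter than
homotypic B.

Synthetic kinetics plates are logistic curves with designed half-times,
replicate structure, Gaussian noise (default 2% of the unit amplitude, the
scale of a well-behaved FRET plate assay), a flat no-seed control and a WT
control; generators are pure functions of (specification, seed).

## Kinetics analysis

Traces are fit with a 4-parameter logistic (an empirical shape for
sigmoidal seeded assembly, not a nucleation-growth mechanism; a model-free
half-maximum interpolation is available as an alternative). A trace is
flagged non-polymerizing — apparent rate 0 — when the fitted amplitude is
within 3 residual SDs of the noise floor or the fitted half-time falls
outside the sampled window. The apparent rate is 1/t_half, the simplest
monotone conversion. Activity ratios normalize a rate between the no-seed
control (0) and the WT control (1); values outside [0, 1] are reported and
flagged, never clipped. Paired comparisons use the classical two-sided
paired t test; no multiplicity correction is applied by default (per-mutant
p values), with Holm step-down available.

## Problem sizes and reproducibility

The shipped benchmarks use 6-level C3 filaments (18 subunits, 40-bead
protomers), 100–1000 dock samples per subsection, 10–20 polarity seeds,
150,000-step metadynamics walkers in quintuplicate, 10,000 null simulations
for the t-test size, and 3-replicate kinetics plates — sizes at which every
documented tolerance holds with margin on commodity hardware in minutes.
Every stochastic routine takes an explicit seed and is bit-stable for fixed
inputs within a release.

## Known limitations

- The bead-and-class energy is ordinal, not thermodynamic: it encodes
  designed contrasts, and published interface scores (Rosetta units,
  kJ/mol) are not reproducible or comparable.
- Rigid bodies throughout: no side-chain repacking, no backbone response,
  mutations cannot introduce true steric strain (prolines are not special).
- The synthetic protomers prove that the *pipeline* recovers designed
  interface codes; they say nothing about whether a particular real filament
  is polarized — that requires the real structures, where this package
  offers geometry (diameters, symmetry fitting, monomer RMSD) and qualitative
  screens only.
- The 1-D metadynamics engine is validated on analytic potentials; applying
  it to a real dissociation coordinate inherits all the usual CV-quality
  caveats.
- `extract_pockets` assumes the six-neighbor honeycomb of six-per-turn
  lattices; other symmetries (e.g. four-per-turn CARD filaments) classify
  correctly but the pocket partition is untested there.
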