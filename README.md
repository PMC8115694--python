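# filapole

Helical filament lattices, interface energetics and directional recognition
for death-domain-like protomers.

Inflammasome signaling platforms are built from pyrin-domain (PYD) filaments:
a receptor filament nucleates an adaptor filament of a homologous domain.
Both filaments are helical (≈53° twist, 14 Å rise per subunit, C3), both
assemble bidirectionally, and yet the receptor filament recruits its partner
at only one axial pole. `filapole` is a toolkit for asking how a lattice of
identical subunits can encode that asymmetry, at residue-bead resolution:

- **helix** — build filaments from (twist, rise, Cn) and fit the parameters
  back from coordinates via the consensus inter-subunit screw transform;
- **lattice** — classify the three recurring subunit–subunit interface types
  (1a:1b, 2a:2b, 3a:3b) from contact geometry and carve the six honeycomb
  ligand–pocket subsections around an interior subunit;
- **energetics** — a transparent residue-class contact potential
  `E = [ε(class_i, class_j) + q_i·q_j]·S(d)` with local rigid-body docking
  funnels (energy vs RMSD);
- **mutscreen** — dual-context saturation mutagenesis:
  ΔΔG = ΔG(mutant) − ΔG(wild type) in homotypic and heterotypic honeycombs,
  with quadrant classification of positions into self-assembly-critical vs
  partner-recognition-critical;
- **directionality** — top-vs-bottom docking polarity with bootstrap
  verdicts, rigid-body separation free-energy profiles, and a 1-D
  well-tempered metadynamics engine (hills of height
  `w0·e^{−V/((γ−1)kT)}`, estimate `F = −γ/(γ−1)·V`);
- **kinetics** — seeded-polymerization curve fitting (4-parameter logistic),
  half-time → apparent rate, activity ratios normalized between no-seed (0)
  and wild-type (1) controls, paired t tests;
- **synthetic_data** — toy protomers whose surface patches carry designed
  interaction codes, giving every stage exact ground truth;
- **io_model** — PDB/mmCIF in, residue beads out; PDB/TSV/JSON writers and a
  `filapole` command-line interface over all of the above.

Real structures can be read and measured (symmetry fitting, diameters,
monomer RMSD); the energy model, however, is ordinal by design — see
`docs/methods.md` for every model, default and limitation.

## A worked example

Build the polarized scenario — an A-species filament whose top face carries
retracted arginine recognition sites, and a B species whose protruding
aspartate arm can reach them only from above:

```python
from filapole import (EnergyModel, build_filament, classify_interfaces,
                      contact_map, extract_pockets, make_scenario,
                      polarity_score)

sc = make_scenario("hetero_polarized", seed=1)
fil = build_filament(sc["protomer_a"], sc["lattice"])
edges = contact_map(fil, cutoff=8.0)
classify_interfaces(edges)                      # -> 3 interface clusters
subs = extract_pockets(fil, fil.index_of(3, 0), edges)   # 6 subsections

res = polarity_score(fil, subs, EnergyModel(),
                     ligand=sc["protomer_b"], n_samples=100, seed=1)
print(res.verdict, round(res.delta, 1), [round(c, 1) for c in res.bootstrap_ci])
```

prints

```
polarized_top -110.9 [-112.0, -109.6]
```

meaning: summed over the three top subsections, the best docked energies of
a B ligand are 110.9 score units more favorable than over the three bottom
subsections, and the bootstrap interval excludes zero — the B species
recognizes this filament's top face only. Running the same call with
`ligand=None` on the `homo_bidirectional` scenario gives deltas within a few
tenths of zero and the verdict `bidirectional`: the filament itself grows
both ways. The same scenario drives the mutagenesis screen:

```python
from filapole import saturation_scan, selectivity_report

recs = saturation_scan(fil, subs, EnergyModel(),
                       contexts={"homo": None, "hetero": sc["protomer_b"]})
calls, scatter = selectivity_report(recs)
print({c.position: c.call for c in calls if c.call != "neutral"})
```

which recovers exactly the designed code — the 12 charged lateral-patch
positions as `homo_disrupting` (they hold the filament together without
biasing a direction) and the 4 axial arm arginines as `hetero_disrupting`
(they are the partner-recognition site).

The same pipelines are scriptable from the shell (`filapole build`,
`fitsym`, `lattice`, `dock`, `energy`, `mutscan`, `selectivity`, `polarity`,
`pmf`, `metad`, `kinetics`, `simulate …`); run `filapole --help`.

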