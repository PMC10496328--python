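# rinkit

Residue Interaction Networks (RINs) from protein 3D structures.

`rinkit` reads a PDB or mmCIF file and maps each model onto an attributed
undirected graph: nodes are residues, edges are geometrically detected
non-covalent interactions — hydrogen bonds, van der Waals contacts, ionic
bridges, π–π stacks, π–cation interactions, hydrophobic contacts — or,
alternatively, the Cα contact map. Every edge carries the bond type, the
participating atoms, the distance, an orientation angle where the criterion
is angular, and a distance/orientation-dependent energy in kcal/mol. Output
is GraphML (default) or a node/edge CSV pair, with one output file per model
for multi-model inputs (NMR ensembles, MD trajectories).

Detection is driven by closed-ball radius queries against a balanced 3D
kD-tree built per atom subset (acceptors, heavy atoms, ring centroids, …),
so candidate enumeration scales sub-quadratically with structure size. All
thresholds and energy constants are configurable from the CLI or a flat
`key = value` config file.

## CLI

```sh
# GraphML RIN of model 1 with all specific bond detectors
rinkit rin input.pdb --out input.graphml

# node/edge CSV instead
rinkit rin input.pdb --out rin --format csv     # writes rin_nodes.csv, rin_edges.csv

# Cα contact map, custom cutoff
rinkit rin input.pdb --out ca.graphml --ca --ca-dist 7.0

# one RIN per model of a trajectory
rinkit rin traj.pdb --all-models --out-dir rins/

# tune thresholds; print the effective configuration
rinkit rin input.pdb --out out.graphml --hbond-dist 3.2 --pipi-parallel 25
rinkit rin --dump-config > defaults.cfg
rinkit rin input.pdb --out out.graphml --config defaults.cfg

# emit the curated test-fixture catalog (PDB files + manifest.tsv)
rinkit fixtures --out-dir fixtures/

# node/edge counts and betweenness of an existing RIN
rinkit stats input.graphml
```

Preparation flags: `--model K` / `--all-models`, `--keep-hetero`,
`--no-hydrogen` (strip hydrogens), `--add-backbone-h` (synthesize backbone
amide hydrogens; the only hydrogen addition supported), `--altloc
highest-occupancy|first`. Waters are always removed.

Hydrogen-bond detection defaults to the angular criterion (donor must carry
an H; D–H···A angle ≥ 120°). For hydrogen-free crystal structures either add
backbone hydrogens (`--add-backbone-h`) or switch to distance-only mode
(`--no-hbond-require-h`).

`stats` reports betweenness in the path-ratio form (shortest paths through a
node divided by the total number of shortest paths in the network);
`--brandes` switches to the standard pair-normalized variant.

## Library

```python
from rinkit import (BondParams, PrepOptions, parse_structure, prepare_model,
                    annotate_chemistry, detect_contacts, build_rin,
                    write_graphml, betweenness)

structure = parse_structure("input.pdb")
prepared = prepare_model(structure.models[0], PrepOptions())
chem = annotate_chemistry(prepared)
contacts = detect_contacts(prepared, chem, BondParams())
rin = build_rin(prepared, contacts, structure_id=structure.id)
write_graphml(rin, "input.graphml")
print(betweenness(rin))
```

`rinkit.fixtures` generates minimal synthetic molecules with exactly
realized geometry (donor/acceptor pairs, ring stacks, ideal chains, random
globules) — every detector is testable without downloading anything.

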