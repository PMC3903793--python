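# piface

Extraction, structural comparison and clustering of protein–protein
interfaces from PDB coordinate files.

The pipeline:

1. **structure_io** – parse PDB/mmCIF entries, keep the first model,
   drop nucleic-acid chains, waters/ligands and chains with nonstandard
   amino acids, enumerate all binary chain pairs.
2. **sasa** – Shrake–Rupley accessible surface area (deterministic
   golden-spiral sampling, probe 1.4 Å). Chain pairs burying ≤ 1 Å² are
   discarded before interface extraction; relative ASA (RASA) uses an
   Ala-X-Ala reference table.
3. **interface_extract** – contact residues (any heavy-atom pair closer
   than the vdW-radius sum + 0.5 Å), nearby residues (Cα within 6 Å of a
   contact Cα on the same chain), the ≥5-contacts-per-side rule, and
   PDB-format interface files named like `1GQPAB`.
4. **structural_align** – order-independent (non-sequential) alignment
   of two interfaces: congruent-Cα-triangle seeding, mutual-nearest-
   neighbour extension inside a 3 Å threshold, Kabsch refinement.
   Similarity = matched residues / smaller interface size. A size gate
   (contacts within 1.25×, totals within 1.50×) prunes hopeless pairs.
   Precomputed similarities can be imported from TSV instead.
5. **interface_network** – similarity network (edge iff similarity
   ≥ 0.75 by default) clustered by node-grouping-accelerated
   Girvan–Newman edge-betweenness division: five grouping stages at
   thresholds 0.80…1.00, community finding after each, then a final
   ungrouped division. Stopping rules: mean local clustering coefficient
   ≥ cc_stop, minimum cluster size 5.
6. **evaluation** – silhouette index (dissimilarity 1 − similarity),
   parameter-grid model selection (cells tagged e.g. `100_5_max`),
   cluster size distributions.
7. **surface_multibinding** – monomer surface extraction at 40% RASA,
   per-interface RASA statistics, 100%-identity sequence clustering,
   detection of protein pairs binding through multiple interface
   architectures, and shared- vs distinct-site classification.
8. **synthetic_fixtures** – toy two-chain complexes with controllable
   contact geometry, perturbed/bent copies, and planted-partition
   similarity networks (all seeded).

## CLI

```sh
piface extract 1abc.pdb                   # filtered chain summary
piface asa 1abc.pdb --probe 1.4 --points 960
piface interfaces 1abc.pdb 2xyz.pdb --out ifaces/
piface align ifaces/ --rmsd 3.0 --out similarity.tsv
piface cluster similarity.tsv --cc-stop 1.0 --step 5 --merge max --out clusters.tsv
piface evaluate clusters.tsv similarity.tsv
piface surface 1abc.pdb --cutoff 40
piface synth complex --gap 3.6 --span 2 10 --out toy.pdb
piface synth graph --blocks 6,6 --out planted.graphml
piface run --config run.cfg --out rundir/   # full pipeline
```

`run.cfg` is a flat `key=value` file; defaults match the documented
thresholds (contact slack 0.5 Å, nearby cutoff 6 Å, min contacts 5, ASA
prefilter 1 Å², RMSD threshold 3 Å, size gate 1.25/1.50, edge threshold
0.75, grouping steps 0.80–1.00, cc stop 1.0, min cluster size 5, RASA
cutoff 40%).

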