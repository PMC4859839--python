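# File formats

Energies are kcal/mol in every external file (hartree only inside the
engine and where explicitly labelled); distances and coordinates are Å.
Atom and frame indices in configs and reports are 0-based.

## Fragment-annotated XYZ (dimers)

Standard XYZ with the comment line carrying fragment ranges (1-based atom
serials, as in the XYZ body) and formal charges:

```
9
FRAG_A=1..6 FRAG_B=7..9 CHARGE_A=0 CHARGE_B=-1
N    0.0000000000 ...
```

Read/written by `pocket_eda.fragments.read_dimer_xyz` / `write_dimer_xyz`;
input to `pocket-eda decompose`.

## Trajectories

* multi-model PDB: `MODEL`/`ATOM`/`ENDMDL` records, identical atom order in
  every model;
* concatenated XYZ: repeated `natoms / comment / atoms` blocks.

## Mixture specs (YAML, `pocket-eda synth --config`)

```yaml
n_frames: 2000
hbonds:
  - bond_id: ASP118_O1
    mixture: [[0.7, 1.9, 0.12], [0.3, 2.9, 0.45]]   # weight, mean Å, sd Å
rings:
  - ring_id: PHE44
    mixture: [[1.0, 4.8, 0.5]]
```

## Monitored pairs (YAML, `pocket-eda hbonds/select --config`)

```yaml
pairs:
  - {bond_id: b1, hydrogen: 1, acceptor: 2}   # 0-based atom indices
rings:
  - {ring_id: r1, ring_a: [0, 1, 2], ring_b: [3, 4, 5]}
```

## CSV tables

* **H-bond frequency table**: rows = bonds; columns = bin centers
  (1.625 … 3.375 by default) plus `out_of_range`; entries = percent of all
  frames, 1 decimal.
* **Component table**: columns `label, DE_HL, e_el_10, DE_ex_HL,
  DE_del_HF, DE_HF` (kcal/mol).  The packaged reference table is
  `pocket_eda/data/table2.csv`.
* **Correlation matrix**: 5×5 Spearman ρ over the component columns.
* **Covalency report**: `label, hbond_distance, e_hf, ratio,
  classification` with `ratio = DE_del_HF / e_el_10` at 2 dp.

## JSON artifacts

* **EDA result**: the five components, monomer/dimer total energies
  (hartree), basis name and the hartree→kcal/mol constant used.
* **Selection report**: chosen frame (0-based), per-frame totals and
  modal-membership counts, the criteria configuration.
* **Pipeline manifest**: package version, seed, thresholds, per-stage wall
  times and SHA-256 checksums of every emitted file.
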