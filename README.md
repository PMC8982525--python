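# phoreqsar

Pharmacophore fitting, docking-based ligand/receptor contact fingerprints
(LRCFs) and GA-driven ML-QSAR, as a tested, reusable pipeline. The package
covers the full discovery computation: perceiving chemical features on 3D
conformers, scoring molecules against pharmacophore models (feature-sphere
fit values with exclusion-sphere screening), turning scored docking poses
into binary contact fingerprints, assembling descriptor matrices, selecting
descriptor subsets with a genetic algorithm wrapped around pluggable
regressors (MLR / nu-SVR / random forest), and validating models with
cross-validated q², predictive r², ROC AUC and the Güner–Henry score.
A seeded synthetic-data module generates every input the pipeline needs,
so all stages are testable offline.

## Layout

| module | role |
| --- | --- |
| `phoreqsar.descriptors` | molecule data model, feature perception, connectivity/kappa/ring/dipole/inertia/shadow descriptors, SDF/SMILES I/O |
| `phoreqsar.pharmacophore` | PHORE model format, Kabsch alignment, fit values, 3D screening, F-value ranking |
| `phoreqsar.contacts` | receptor structures (PDB), top-pose selection, 2.5 Å contact bits, LRCF matrices |
| `phoreqsar.qsar` | descriptor-matrix assembly, potency-ranked train/test split, GA feature selection, validation statistics |
| `phoreqsar.screening` | activity-threshold labeling, confusion/ROC/GH metrics, hit ranking and filtering |
| `phoreqsar.synthetic` | seeded generators: pockets, planted-match ligands, scored poses, activities, ROC sets |
| `phoreqsar.pipeline` | nine-stage end-to-end workflow with a reproducible run manifest |

Three pharmacophore model files and a reference MLR equation ship under
`phoreqsar/data/`.

## CLI

Every stage is exposed through one console script:

```sh
phoreqsar simulate  --seed 1 --n-compounds 40 --match-fraction 0.5 --out bundle/
phoreqsar descriptors --in bundle/ligands.sdf --out physchem.tsv
phoreqsar fit       --phore bundle/Hypo_5_R2_08.phore --in bundle/ligands.sdf --out fits.tsv
phoreqsar screen    --phore bundle/Hypo_5_R2_08.phore --in bundle/ligands.sdf --hits hits.tsv
phoreqsar lrcf      --receptor bundle/pocket.pdb --poses poses.sdf --scores scores.tsv --out lrcf.tsv
phoreqsar assemble  --fits fits.tsv --lrcf lrcf.tsv --physchem physchem.tsv \
                    --activities act.tsv --out matrix.tsv
phoreqsar gfa       --matrix matrix.tsv --learner mlr --seed 1 --out selected.json
phoreqsar validate  --matrix matrix.tsv --subset selected.json --out report.json
phoreqsar roc       --scores scores.tsv --labels labels.tsv
phoreqsar hits      --pred predictions.tsv --out retained.tsv
phoreqsar pipeline  --config config.json --out run/
```

`pipeline` runs all nine stages (simulate → descriptors → fits → lrcf →
assemble → split → gfa → validate → screen) and writes `manifest.json`
with per-output SHA-256 digests; rerunning an identical config reproduces
identical digests.

## Conventions

- IC50 values are molar; the modeled response is log10(1/IC50) (pIC50).
- Contact distance threshold is inclusive (≤ 2.5 Å), all-atom, hydrogens
  eligible; fingerprint columns are named `RES_<num>_<atomname>^<channel>`
  with channels `LD` and `CD`.
- The fit value is `n_mapped × W × (1 − Σ(disp/tol)²)` summed over every
  mapped feature point; a `per_feature_sum` variant is available because
  the product form can go negative for many poorly mapped features.
- Exclusion spheres default to 0.6 Å radius (1.2 Å diameter); configurable.
- Leave-20%-out folds are deterministic, rank-striped on activity.
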