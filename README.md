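# pocketgcn

Graph-convolutional prediction of GPCR pocket–ligand binding, for
computational chemists screening compound libraries against
G-protein-coupled receptors when no receptor–ligand complex structure
is available.

The package covers the full pipeline:

* **I/O** (`chemio`) — a strict PDB subset reader (exact Å→nm
  conversion, first-altloc policy), SMILES/SDF ligands via RDKit,
  delimited affinity tables, and checksummed graph archives.
* **Featurization** (`featurize`) — GraphDTA-style one-hot atom
  features; Morgan-substructure "sentences" and a seeded skip-gram
  embedding that yields a 30-dimensional vector per amino acid.
* **Pockets** (`pocket`) — ligand-defined pocket extraction (0.6 nm
  known-ligand / 0.8 nm placed-ligand cutoffs) and α-carbon contact
  graphs (0.5 nm).
* **Curation** (`curate`) — binder/non-binder labels (< 4 nM positive,
  > 4000 nM negative, mid-range excluded), pKa regression labels,
  duplicate reconciliation, pair- and protein-disjoint splits.
* **Models** (`gcnmodel`) — a dual-branch GCN (pocket branch + ligand
  branch merged into fully connected layers) with a sigmoid
  classification head and a linear pKa regression head; BCE/MSE losses,
  Adam, dropout 0.2, periodic checkpoints. Forward and backward passes
  are explicit NumPy, finite-difference-verified, and fully seeded.
* **Metrics** (`metrics`) — AUC, TPR, precision, accuracy, MCC, F1;
  RMSE, MSE, Pearson, Spearman, concordance index, Prmsd
  (RMSE / mean pKa); docking-score binarization; per-target reports
  with pooled ALL / averaged Average rows.
* **Screening** (`screen`) — multi-score candidate tables and the
  Strategy A (BC ∧ RG ∧ docking) / Strategy B (RG ∧ docking) inclusive
  threshold filters with ranked survivor reports.
* **Synthetic studies** (`synthdata`) — a deterministic generator of
  toy structures, ligand libraries and affinity tables with a planted
  pocket-composition × ligand-aromaticity signal
  (pKa = 6.5 + β·z₁·z₂ + N(0, σ)), so everything above is testable
  without downloads.

The regression target is pKa = −log₁₀ K with K the affinity (IC50, Ki
or Kd) in molar: 1 nM ↦ 9.0, 1000 nM ↦ 6.0. See `docs/methods.md` for
the full model description, parameter defaults and limitations.

## Worked example

Generate a small synthetic study, train the classifier, and evaluate on
held-out pairs:

```python
import numpy as np
from pocketgcn import synthdata, featurize, curate, gcnmodel, metrics

cfg = synthdata.SynthConfig(n_proteins=8, n_ligands=40, seed=42)
ds = synthdata.generate_dataset(cfg)
table = featurize.default_embedding_table(list(ds.ligand_smiles.values()), seed=0)
pairs, info = synthdata.build_labeled_pairs(ds, mode="bc", table=table)
print("label counts:", info["label_counts"])

split = curate.split_dataset(pairs, level="pair", fraction=0.25, seed=0)
tr = [pairs[i] for i in split.train_ids]; te = [pairs[i] for i in split.test_ids]
model = gcnmodel.build_model(
    gcnmodel.ModelConfig(pocket_widths=(16, 16), ligand_widths=(16, 16),
                         fc_widths=(32, 16), head="bc"),
    30, tr[0].ligand.node_features.shape[1], seed=0)
gcnmodel.train(model, tr, te,
               gcnmodel.TrainConfig(lr=0.005, epochs=120, checkpoint_interval=60,
                                    batch_size=64, seed=0))
scores = gcnmodel.predict_batch(model, te)
labels = np.array([p.label for p in te])
row = metrics.classification_metrics(scores, labels, name="held-out")
print(metrics.report_to_tsv([row], metrics.CLASSIFICATION_COLUMNS))
```

Output:

```
label counts: {'positive': 61, 'negative': 93, 'excluded': 166}
name	auc	tpr	precision	accuracy	mcc	f1	pos_num	neg_num
held-out	0.99	0.88	1.00	0.95	0.90	0.94	17	21
```

Of the 320 generated receptor–ligand pairs, 154 fall outside the
ambiguous 4–4000 nM band and receive labels; after 120 epochs the model
separates held-out binders from non-binders almost perfectly
(AUC 0.99), recovering the planted composition×aromaticity signal.

A command-line interface mirrors the stages
(`pocketgcn simulate|pocket|curate|train|predict|evaluate|screen`);
`pocketgcn --help` lists flags.

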