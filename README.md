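# mcldti

Multimodal drug–target interaction (DTI) prediction with bi-directional
cross-attention, in pure scientific Python.

## The problem

Given a small molecule (as a SMILES string) and a protein target (as an
amino-acid sequence), predict whether the two interact — a binary
classification at the heart of virtual screening and drug repositioning.
The same formulation covers drug–drug interaction (DDI) over two SMILES.

This package implements a two-modality, cross-attention architecture:

* the drug is represented both as a **rendered structural-formula
  image** (encoded by a CNN backbone into spatial tokens) and as
  **chemical text** — its pharmacophore features (donor, acceptor,
  aromatic, … with their atom sites) serialized to a word sequence;
* each modality stream passes through pre-norm multi-head
  self-attention (MSA) blocks and the two are fused with learnable
  scalar weights, `X_drug = λ₁·X_img + λ₂·X_txt`;
* the protein sequence is k-gram tokenized (3-mers by default),
  embedded and MSA-encoded;
* two decoders exchange information through **multi-head
  cross-attention (MCA)** — queries from one entity, keys/values from
  the other — giving interaction maps `Z_drug→target` and
  `Z_target→drug`, which a convolutional fusion head turns into an
  interaction probability, trained with binary cross-entropy and Adam.

Everything — including the reverse-mode autodiff engine behind the
network — runs on NumPy; RDKit provides depiction and pharmacophore
features, Biopython the FASTA I/O. A built-in synthetic benchmark with
a *planted* rule (drug substructure AND protein motif) makes training,
evaluation, ablations and the λ study fully reproducible offline.

## Worked example

```python
from mcldti import DTIClassifier, SyntheticSpec, gen_dataset, roc_auc

data = gen_dataset(SyntheticSpec(n_examples=1000, seed=7))
X = [(ex.drug_smiles, ex.partner) for ex in data]
y = [ex.label for ex in data]

clf = DTIClassifier(seed=0).fit(X[:800], y[:800])   # 30 epochs by default
probs = clf.predict_proba(X[800:])[:, 1]
print(f"held-out ROC-AUC: {roc_auc(probs, y[800:]):.3f}")
print("lambda_img=%.2f lambda_txt=%.2f" % (
    float(clf.result_.net.lam1.data), float(clf.result_.net.lam2.data)))
```

```
held-out ROC-AUC: 0.965
lambda_img=0.98 lambda_txt=1.02
```

The classifier fuses the rendered image and pharmacophore text of each
drug with the 3-mer-tokenized protein and learns the conjunctive
interaction rule. The printed ROC-AUC is the probability that a random
interacting pair is ranked above a random non-interacting one among the
held-out 200 pairs; the two learnable modality weights stay near their
1.0 initialization, indicating both drug modalities keep contributing.
Training takes a couple of minutes on one CPU core.

The same pipeline is scriptable from the shell:

```bash
mcldti synth --n 1000 --seed 7 --out data/
mcldti prepare --input data/pairs.tsv --ratios 0.8 0.1 0.1 --seed 0 --out data/
mcldti train --data data/ --out run/
mcldti evaluate --checkpoint run/checkpoint.npz --data data/test.tsv
mcldti ablate --data data/ --variants full,-mca,-mca-text --seeds 0,1,2 --out ablation.csv
```

Public benchmark pair files (balanced human/worm sets, Kd-thresholded
kinase panels, DDI tables) use the same three-column format and are
consumed by the identical commands; `--affinity` binarizes a Kd column
at the strict `< 30` threshold.

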