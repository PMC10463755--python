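# Methods

## The model

`mcldti` predicts whether a small molecule interacts with a protein
target (or, in the drug–drug variant, with a second small molecule) as a
binary classification over (SMILES, sequence) pairs.

**Drug representation — two modalities.** The drug is represented twice:

1. *Molecular image.* The SMILES string is depicted as a standard 2-D
   structural formula (RDKit, white background) on an `h × h` RGB grid
   with intensities scaled to [0, 1]. A CNN backbone of four
   conv(3×3) → batch-norm → ReLU → max-pool(2×2) stages reduces each
   side by 16; the resulting `(h/16)²` spatial cells are flattened
   row-major into tokens and projected linearly to the model width `d`.
   Convolutions use replicate padding, so a featureless (constant) image
   produces identical tokens — border artifacts carry no spurious
   signal.
2. *Chemical text.* RDKit's pharmacophore feature factory (default
   `BaseFeatures.fdef`) reports one feature per matched atom group. Each
   feature is serialized as three words — family (`Donor`, `Acceptor`,
   `Aromatic`, …), type (`SingleAtomDonor`, …) and the atom index tuple
   `(i,j,...)` — ordered by (first atom index, family, type). This word
   sequence is k-gram tokenized and embedded. The serialization is this
   package's committed dialect; the atom-tuple word ties a feature to
   its location in the molecular graph so that identical families on
   different sites remain distinguishable.

Each modality stream is refined by pre-norm multi-head self-attention
(MSA) blocks — `x + MHSA(LN(x))` then `x + MLP(LN(x))` — after adding
learned positional embeddings (attention is otherwise
permutation-equivariant). The two streams are then combined

    X_drug = λ₁ · X_img + λ₂ · X_txt

with scalar weights that are either trainable (initialized at 1.0, so
both modalities start on an equal footing) or fixed by configuration. Because the streams
have different token counts, image tokens are first resampled along the
token axis by adaptive averaging to the text length; the resampling is a
fixed row-stochastic matrix, hence differentiable and parameter-free.

**Target representation.** The protein's amino-acid string is uppercased,
cut into overlapping k-grams (stride 1), indexed against a dictionary
built in first-appearance order over the *training* corpus only
(PAD = 0, UNK = 1; out-of-vocabulary phrases at inference map to UNK),
embedded, positionally encoded and refined by MSA blocks. In the DDI
variant the partner drug is encoded by the same drug encoder (shared
weights) — the natural reading of "the same method" for the partner's
embedding.

**Bi-directional cross-attention decoders.** Each entity has a decoder:
an MSA block followed by a multi-head cross-attention (MCA) block with
the same pre-norm/residual/MLP skeleton, whose queries are projected
from the decoder's own stream and keys/values from the other entity's
post-MSA stream. The drug decoder yields `Z_drug→target`, the target
decoder `Z_target→drug`. A reading in which both the query and the
key/value are projected from the same entity would collapse the block
into plain self-attention, so the default follows the standard decoder
convention — queries from the decoder's own stream, keys/values from
the other entity — with a config flag
`mca_query_source={"self","other"}` to flip the assignment. Which
decoder output carries which name is likewise a convention of this
package. Setting `use_mca=False` removes the MCA blocks entirely,
leaving MSA-only decoders (the cross-attention ablation).

**Fusion head and loss.** Both decoder outputs are resampled to a common
token length `L_fuse = min(L_drug, L_tgt)` and stacked as a 2-channel
`L_fuse × d` image: Conv2D(3×3, 8 channels) → ReLU → token-axis mean →
Conv1D(3, 16 channels) → ReLU → MLP(512, ReLU, dropout) → FC → one
logit → logistic squashing. Padded key positions are excluded from every
attention softmax via additive −∞ masking (a fully padded stream keeps
position 0 attendable so the softmax stays well defined). Training
minimizes the mean binary cross-entropy, with probabilities clamped to
[1e−7, 1 − 1e−7] because the loss is undefined at 0 and 1.

## Optimization protocol

Adam, mini-batch shuffling per epoch, learning rate `lr · decay^⌊e/10⌋`
(the decay coefficient applies every 10 epochs — the cadence is a
package choice; only the coefficient is prescribed), and checkpoint
selection by validation ROC-AUC; without a validation set the final
epoch is returned. The two-phase grid search first scans learning rate ×
batch size, then fixes the winners and scans dropout × decay, each cell
trained for a budgeted epoch count and judged by validation ROC-AUC
(ties break toward the lower learning rate, then the smaller batch).
Repeated evaluation trains over seeds {0..4} and reports per-metric mean
± sample standard deviation (n−1), rendered to three decimals.

The default dropout (0.2) and learning rate (1e−3) are the winners of
this search protocol replayed on the synthetic benchmark (budgeted
epochs, validation ROC-AUC as the criterion; lower learning rates
converged more slowly and scored worse within the 30-epoch budget).
Reference settings for GPU-scale runs on the public benchmarks are
lr 1e−3, decay 0.8, dropout 0.1 and batch 128 over 100 epochs.

All randomness — weight initialization, shuffling, dropout masks —
derives from the single `TrainConfig.seed`, so two runs with the same
seed are bitwise identical (the engine is plain NumPy; no threading
nondeterminism).

## Numerical engine

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine on NumPy arrays (`mcldti.nn`) with exactly
the operators the architecture needs (broadcast arithmetic, batched
matmul, softmax, fused layer/batch norm, im2col convolution, 2×2 max
pooling, embedding gather). Arrays are float32 by default; every
operator's analytic gradient is tested against central differences in
float64. Attention uses additive −∞ masks, so masked keys receive
exactly zero weight.

## Defaults and problem sizes

The defaults are a CPU-scale protocol chosen so the full pipeline —
training included — runs in minutes on one core while preserving every
architectural element:

| parameter | default | note |
|---|---|---|
| image side `h` | 48 | divisible by 16 → 9 image tokens |
| model width `d` | 32 | 4 heads of 8 |
| depth | 1 MSA + 1 MCA layer per block | matches the single-block design |
| `L_drug` / `L_tgt` | 48 / 80 | truncate longer token streams |
| drug-text k / protein k | 1 / 3 | see below |
| conv channels | (8, 16, 32, 64) | backbone stages |
| fusion | Conv2D 8 ch, Conv1D 16 ch, MLP 512 | |
| lr / decay / batch | 1e−3 / 0.8 per 10 epochs / 32 | |
| epochs | 30 | synthetic benchmark protocol |
| dropout | 0.2 | selected by the grid-search protocol on the synthetic benchmark |

Larger, GPU-era settings (h = 224 → 196 tokens, d = 256, 8 heads,
protein window 1000, batch 128, 100 epochs) remain plain configuration
values; nothing in the code assumes the small sizes.

Protein tokens default to 3-mers, a standard protein tokenization in
interaction models, rather than single residues: at desk scale a
single-residue vocabulary forces the network to learn motif composition
purely from positional context, which needs far more data and epochs,
while 3-mers make short sequence motifs first-class tokens. k is fully
configurable (k = 1 reproduces per-residue tokens).

## The synthetic benchmark

Public DTI benchmarks (balanced human/worm sets, the Kd-thresholded
kinase panel) are pair tables of SMILES, sequence and a 0/1 label; the
generator emulates exactly that shape with a *planted* rule so that
every stage of the pipeline is exercisable offline and the labels have a
known generative mechanism:

* a hand-curated library of 64 valid drug-like SMILES, half carrying a
  free carboxylic-acid group (the marker substructure, SMARTS
  `[CX3](=O)[OX2H1]`);
* uniform random amino-acid strings of length 40–80, with a 3-residue
  motif (`HKH`) written in by *replacement* at a random position for
  motif-positive sequences — replacement, not insertion, so sequence
  length carries no label signal;
* label 1 iff the drug has the substructure AND the protein the motif
  (single-condition rules are available for modality-sensitivity
  studies); negatives violate a uniformly chosen condition pattern, and
  motif-free sequences are rejection-sampled to be genuinely motif-free.

A positive rate of 0.5 mirrors the balanced public sets; a 0.05 preset
mirrors the 1:19 test imbalance of the kinase panel for PR-AUC stress
tests. What passing on this benchmark shows: the architecture can carry
drug-side signal through both modalities, protein-side signal through
the k-gram pathway, and combine them conjunctively via cross-attention.
What it does not show: anything about real binding physics, assay noise,
scaffold or target-family generalization, or dataset bias — the rule is
a logical conjunction, far cleaner than any binding database.

## Design choices in open territory

* **Splits** are uniform seeded shuffles with floor-rule sizes (valid
  and test get ⌊ratio·N⌋, train the remainder); stratification is an
  opt-in flag, since the source protocol states only the 8:1:1 ratio.
* **Kd binarization** is strict: positive iff Kd < 30.
* **ROC-AUC** follows the Mann–Whitney convention (ties half credit);
  **PR-AUC** is step-integrated average precision with tied scores
  grouped — no trapezoidal interpolation, so values are reproducible
  bit-for-bit. Recall and F1 use the fixed threshold 0.5.
* **Ablations** are config deltas: single-modality variants drop the
  other encoder branch's parameters entirely; `-mca` removes exactly
  the cross-attention blocks; `image+smiles` feeds raw SMILES
  characters through the unchanged text machinery.
* **Vocabularies** are fit on the training split only and persisted as
  JSON; drug-text and protein vocabularies are separate.
* **Duplicate pairs** are kept as-is; no deduplication is applied.

## Known limitations

* The NumPy engine is single-threaded and eager; it is sized for the
  desk-scale protocol, not for the full public benchmarks.
* RDKit depiction determinism holds within one RDKit version; images
  rendered by different versions may differ at the pixel level.
* The chemical-text dialect (three words per pharmacophore feature) is
  a committed convention of this package, not a published standard.
* With `mca_query_source="other"` the two streams must share a token
  length; the default `"self"` has no such restriction.
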