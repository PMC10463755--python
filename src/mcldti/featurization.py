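"""Drug and target featurization.

A drug SMILES string yields two modalities:

* a rendered 2-D structural-formula image (``render_image``), consumed by
  the convolutional backbone, and
* a "chemical text" — the pharmacophore features reported by RDKit's
  feature factory, serialized as a word sequence of family name, type name
  and the contributing atom indices (``chemical_text``).

Targets are amino-acid strings tokenized character-wise.  Both text kinds
go through the same k-gram pipeline: a stride-1 sliding window of length k
(``segment_kgrams``), a first-appearance dictionary built on the training
corpus (``KGramVocab``), and fixed-length integer encoding (``encode``).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from PIL import Image
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import Draw
from rdkit.Chem import ChemicalFeatures

RDLogger.DisableLog("rdApp.*")

PAD = 0
UNK = 1


class FeaturizationError(ValueError):
    """Raised when a SMILES or sequence cannot be featurized."""


def _mol_from_smiles(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    return mol


def render_image(smiles: str, h: int = 48, channels: int = 3) -> np.ndarray:
    """Render a SMILES string to an h x h x channels intensity grid in [0, 1].

    White background, standard 2-D depiction; deterministic for a fixed
    RDKit version.
    """
    mol = _mol_from_smiles(smiles)
    img: Image.Image = Draw.MolToImage(mol, size=(h, h))
    arr = np.asarray(img.convert("RGB"), dtype=np.float64) / 255.0
    if channels == 1:
        arr = arr.mean(axis=-1, keepdims=True)
    elif channels != 3:
        raise ValueError(f"channels must be 1 or 3, got {channels}")
    return arr


@lru_cache(maxsize=1)
def _feature_factory():
    fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
    return ChemicalFeatures.BuildFeatureFactory(fdef)


def chemical_text(smiles: str) -> list[str]:
    """Pharmacophore features of a molecule as an ordered word sequence.

    Each feature contributes three words: its family (e.g. ``Donor``,
    ``Aromatic``), its type (e.g. ``SingleAtomDonor``) and its atom index
    tuple rendered without spaces, e.g. ``(4,5,6,7,8,9)``.  Features are
    ordered by (first atom index, family name); the empty list is a legal
    result for featureless molecules.
    """
    mol = _mol_from_smiles(smiles)
    feats = _feature_factory().GetFeaturesForMol(mol)
    keyed = sorted(
        ((min(f.GetAtomIds()), f.GetFamily(), f.GetType(), tuple(f.GetAtomIds()))
         for f in feats),
        key=lambda t: (t[0], t[1], t[2]),
    )
    words: list[str] = []
    for _, family, ftype, atoms in keyed:
        words.append(family)
        words.append(ftype)
        words.append("(" + ",".join(str(a) for a in atoms) + ")")
    return words


def smiles_text(smiles: str) -> list[str]:
    """SMILES as a character token sequence (the image+SMILES ablation)."""
    _mol_from_smiles(smiles)
    return list(smiles)


def segment_kgrams(tokens, k: int) -> list:
    """Stride-1 sliding window of length k over a token sequence.

    For k = 1 this is the sequence itself; sequences shorter than k give
    the empty list.  Multi-token phrases are joined into single strings.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    tokens = list(tokens)
    if len(tokens) < k:
        return []
    if k == 1:
        return [str(t) for t in tokens]
    return ["".join(str(t) for t in tokens[i:i + k]) for i in range(len(tokens) - k + 1)]


@dataclass
class TokenSeq:
    """Fixed-length integer encoding of one phrase sequence."""

    indices: np.ndarray          # shape (L,), int64
    valid_length: int
    pad_mask: np.ndarray         # shape (L,), bool; True on padded positions

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.pad_mask = np.asarray(self.pad_mask, dtype=bool)


@dataclass
class KGramVocab:
    """First-appearance phrase dictionary with PAD=0 and UNK=1 reserved."""

    k: int
    index: dict = field(default_factory=dict)

    def add_corpus(self, corpus) -> "KGramVocab":
        for phrases in corpus:
            for ph in phrases:
                if ph not in self.index:
                    self.index[ph] = len(self.index) + 2
        return self

    def __len__(self) -> int:
        return len(self.index) + 2

    def __getitem__(self, phrase: str) -> int:
        return self.index.get(phrase, UNK)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"k": self.k, "index": self.index}, fh)

    @classmethod
    def from_json(cls, path) -> "KGramVocab":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(k=obj["k"], index=dict(obj["index"]))


def build_vocab(corpus, k: int) -> KGramVocab:
    """Index every phrase of a (training) corpus in first-appearance order."""
    return KGramVocab(k=k).add_corpus(corpus)


def encode(phrases, vocab: KGramVocab, L: int) -> TokenSeq:
    """Map phrases through the vocab, truncate to L, right-pad with PAD."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    idx = [vocab[p] for p in list(phrases)[:L]]
    n = len(idx)
    indices = np.full(L, PAD, dtype=np.int64)
    indices[:n] = idx
    pad_mask = np.arange(L) >= n
    return TokenSeq(indices=indices, valid_length=n, pad_mask=pad_mask)


def featurize_protein(sequence: str, vocab: KGramVocab, k: int, L: int) -> TokenSeq:
    """Character-level k-gram segmentation of an amino-acid string, encoded.

    Input is uppercased; non-standard letters become their own tokens.
    """
    if not sequence:
        raise FeaturizationError("empty protein sequence")
    return encode(segment_kgrams(sequence.upper(), k), vocab, L)


@dataclass
class MoleculeRecord:
    """One drug: its SMILES plus the two derived modalities."""

    smiles: str
    image: np.ndarray            # (h, h, channels) in [0, 1]
    chem_words: list[str]

    @classmethod
    def from_smiles(cls, smiles: str, h: int = 48, channels: int = 3,
                    text_source: str = "chem") -> "MoleculeRecord":
        if text_source == "chem":
            words = chemical_text(smiles)
        elif text_source == "smiles":
            words = smiles_text(smiles)
        else:
            raise ValueError(f"unknown text_source {text_source!r}")
        return cls(smiles=smiles, image=render_image(smiles, h, channels),
                   chem_words=words)
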