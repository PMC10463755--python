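"""Loss, learning-rate schedule, seeded training loop and grid search.

Optimization follows the reference protocol: Adam on the binary
cross-entropy, a stepwise learning-rate decay, mini-batch shuffling per
epoch, and checkpoint selection by validation ROC-AUC.  All randomness
(weight init, shuffling, dropout) derives from ``TrainConfig.seed``, so a
run is exactly repeatable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import roc_auc
from .featurization import (
    KGramVocab,
    MoleculeRecord,
    encode,
    featurize_protein,
    segment_kgrams,
)
from .network import MCLDTINet, ModelConfig
from .nn.autograd import Tensor, no_grad
from .nn.layers import seed_dropout
from .nn.optim import Adam

logger = logging.getLogger(__name__)

LOSS_EPS = 1e-7  # clamp: the cross-entropy is undefined at p in {0, 1}


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    ``lr_decay`` multiplies the learning rate every ``decay_every``
    epochs.  Defaults are the CPU-scale training protocol used for the
    synthetic benchmarks; see the methods note for the full-scale values.
    """

    lr: float = 1e-3
    lr_decay: float = 0.8
    decay_every: int = 10
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0
    checkpoint_metric: str = "roc_auc"

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if not (0.0 < self.lr_decay <= 1.0):
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class GridSpec:
    """Candidate lists for the two-phase hyperparameter grid search."""

    lr: tuple = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5)
    lr_decay: tuple = (0.5, 0.6, 0.7, 0.8, 0.9)
    batch_size: tuple = (32, 64, 128, 256)
    dropout: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    two_phase: bool = True

    def __post_init__(self):
        for name in ("lr", "lr_decay", "batch_size", "dropout"):
            if not getattr(self, name):
                raise ValueError(f"empty candidate list for {name}")


def bce_loss(p, y) -> float:
    """Mean binary cross-entropy of probabilities against 0/1 labels."""
    p = np.clip(np.asarray(p, dtype=float), LOSS_EPS, 1.0 - LOSS_EPS)
    y = np.asarray(y, dtype=float)
    if p.size == 0:
        raise ValueError("bce_loss of an empty batch")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def bce_loss_t(p: Tensor, y: np.ndarray) -> Tensor:
    """Autograd version of :func:`bce_loss` used inside the training loop."""
    y = Tensor(np.asarray(y, dtype=float))
    p = p.clip(LOSS_EPS, 1.0 - LOSS_EPS)
    one = Tensor(1.0)
    return -(y * p.log() + (one - y) * (one - p).log()).mean()


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Stepwise-decayed learning rate at a given (0-based) epoch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr * cfg.lr_decay ** (epoch // cfg.decay_every)


# -- featurization pipeline ----------------------------------------------------

@dataclass
class FeaturePipeline:
    """Frozen featurization state: config plus training-corpus vocabularies."""

    cfg: ModelConfig
    vocab_drug: KGramVocab
    vocab_tgt: KGramVocab
    _mol_cache: dict = field(default_factory=dict, repr=False)

    def molecule(self, smiles: str) -> MoleculeRecord:
        rec = self._mol_cache.get(smiles)
        if rec is None:
            rec = MoleculeRecord.from_smiles(
                smiles, h=self.cfg.h, channels=self.cfg.channels,
                text_source=self.cfg.drug_text_source)
            self._mol_cache[smiles] = rec
        return rec


def _drug_phrases(smiles: str, pipe: FeaturePipeline) -> list:
    return segment_kgrams(pipe.molecule(smiles).chem_words, pipe.cfg.k_drug)


def build_pipeline(train_examples, cfg: ModelConfig) -> FeaturePipeline:
    """Build drug/target vocabularies from the training split only."""
    pipe = FeaturePipeline(cfg=cfg, vocab_drug=KGramVocab(k=cfg.k_drug),
                           vocab_tgt=KGramVocab(k=cfg.k_tgt))
    drug_corpus, tgt_corpus = [], []
    for ex in train_examples:
        if "text" in cfg.modalities:
            drug_corpus.append(_drug_phrases(ex.drug_smiles, pipe))
        if cfg.task == "ddi":
            if "text" in cfg.modalities:
                drug_corpus.append(_drug_phrases(ex.partner, pipe))
        else:
            tgt_corpus.append(segment_kgrams(ex.partner.upper(), cfg.k_tgt))
    pipe.vocab_drug.add_corpus(drug_corpus)
    pipe.vocab_tgt.add_corpus(tgt_corpus)
    return pipe


def prepare_arrays(examples, pipe: FeaturePipeline) -> dict:
    """Featurize examples into stacked arrays ready for mini-batching."""
    cfg = pipe.cfg
    n = len(examples)
    data: dict = {"labels": np.array([ex.label for ex in examples], dtype=float)}

    def drug_side(smiles_list, prefix):
        if "image" in cfg.modalities:
            imgs = np.empty((n, cfg.channels, cfg.h, cfg.h), dtype=np.float32)
            for i, s in enumerate(smiles_list):
                imgs[i] = pipe.molecule(s).image.transpose(2, 0, 1)
            data[f"{prefix}_images"] = imgs
        if "text" in cfg.modalities:
            toks = np.empty((n, cfg.L_drug), dtype=np.int64)
            mask = np.empty((n, cfg.L_drug), dtype=bool)
            for i, s in enumerate(smiles_list):
                ts = encode(_drug_phrases(s, pipe), pipe.vocab_drug, cfg.L_drug)
                toks[i], mask[i] = ts.indices, ts.pad_mask
            data[f"{prefix}_tokens"] = toks
            data[f"{prefix}_mask"] = mask

    drug_side([ex.drug_smiles for ex in examples], "drug")
    if cfg.task == "ddi":
        drug_side([ex.partner for ex in examples], "partner")
    else:
        toks = np.empty((n, cfg.L_tgt), dtype=np.int64)
        mask = np.empty((n, cfg.L_tgt), dtype=bool)
        for i, ex in enumerate(examples):
            ts = featurize_protein(ex.partner, pipe.vocab_tgt, cfg.k_tgt, cfg.L_tgt)
            toks[i], mask[i] = ts.indices, ts.pad_mask
        data["tgt_tokens"] = toks
        data["tgt_mask"] = mask
    return data


def _slice_batch(data: dict, idx: np.ndarray) -> dict:
    return {key: arr[idx] for key, arr in data.items()}


def predict_scores(net: MCLDTINet, data: dict, batch_size: int = 64) -> np.ndarray:
    """Deterministic (eval-mode) interaction probabilities for a dataset."""
    was_training = net.training
    net.eval()
    n = len(data["labels"])
    out = np.empty(n)
    with no_grad():
        for lo in range(0, n, batch_size):
            idx = np.arange(lo, min(lo + batch_size, n))
            out[idx] = net(_slice_batch(data, idx)).data
    if was_training:
        net.train()
    return out


@dataclass
class TrainResult:
    net: MCLDTINet
    pipeline: FeaturePipeline
    history: list
    best_epoch: int

    def predict(self, examples, batch_size: int = 64) -> np.ndarray:
        data = prepare_arrays(examples, self.pipeline)
        return predict_scores(self.net, data, batch_size=batch_size)


def train_model(model_cfg: ModelConfig, train_cfg: TrainConfig,
                train_set, valid_set=None, verbose: bool = False) -> TrainResult:
    """Train the network; return the checkpoint with the best valid ROC-AUC.

    Without a validation set the final-epoch weights are returned.
    """
    train_set = list(train_set)
    if not train_set:
        raise ValueError("empty training set")
    pipe = build_pipeline(train_set, model_cfg)
    train_data = prepare_arrays(train_set, pipe)
    valid_data = prepare_arrays(valid_set, pipe) if valid_set else None

    net = MCLDTINet(model_cfg, len(pipe.vocab_drug), len(pipe.vocab_tgt),
                    seed=train_cfg.seed)
    seed_dropout(net, np.random.default_rng(train_cfg.seed + 1))
    shuffle_rng = np.random.default_rng(train_cfg.seed + 2)
    opt = Adam(net.parameters(), lr=train_cfg.lr)

    history: list = []
    best_auc, best_epoch, best_state = -np.inf, -1, None
    n = len(train_set)
    for epoch in range(train_cfg.epochs):
        opt.lr = lr_at(epoch, train_cfg)
        net.train()
        order = shuffle_rng.permutation(n)
        losses = []
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo:lo + train_cfg.batch_size]
            batch = _slice_batch(train_data, idx)
            probs = net(batch)
            loss = bce_loss_t(probs, batch["labels"])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "lr": opt.lr,
                  "train_loss": float(np.mean(losses))}
        if valid_data is not None:
            scores = predict_scores(net, valid_data)
            record["valid_roc_auc"] = roc_auc(scores, valid_data["labels"])
            if record["valid_roc_auc"] > best_auc:
                best_auc = record["valid_roc_auc"]
                best_epoch = epoch
                best_state = net.state_dict()
        history.append(record)
        if verbose:
            logger.info("epoch %d: %s", epoch, record)
    if best_state is not None:
        net.load_state_dict(best_state)
    else:
        best_epoch = train_cfg.epochs - 1
    net.eval()
    return TrainResult(net=net, pipeline=pipe, history=history,
                       best_epoch=best_epoch)


def save_checkpoint(path, result: TrainResult) -> None:
    """Serialize weights, config and vocabularies into one ``.npz`` file."""
    import json

    meta = {
        "model_cfg": result.pipeline.cfg.to_dict(),
        "vocab_drug": {"k": result.pipeline.vocab_drug.k,
                       "index": result.pipeline.vocab_drug.index},
        "vocab_tgt": {"k": result.pipeline.vocab_tgt.k,
                      "index": result.pipeline.vocab_tgt.index},
        "best_epoch": result.best_epoch,
    }
    arrays = {f"param::{k}": v for k, v in result.net.state_dict().items()}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> TrainResult:
    """Rebuild a trained model (empty history) from :func:`save_checkpoint`."""
    import json

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        state = {k[len("param::"):]: npz[k] for k in npz.files
                 if k.startswith("param::")}
    cfg = ModelConfig.from_dict(meta["model_cfg"])
    pipe = FeaturePipeline(
        cfg=cfg,
        vocab_drug=KGramVocab(k=meta["vocab_drug"]["k"],
                              index=dict(meta["vocab_drug"]["index"])),
        vocab_tgt=KGramVocab(k=meta["vocab_tgt"]["k"],
                             index=dict(meta["vocab_tgt"]["index"])))
    net = MCLDTINet(cfg, len(pipe.vocab_drug), len(pipe.vocab_tgt))
    net.load_state_dict(state)
    net.eval()
    return TrainResult(net=net, pipeline=pipe, history=[],
                       best_epoch=meta["best_epoch"])


def _valid_auc(result: TrainResult, valid_set) -> float:
    scores = result.predict(valid_set)
    return roc_auc(scores, [ex.label for ex in valid_set])


def grid_search(grid: GridSpec, model_cfg: ModelConfig, train_set, valid_set,
                search_epochs: int = 10, base_cfg: TrainConfig | None = None):
    """Two-phase grid search over the optimization hyperparameters.

    Phase 1 scans learning rate x batch size with the other knobs at
    their defaults; phase 2 fixes the winners and scans dropout x
    learning-rate decay.  The winner maximizes validation ROC-AUC; ties
    break toward lower learning rate, then smaller batch.  Returns
    ``(best TrainConfig, best ModelConfig, log)`` where the log lists one
    record per evaluated cell.
    """
    base = base_cfg or TrainConfig()
    log: list = []

    def run(tc: TrainConfig, mc: ModelConfig, phase: int):
        result = train_model(mc, replace(tc, epochs=search_epochs),
                             train_set, valid_set)
        auc = _valid_auc(result, valid_set)
        log.append({"phase": phase, "lr": tc.lr, "batch_size": tc.batch_size,
                    "lr_decay": tc.lr_decay, "dropout": mc.dropout,
                    "valid_roc_auc": auc})
        return auc

    best = None  # (auc, -lr, -batch) maximized -> ties to lower lr/batch
    for lr, bs in itertools.product(grid.lr, grid.batch_size):
        tc = replace(base, lr=lr, batch_size=bs)
        auc = run(tc, model_cfg, phase=1)
        key = (auc, -lr, -bs)
        if best is None or key > best[0]:
            best = (key, tc)
    best_tc = best[1]

    best2 = None
    best_mc = model_cfg
    for dr, decay in itertools.product(grid.dropout, grid.lr_decay):
        tc = replace(best_tc, lr_decay=decay)
        mc = replace(model_cfg, dropout=dr)
        auc = run(tc, mc, phase=2)
        key = (auc, -decay, -dr)
        if best2 is None or key > best2[0]:
            best2 = (key, tc, mc)
    if best2 is not None:
        best_tc, best_mc = best2[1], best2[2]
    return best_tc, best_mc, log


def repeated_runs(model_cfg: ModelConfig, train_cfg: TrainConfig, train_set,
                  valid_set, test_set, seeds=(0, 1, 2, 3, 4)):
    """Repeat training over seeds; return one (scores, labels) per run."""
    runs = []
    labels = np.array([ex.label for ex in test_set], dtype=float)
    for seed in seeds:
        result = train_model(model_cfg, replace(train_cfg, seed=seed),
                             train_set, valid_set)
        runs.append((result.predict(test_set), labels))
    return runs
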