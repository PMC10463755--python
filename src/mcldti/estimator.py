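"""Scikit-learn estimator interface to the interaction classifier.

``DTIClassifier`` wraps featurization, network construction and seeded
training behind the familiar ``fit`` / ``predict_proba`` surface, so the
model composes with sklearn pipelines and model selection.  ``X`` is any
(n, 2) array-like of strings: column 0 the drug SMILES, column 1 the
partner (protein sequence, or second SMILES with ``task="ddi"``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import InteractionExample, SplitSpec, split_examples
from .network import ModelConfig
from .training import TrainConfig, train_model

_MODEL_KEYS = ("h", "d_model", "n_heads", "depth", "mlp_ratio", "dropout",
               "L_drug", "L_tgt", "k_drug", "k_tgt", "lambda_mode",
               "modalities", "use_mca", "mca_query_source", "task",
               "drug_text_source")
_TRAIN_KEYS = ("lr", "lr_decay", "decay_every", "batch_size", "epochs", "seed")


class DTIClassifier(ClassifierMixin, BaseEstimator):
    """Binary drug-target (or drug-drug) interaction classifier.

    Parameters mirror :class:`~mcldti.network.ModelConfig` and
    :class:`~mcldti.training.TrainConfig`; see those classes for
    semantics.  ``validation_fraction`` of the training pairs is held out
    for checkpoint selection by ROC-AUC (0 disables it, returning the
    final-epoch weights).

    Examples
    --------
    >>> from mcldti.synthetic import SyntheticSpec, gen_dataset
    >>> data = gen_dataset(SyntheticSpec(n_examples=64, seed=0))
    >>> X = [(ex.drug_smiles, ex.partner) for ex in data]
    >>> y = [ex.label for ex in data]
    >>> clf = DTIClassifier(epochs=2).fit(X, y)
    >>> probs = clf.predict_proba(X)[:, 1]
    """

    def __init__(self, *, h: int = 48, d_model: int = 32, n_heads: int = 4,
                 depth: int = 1, mlp_ratio: float = 2.0, dropout: float = 0.2,
                 L_drug: int = 48, L_tgt: int = 80, k_drug: int = 1,
                 k_tgt: int = 3, lambda_mode: str = "learnable",
                 modalities: tuple = ("image", "text"), use_mca: bool = True,
                 mca_query_source: str = "self", task: str = "dti",
                 drug_text_source: str = "chem", lr: float = 1e-3,
                 lr_decay: float = 0.8, decay_every: int = 10,
                 batch_size: int = 32, epochs: int = 30,
                 validation_fraction: float = 0.1, seed: int = 0):
        self.h = h
        self.d_model = d_model
        self.n_heads = n_heads
        self.depth = depth
        self.mlp_ratio = mlp_ratio
        self.dropout = dropout
        self.L_drug = L_drug
        self.L_tgt = L_tgt
        self.k_drug = k_drug
        self.k_tgt = k_tgt
        self.lambda_mode = lambda_mode
        self.modalities = modalities
        self.use_mca = use_mca
        self.mca_query_source = mca_query_source
        self.task = task
        self.drug_text_source = drug_text_source
        self.lr = lr
        self.lr_decay = lr_decay
        self.decay_every = decay_every
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _configs(self):
        kwargs = {k: getattr(self, k) for k in _MODEL_KEYS}
        kwargs["modalities"] = tuple(kwargs["modalities"])
        model_cfg = ModelConfig(**kwargs)
        train_cfg = TrainConfig(**{k: getattr(self, k) for k in _TRAIN_KEYS})
        return model_cfg, train_cfg

    @staticmethod
    def _as_examples(X, y) -> list[InteractionExample]:
        X = np.asarray(X, dtype=object)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): SMILES and partner")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        return [InteractionExample(str(d), str(p), int(lab))
                for (d, p), lab in zip(X, y)]

    def fit(self, X, y):
        examples = self._as_examples(X, y)
        labels = sorted({ex.label for ex in examples})
        if labels != [0, 1]:
            raise ValueError("y must contain both classes 0 and 1")
        model_cfg, train_cfg = self._configs()
        vf = self.validation_fraction
        if vf > 0:
            train_set, valid_set, _ = split_examples(
                examples, SplitSpec(ratios=(1.0 - vf, vf, 0.0), seed=self.seed))
        else:
            train_set, valid_set = examples, None
        self.result_ = train_model(model_cfg, train_cfg, train_set, valid_set)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        self.history_ = self.result_.history
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "result_")
        X = np.asarray(X, dtype=object)
        examples = [InteractionExample(str(d), str(p), 0) for d, p in X]
        p1 = self.result_.predict(examples)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
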