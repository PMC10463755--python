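"""Pair-table I/O, affinity binarization and reproducible splits.

The benchmark files this package consumes are plain-text tables with one
interaction per row: drug SMILES, partner (protein amino-acid string for
DTI, second SMILES for DDI) and a 0/1 label, optionally followed by a Kd
affinity.  Delimiters vary between distributions (tab, comma or space),
so the reader sniffs the dialect per file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)


class PairTableError(ValueError):
    """Malformed pair-table content; carries the offending line number."""


@dataclass
class InteractionExample:
    """One (drug, partner, label) sample; the unit of every dataset."""

    drug_smiles: str
    partner: str
    label: int
    affinity: float | None = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")
        if not self.drug_smiles:
            raise ValueError("empty drug SMILES")
        if not self.partner:
            raise ValueError("empty partner")


@dataclass
class SplitSpec:
    """Train/valid/test ratios plus the shuffling seed."""

    ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be three non-negative reals")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {self.ratios}")


def label_davis(kd: float | None, threshold: float = 30.0) -> int:
    """Binarize a Davis-style Kd: positive iff kd < threshold (strict)."""
    if kd is None:
        raise ValueError("missing Kd value; use a pre-labeled pair file instead")
    return 1 if kd < threshold else 0


def _split_line(line: str) -> list[str]:
    for sep in ("\t", ","):
        if sep in line:
            return [f.strip() for f in line.split(sep)]
    return line.split()


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_pair_table(path, task: str = "dti", affinity: bool = False,
                    fasta: dict | None = None) -> list[InteractionExample]:
    """Read a pair file into examples, preserving row order.

    With ``affinity=True`` the third column is a real Kd and labels are
    derived by :func:`label_davis`; otherwise the third column must be a
    0/1 label (a fourth column, if present, is stored as the affinity).
    ``fasta`` maps sequence ids to sequences, letting the partner column
    hold FASTA header ids.
    """
    if task not in ("dti", "ddi"):
        raise ValueError(f"task must be 'dti' or 'ddi', got {task!r}")
    examples: list[InteractionExample] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    rows = [(i + 1, _split_line(ln)) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        logger.warning("pair table %s is empty", path)
        return examples
    # header: first row whose third column is not numeric
    first_fields = rows[0][1]
    if len(first_fields) >= 3 and not _is_number(first_fields[2]):
        rows = rows[1:]
    for lineno, fields in rows:
        if len(fields) < 3:
            raise PairTableError(
                f"{path}: line {lineno}: expected >= 3 columns, got {len(fields)}")
        smiles, partner, third = fields[0], fields[1], fields[2]
        if fasta is not None and partner in fasta:
            partner = fasta[partner]
        kd = None
        if affinity:
            if not _is_number(third):
                raise PairTableError(
                    f"{path}: line {lineno}: Kd column not numeric: {third!r}")
            kd = float(third)
            label = label_davis(kd)
        else:
            if third not in ("0", "1"):
                raise PairTableError(
                    f"{path}: line {lineno}: label must be 0 or 1, got {third!r}")
            label = int(third)
            if len(fields) >= 4 and _is_number(fields[3]):
                kd = float(fields[3])
        try:
            examples.append(InteractionExample(smiles, partner, label, kd))
        except ValueError as exc:
            raise PairTableError(f"{path}: line {lineno}: {exc}") from exc
    return examples


def write_pair_table(path, examples) -> None:
    """Write examples as a tab-separated pair table (no header)."""
    with open(path, "w") as fh:
        for ex in examples:
            row = [ex.drug_smiles, ex.partner, str(ex.label)]
            if ex.affinity is not None:
                row.append(repr(ex.affinity))
            fh.write("\t".join(row) + "\n")


def load_fasta(path) -> dict:
    """FASTA file -> {header id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def split_examples(examples, spec: SplitSpec, stratify: bool = False):
    """Seeded random partition into (train, valid, test).

    Sizes follow the floor rule: valid and test get floor(ratio * N) each
    and train the remainder.  With ``stratify=True`` the rule is applied
    within each label class.
    """
    examples = list(examples)
    n = len(examples)
    if stratify:
        pos = [e for e in examples if e.label == 1]
        neg = [e for e in examples if e.label == 0]
        tr_p, va_p, te_p = split_examples(pos, spec, stratify=False)
        tr_n, va_n, te_n = split_examples(
            neg, SplitSpec(spec.ratios, spec.seed + 1), stratify=False)
        return tr_p + tr_n, va_p + va_n, te_p + te_n
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_valid = int(np.floor(spec.ratios[1] * n))
    n_test = int(np.floor(spec.ratios[2] * n))
    n_train = n - n_valid - n_test
    train = [examples[i] for i in order[:n_train]]
    valid = [examples[i] for i in order[n_train:n_train + n_valid]]
    test = [examples[i] for i in order[n_train + n_valid:]]
    return train, valid, test


def dataset_summary(examples) -> dict:
    """Counts record: unique drugs, unique partners, samples, positives."""
    examples = list(examples)
    return {
        "drugs": len({e.drug_smiles for e in examples}),
        "partners": len({e.partner for e in examples}),
        "samples": len(examples),
        "positives": sum(e.label for e in examples),
    }


def write_summary(path, examples) -> None:
    with open(path, "w") as fh:
        json.dump(dataset_summary(examples), fh, indent=2)
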