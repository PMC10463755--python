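"""Synthetic interaction benchmarks with a planted, learnable rule.

Real DTI benchmarks pair drug SMILES with protein sequences under labels
from binding databases.  This module emulates their shape with a rule the
network can actually learn: an interaction is positive exactly when the
drug carries a marker substructure (by default a carboxylic acid group)
and the protein contains a short sequence motif.  Negatives violate at
least one of the two conditions, so solving the task requires signal from
both the drug and the target stream.

The drug side draws from a hand-curated library of valid drug-like SMILES
strings, half of which carry the default marker substructure.  No binding
physics is implied; the rule exists to make cross-modal learning testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .datasets import InteractionExample

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Carboxylic-acid-bearing, drug-like molecules (marker substructure present).
ACID_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",       # ibuprofen
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",     # naproxen
    "OC(=O)c1ccccc1",                   # benzoic acid
    "OC(=O)c1ccccc1O",                  # salicylic acid
    "OC(=O)c1cccnc1",                   # nicotinic acid
    "CCCC(CCC)C(=O)O",                  # valproic acid
    "NC(Cc1ccccc1)C(=O)O",              # phenylalanine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",      # tryptophan
    "NC(Cc1ccc(O)cc1)C(=O)O",           # tyrosine
    "CC(C)CC(N)C(=O)O",                 # leucine
    "OC(=O)CCC(=O)O",                   # succinic acid
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",       # citric acid
    "CCCCCCCC(=O)O",                    # caprylic acid
    "CC=CC=CC(=O)O",                    # sorbic acid
    "OC(=O)C=Cc1ccccc1",                # cinnamic acid
    "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl",   # diclofenac
    "CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1",  # ketoprofen
    "CC(C(=O)O)c1ccc(-c2ccccc2)c(F)c1",  # flurbiprofen
    "Nc1ccc(C(=O)O)cc1",                # 4-aminobenzoic acid
    "Nc1ccccc1C(=O)O",                  # anthranilic acid
    "Cc1ccc(C(=O)O)cc1",                # p-toluic acid
    "OC(=O)c1ccc2ccccc2c1",             # 2-naphthoic acid
    "OC(=O)c1ccco1",                    # 2-furoic acid
    "OC(=O)c1ccccn1",                   # picolinic acid
    "COc1cc(C=CC(=O)O)ccc1O",           # ferulic acid
    "NCC(=O)O",                         # glycine
    "CC(N)C(=O)O",                      # alanine
    "NC(CS)C(=O)O",                     # cysteine
    "NC(CO)C(=O)O",                     # serine
    "OC(=O)CCc1ccccc1",                 # hydrocinnamic acid
    "OC(=O)C(O)c1ccccc1",               # mandelic acid
]

#: Drug-like molecules without a free carboxylic acid.
DECOY_SMILES = [
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "Cn1c(=O)c2[nH]cnc2n(C)c1=O",       # theophylline
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "CC(=O)Nc1ccccc1",                  # acetanilide
    "NC(=O)c1ccccc1",                   # benzamide
    "NC(=O)c1cccnc1",                   # nicotinamide
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",  # diazepam
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",       # lidocaine
    "CCN(CC)CCOC(=O)c1ccc(N)cc1",       # procaine
    "CCOC(=O)c1ccc(N)cc1",              # benzocaine
    "COC(=O)c1ccccc1O",                 # methyl salicylate
    "COc1ccccc1",                       # anisole
    "COc1cc(C=O)ccc1O",                 # vanillin
    "O=c1ccc2ccccc2o1",                 # coumarin
    "c1ccc2[nH]ccc2c1",                 # indole
    "c1ccc2[nH]cnc2c1",                 # benzimidazole
    "c1ccc2ncccc2c1",                   # quinoline
    "c1ccc2ccccc2c1",                   # naphthalene
    "CN1CCCC1c1cccnc1",                 # nicotine
    "CC(NC)C(O)c1ccccc1",               # ephedrine
    "CC(N)Cc1ccccc1",                   # amphetamine
    "CN(C)CCOC(c1ccccc1)c1ccccc1",      # diphenhydramine
    "NS(=O)(=O)c1ccc(N)cc1",            # sulfanilamide
    "Cc1ncc([N+](=O)[O-])n1CCO",        # metronidazole
    "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC",  # trimethoprim
    "OCc1ccccc1",                       # benzyl alcohol
    "CC(=O)c1ccccc1",                   # acetophenone
    "CC1=CC(=O)N(c2ccccc2)N1C",         # antipyrine
    "CN1CCOCC1",                        # N-methylmorpholine
    "Oc1ccccc1",                        # phenol
    "CCO",                              # ethanol
    "CC(C)NCC(O)COc1ccccc1",            # propranolol fragment analogue
]

SMILES_LIBRARY = ACID_SMILES + DECOY_SMILES

DEFAULT_SUBSTRUCTURE = "[CX3](=O)[OX2H1]"  # free carboxylic acid


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_examples: int = 1000
    seed: int = 0
    positive_rate: float = 0.5
    rule: str = "substructure_and_motif"
    motif: str = "HKH"
    substructure: str = DEFAULT_SUBSTRUCTURE
    protein_length: tuple = (40, 80)
    library: list = field(default_factory=lambda: list(SMILES_LIBRARY))

    def __post_init__(self):
        if self.n_examples < 4:
            raise ValueError("n_examples must be >= 4")
        if not (0.0 < self.positive_rate < 1.0):
            raise ValueError("positive_rate must lie in (0, 1)")
        if self.positive_rate * self.n_examples < 1:
            raise ValueError("positive_rate * n_examples must be >= 1")
        if len(self.motif) < 3:
            raise ValueError("motif length must be >= 3")
        if self.rule not in ("substructure_and_motif", "substructure_only",
                             "motif_only"):
            raise ValueError(f"unknown rule {self.rule!r}")


def _pattern(spec: SyntheticSpec):
    patt = Chem.MolFromSmarts(spec.substructure)
    if patt is None:
        raise ValueError(f"bad SMARTS pattern {spec.substructure!r}")
    return patt


def _has_substructure(smiles: str, patt) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    return mol.HasSubstructMatch(patt)


def rule_label(smiles: str, sequence: str, spec: SyntheticSpec) -> int:
    """Ground-truth oracle: evaluate the planted rule on one pair."""
    patt = _pattern(spec)
    sub = _has_substructure(smiles, patt)
    motif = spec.motif in sequence
    if spec.rule == "substructure_and_motif":
        return int(sub and motif)
    if spec.rule == "substructure_only":
        return int(sub)
    return int(motif)


def _random_protein(rng, spec: SyntheticSpec, with_motif: bool) -> str:
    lo, hi = spec.protein_length
    while True:
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        if with_motif:
            pos = int(rng.integers(0, n - len(spec.motif) + 1))
            # replacement, not insertion: length carries no label signal
            seq = seq[:pos] + spec.motif + seq[pos + len(spec.motif):]
            return seq
        if spec.motif not in seq:
            return seq


def _split_library(spec: SyntheticSpec):
    patt = _pattern(spec)
    with_sub = [s for s in spec.library if _has_substructure(s, patt)]
    without = [s for s in spec.library if not _has_substructure(s, patt)]
    if not with_sub or not without:
        raise ValueError(
            "SMILES library must contain molecules on both sides of the "
            f"substructure rule {spec.substructure!r}")
    return with_sub, without


def gen_dataset(spec: SyntheticSpec) -> list[InteractionExample]:
    """Generate a DTI dataset whose labels follow the planted rule exactly."""
    rng = np.random.default_rng(spec.seed)
    with_sub, without = _split_library(spec)
    n_pos = int(round(spec.positive_rate * spec.n_examples))
    n_neg = spec.n_examples - n_pos
    examples: list[InteractionExample] = []
    for _ in range(n_pos):
        if spec.rule == "motif_only":
            smiles = str(rng.choice(spec.library))
        else:
            smiles = str(rng.choice(with_sub))
        needs_motif = spec.rule != "substructure_only"
        seq = _random_protein(rng, spec, with_motif=needs_motif)
        examples.append(InteractionExample(smiles, seq, 1))
    for _ in range(n_neg):
        if spec.rule == "substructure_only":
            smiles = str(rng.choice(without))
            seq = _random_protein(rng, spec, with_motif=bool(rng.integers(2)))
        elif spec.rule == "motif_only":
            smiles = str(rng.choice(spec.library))
            seq = _random_protein(rng, spec, with_motif=False)
        else:
            violation = int(rng.integers(3))  # 0: drug, 1: protein, 2: both
            smiles = str(rng.choice(without if violation in (0, 2) else with_sub))
            seq = _random_protein(rng, spec, with_motif=(violation == 0))
        examples.append(InteractionExample(smiles, seq, 0))
    order = rng.permutation(len(examples))
    examples = [examples[i] for i in order]
    for ex in examples:  # labels follow the rule by construction; assert it
        assert rule_label(ex.drug_smiles, ex.partner, spec) == ex.label
    return examples


def gen_ddi_dataset(spec: SyntheticSpec) -> list[InteractionExample]:
    """Drug-drug variant: positive iff both drugs carry the substructure."""
    rng = np.random.default_rng(spec.seed)
    with_sub, without = _split_library(spec)
    n_pos = int(round(spec.positive_rate * spec.n_examples))
    n_neg = spec.n_examples - n_pos
    examples: list[InteractionExample] = []
    for _ in range(n_pos):
        examples.append(InteractionExample(
            str(rng.choice(with_sub)), str(rng.choice(with_sub)), 1))
    for _ in range(n_neg):
        violation = int(rng.integers(3))
        a = str(rng.choice(without if violation in (0, 2) else with_sub))
        b = str(rng.choice(without if violation in (1, 2) else with_sub))
        examples.append(InteractionExample(a, b, 0))
    order = rng.permutation(len(examples))
    return [examples[i] for i in order]
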