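"""Synthetic fixtures with known ground truth.

The generator emulates the statistical structure the moving-average
transform and the linear discriminant assume: class-conditional Gaussian
descriptors whose informative columns separate actives from inactives by a
standardized ``effect_size``, on top of condition-specific location offsets
that the Box-Jenkins recentering is designed to absorb.  The default
condition list reproduces the seven (me, at, bt) combinations observed in a
two-isoform kinase-inhibition dataset, so condition-wise reports have a
realistic shape.

Descriptors here are abstract numbers: they are not derivable from the
bundled SMILES, which exist only so fingerprint-based stages have valid
structures to parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxjenkins import DescriptorBlock
from .core_data import (
    DEFAULT_CUTOFFS,
    ActivityRecord,
    Dataset,
    ExperimentalCondition,
)
from .errors import ConfigurationError

#: The seven experimental conditions of the reference two-isoform dataset.
DEFAULT_CONDITIONS = [
    ExperimentalCondition(bt="MNK-2", me="IC50", at="B"),
    ExperimentalCondition(bt="MNK-1", me="IC50", at="B"),
    ExperimentalCondition(bt="MNK-2", me="Kd", at="B"),
    ExperimentalCondition(bt="MNK-1", me="Kd", at="B"),
    ExperimentalCondition(bt="MNK-2", me="Ki", at="B"),
    ExperimentalCondition(bt="MNK-1", me="Ki", at="B"),
    ExperimentalCondition(bt="MNK-2", me="Ki", at="F"),
]

#: Small vocabulary of valid structures for fingerprint tests.
SMILES_VOCABULARY = [
    "CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "c1ccc2c(c1)cccn2", "C1CCNCC1",
    "c1ccc(cc1)CN", "CC(=O)Nc1ccc(O)cc1", "Clc1ccccc1", "OCCN1CCNCC1",
    "c1ccc(cc1)S(=O)(=O)N", "COc1ccccc1", "CC(N)Cc1ccccc1", "O=C1CCCCC1",
    "c1ccsc1", "c1ccoc1", "c1cnc2[nH]ccc2c1", "CC(=O)c1ccccc1", "NC(=O)c1ccncc1",
]


@dataclass
class SynthSpec:
    """Generator settings; the defaults are the package's study conditions."""

    n_compounds: int = 600
    conditions: list[ExperimentalCondition] = field(
        default_factory=lambda: list(DEFAULT_CONDITIONS)
    )
    n_informative: int = 3
    n_noise: int = 50
    effect_size: float = 2.0
    class_balance: float = 0.35
    #: SD of the per-(condition, column) location offsets on raw descriptors.
    condition_shift: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 0 or self.n_informative < 0 or self.n_noise < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not (0.0 < self.class_balance < 1.0):
            raise ConfigurationError("class_balance must be in (0, 1)")


def generate(spec: SynthSpec) -> tuple[Dataset, DescriptorBlock, dict]:
    """Generate (dataset, raw descriptor block, ground truth).

    Raw descriptor = condition offset + (±effect_size/2 on informative
    columns by class) + unit Gaussian noise.  Activity values in nM are
    drawn consistently with the labels against the default potency cutoffs,
    so the labeling stage reproduces the planted classes exactly.
    Byte-identical output for a given spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    conds = list(spec.conditions)
    n_cols = spec.n_informative + spec.n_noise
    names = [f"INF{i + 1:03d}" for i in range(spec.n_informative)] + [
        f"NSE{i + 1:03d}" for i in range(spec.n_noise)
    ]

    offsets = rng.normal(0.0, spec.condition_shift, size=(len(conds), n_cols))
    cond_idx = rng.integers(0, len(conds), size=n) if conds else np.zeros(n, int)

    n_pos = min(max(int(round(n * spec.class_balance)), 1), n - 1) if n >= 2 else n
    labels = np.full(n, -1, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    X = rng.normal(size=(n, n_cols))
    if conds:
        X += offsets[cond_idx]
    X[:, : spec.n_informative] += (
        labels[:, None] * spec.effect_size / 2.0
    ) * np.ones((1, spec.n_informative))

    records = []
    for i in range(n):
        cond = conds[cond_idx[i]] if conds else DEFAULT_CONDITIONS[0]
        cut = DEFAULT_CUTOFFS.get(cond.me, 100.0)
        # potency drawn on the correct side of the cutoff for the class
        factor = 10.0 ** (
            -rng.uniform(0.1, 1.0) if labels[i] == 1 else rng.uniform(0.1, 1.0)
        )
        records.append(
            ActivityRecord(
                compound_id=f"CPD{i + 1:05d}",
                condition=cond,
                smiles=SMILES_VOCABULARY[i % len(SMILES_VOCABULARY)],
                value_nM=float(cut * factor),
                relation="=",
                label=int(labels[i]),
                row_index=i,
            )
        )
    block = DescriptorBlock(
        column_names=names, values=X, row_ids=[r.compound_id for r in records]
    )
    truth = {
        "informative_columns": names[: spec.n_informative],
        "effect_size": spec.effect_size,
        "n_positive": int((labels == 1).sum()),
        "condition_offsets": {
            f"{c.me}|{c.at}|{c.bt}": offsets[k].tolist() for k, c in enumerate(conds)
        },
        "seed": spec.seed,
    }
    return Dataset(records), block, truth


def generate_library(
    n: int, column_names: Sequence[str], seed: int = 0
) -> tuple[DescriptorBlock, list[str]]:
    """Screening-library fixture sharing the modeling descriptor schema.

    Returns a descriptor block of ``n`` compounds (standard-normal values)
    and a parallel SMILES list drawn from the bundled vocabulary.
    """
    if n < 0:
        raise ConfigurationError("library size must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [f"LIB{i + 1:05d}" for i in range(n)]
    block = DescriptorBlock(
        column_names=list(column_names),
        values=rng.normal(size=(n, len(column_names))),
        row_ids=ids,
    )
    smiles = [SMILES_VOCABULARY[i % len(SMILES_VOCABULARY)] for i in range(n)]
    return block, smiles
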